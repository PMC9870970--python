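"""Simulator contracts: diel structure, hydration physics, determinism."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from crustpam.datamodel import ConfigurationError, campaign_grid, hour_of_day
from crustpam.processing import process_records
from crustpam.simulate import (
    SimConfig,
    WettingEvents,
    day_length_hours,
    draw_wetting_events,
    simulate_campaign,
    simulate_fluorescence,
    simulate_hydration,
    simulate_par,
)
from crustpam.summaries import summarize_campaign, treatment_difference


@pytest.fixture(scope="module")
def grid_30d():
    cfg = SimConfig(end_date=dt.date(2016, 10, 20), seed=2)
    return cfg, campaign_grid(cfg.start_date, cfg.end_date)


def test_par_zero_at_midnight(grid_30d):
    cfg, ts = grid_30d
    par = simulate_par(ts, cfg)
    hours = hour_of_day(ts)
    assert np.all(par[hours == 0.0] == 0.0)
    assert np.all(par >= 0.0)


def test_par_spring_noon_clears_photosynthesis_threshold():
    cfg = SimConfig(
        start_date=dt.date(2017, 4, 1), end_date=dt.date(2017, 4, 30), seed=3
    )
    ts = campaign_grid(cfg.start_date, cfg.end_date)
    par = simulate_par(ts, cfg)
    noon = hour_of_day(ts) == 12.0
    assert np.all(par[noon] > 70.0)


def test_night_fraction_matches_day_length_function():
    """PAR = 0 exactly outside the dawn-dusk window the day-length model sets."""
    cfg = SimConfig(seed=4)
    ts = campaign_grid(cfg.start_date, cfg.end_date)
    par = simulate_par(ts, cfg)
    # independent computation from the day-length function on the same grid
    hours = hour_of_day(ts)
    length = day_length_hours(pd.DatetimeIndex(ts).normalize(), cfg.day_length_amplitude)
    night = (hours <= 12.0 - length / 2.0) | (hours >= 12.0 + length / 2.0)
    assert np.mean(par == 0.0) == pytest.approx(np.mean(night), abs=1e-12)
    assert 0.4 < np.mean(night) < 0.6


def test_warming_offsets_recovered_from_reduced_campaign():
    cfg = SimConfig(end_date=dt.date(2016, 12, 20), seed=9)  # autumn only
    summ = summarize_campaign(process_records(simulate_campaign(cfg)))
    scale = cfg.warming_season_scale["autumn"]
    d_day = treatment_difference(summ, "mean_temperature", period="diurnal")
    d_night = treatment_difference(summ, "mean_temperature", period="nocturnal")
    assert d_day == pytest.approx(cfg.warming_offset_diurnal * scale, abs=0.3)
    assert d_night == pytest.approx(cfg.warming_offset_nocturnal, abs=0.3)


def test_moisture_bounded(small_campaign):
    assert small_campaign["moisture_pct"].between(0.0, 100.0).all()


def test_hydration_no_events_stays_dry():
    cfg = SimConfig()
    n = 200
    temp = np.full(n, 15.0)
    events = WettingEvents(steps=np.array([], int), amplitudes=np.array([], float))
    state = simulate_hydration(np.full(n, 30.0), temp, events, cfg)
    assert np.all(state["water_status"].to_numpy() == 0.0)
    assert not state["is_wet"].any()


@pytest.mark.parametrize("tau", [2.0, 5.0, 10.0, 20.0])
def test_drying_crossing_time_matches_closed_form(tau):
    """After a saturating event at constant T, water status crosses the
    activation threshold at t = tau * ln(1/theta) (exponential decay)."""
    cfg = SimConfig(drying_time_constant=tau)
    n = 4000
    temp = np.full(n, 15.0)  # reference temperature: no Q10 correction
    events = WettingEvents(steps=np.array([0]), amplitudes=np.array([1.0]))
    state = simulate_hydration(np.full(n, 50.0), temp, events, cfg)
    wet_steps = int(state["is_wet"].sum())
    expected_hours = tau * np.log(1.0 / cfg.activation_fraction)
    assert wet_steps * 0.5 == pytest.approx(expected_hours, abs=0.51)


def test_time_to_dry_monotone_in_drying_constant():
    wet_hours = []
    for tau in (2.0, 5.0, 10.0, 20.0):
        cfg = SimConfig(drying_time_constant=tau)
        events = WettingEvents(steps=np.array([0]), amplitudes=np.array([1.0]))
        state = simulate_hydration(
            np.full(3000, 50.0), np.full(3000, 18.0), events, cfg
        )
        wet_hours.append(state["is_wet"].sum())
    assert wet_hours == sorted(wet_hours)


def test_warmer_trace_never_wetter():
    """Same wetting schedule, uniformly warmer thallus: wet hours shrink."""
    cfg = SimConfig(end_date=dt.date(2016, 11, 20), seed=6)
    ts = campaign_grid(cfg.start_date, cfg.end_date)
    events = draw_wetting_events(ts, cfg)
    rng = np.random.default_rng(0)
    temp = 12.0 + 6.0 * rng.standard_normal(len(ts))
    base = simulate_hydration(np.full(len(ts), 40.0), temp, events, cfg)
    warm = simulate_hydration(np.full(len(ts), 40.0), temp + 2.3, events, cfg)
    assert warm["is_wet"].sum() <= base["is_wet"].sum()
    assert np.all(
        warm["water_status"].to_numpy() <= base["water_status"].to_numpy() + 1e-12
    )


def test_dry_fluorescence_below_noise_floors():
    cfg = SimConfig(seed=8)
    n = 500
    hyd = pd.DataFrame({"water_status": np.zeros(n), "is_wet": np.zeros(n, bool)})
    fluor = simulate_fluorescence(hyd, np.zeros(n), cfg)
    assert (fluor["ft"] < 10.0).all()
    assert (fluor["fm"] < 50.0).all()


def test_zero_noise_nocturnal_efficiency_inverts_exactly():
    cfg = SimConfig(noise_sd_ft=0.0, noise_sd_fm=0.0)
    hyd = pd.DataFrame({"water_status": [1.0], "is_wet": [True]})
    fluor = simulate_fluorescence(hyd, np.zeros(1), cfg)
    recovered = (fluor["fm"] - fluor["ft"]) / fluor["fm"]
    assert float(recovered.iloc[0]) == pytest.approx(cfg.fvfm_healthy, abs=1e-12)


def test_campaign_mean_nocturnal_efficiency_near_truth(small_processed, small_config):
    night_active = small_processed[
        (small_processed["period"] == "nocturnal") & small_processed["active"]
    ]
    assert len(night_active) > 100
    assert night_active["efficiency"].mean() == pytest.approx(
        small_config.fvfm_healthy, abs=0.05
    )


def test_campaign_row_count_and_determinism(small_config, small_campaign):
    n_days = (small_config.end_date - small_config.start_date).days + 1
    expected = 2 * n_days * small_config.records_per_day
    assert len(small_campaign) == expected
    again = simulate_campaign(small_config)
    pd.testing.assert_frame_equal(small_campaign, again)


def test_different_seeds_differ(small_config):
    other = simulate_campaign(small_config.with_(seed=small_config.seed + 1))
    assert not np.allclose(
        other["ft"].to_numpy(),
        simulate_campaign(small_config)["ft"].to_numpy(),
    )


def test_dropout_reduces_rows(small_config):
    full = simulate_campaign(small_config)
    sparse = simulate_campaign(small_config.with_(dropout_rate=0.1))
    assert 0.85 * len(full) < len(sparse) < 0.95 * len(full)


def test_invalid_config_lists_offending_fields():
    cfg = SimConfig(dew_probability=1.5, fvfm_healthy=2.0, drying_q10=-1.0)
    with pytest.raises(ConfigurationError) as exc:
        cfg.validate()
    msg = str(exc.value)
    assert "dew_probability" in msg
    assert "fvfm_healthy" in msg
    assert "drying_q10" in msg


def test_stronger_warming_weakly_decreases_diurnal_activity():
    """Matched seeds: raising the diurnal warming offset never adds activity."""
    counts = []
    for offset in (0.0, 2.3, 5.0):
        cfg = SimConfig(
            n_control=0,
            n_warming=1,
            end_date=dt.date(2016, 11, 20),
            seed=13,
            warming_offset_diurnal=offset,
        )
        proc = process_records(simulate_campaign(cfg))
        counts.append(int(proc.loc[proc["period"] == "diurnal", "active"].sum()))
    assert counts[0] >= counts[1] >= counts[2]
    assert counts[0] > counts[2]  # and the effect is real at this scale
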