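"""Seeded synthetic monitoring campaigns.

Generates 30-minute monitoring records with the statistical structure the
downstream analysis assumes: diel and seasonal temperature and PAR cycles,
open-top-chamber warming offsets concentrated in the daylight period (with
the seasonal modulation such passive chambers show — strongest in the warm
season), thallus moisture coupled to temperature with rain and
early-morning dew wetting events, and hydration-gated chlorophyll
fluorescence with instrument noise.

The organism is poikilohydric: it is metabolically active only while the
thallus holds water.  Hydration is a latent 0-1 water status that jumps at
wetting events (to saturation for rain, part-way for dew) and decays
exponentially with a drying time constant that shortens as temperature
rises (a Q10-style evapotranspiration sensitivity).  Photosystem-II
efficiency while hydrated starts from a healthy dark-adapted value,
declines with incident PAR, and is additionally suppressed above a heat
stress onset temperature; steady-state (Ft) and saturation-pulse maximal
(Fm) fluorescence are back-computed from the target efficiency under the
standard relation efficiency = (Fm - Ft) / Fm, plus Gaussian instrument
noise.  Dry steps emit floor readings below the instrument noise
thresholds.

All randomness flows from ``SimConfig.seed`` through fixed, purpose-keyed
streams, so a campaign is reproducible bit-for-bit and structural
parameters (e.g. the warming offset) can be varied under matched noise.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import ConfigurationError, campaign_grid, hour_of_day
from .seasons import SeasonRule

__all__ = [
    "SimConfig",
    "WettingEvents",
    "day_length_hours",
    "simulate_par",
    "simulate_microclimate",
    "simulate_hydration",
    "simulate_fluorescence",
    "simulate_campaign",
]


@dataclass(frozen=True)
class SimConfig:
    """All simulator parameters; defaults reproduce the reference campaign.

    The reference design is six sensors (three control, three warming)
    recorded every 30 minutes for 247 days, 21 Sep 2016 - 25 May 2017.
    """

    start_date: dt.date = dt.date(2016, 9, 21)
    end_date: dt.date = dt.date(2017, 5, 25)
    n_control: int = 3
    n_warming: int = 3
    records_per_day: int = 48

    #: Mean chamber warming of lichen surface temperature while PAR > 0 (degC).
    warming_offset_diurnal: float = 2.3
    #: Chamber warming while PAR = 0 (degC); passive chambers barely warm nights.
    warming_offset_nocturnal: float = 0.2
    #: Seasonal modulation of the diurnal warming offset (day-weighted mean 1.0
    #: over the reference campaign); passive chambers heat most under strong sun.
    warming_season_scale: Mapping[str, float] = field(
        default_factory=lambda: {"autumn": 0.75, "winter": 0.45, "spring": 1.95}
    )
    #: Chamber effect on relative moisture at the thallus (% points).
    moisture_offset_diurnal: float = -4.75
    moisture_offset_nocturnal: float = 3.16

    #: Per-day rain probability by season.
    rain_event_rate: Mapping[str, float] = field(
        default_factory=lambda: {"autumn": 0.30, "winter": 0.30, "spring": 0.25}
    )
    #: Per-night probability of an early-morning dew wetting.
    dew_probability: float = 0.35
    #: Water status reached by a dew event (rain saturates to 1).
    dew_amplitude: float = 0.55
    #: Water status at or above which the thallus counts as hydrated.
    activation_fraction: float = 0.25
    #: e-folding drying time (hours) at the 15 degC reference temperature.
    drying_time_constant: float = 10.0
    #: Multiplicative shortening of the drying time per 10 degC warming.
    drying_q10: float = 3.5

    #: Seasonal mean lichen-surface temperature (degC).
    seasonal_temperature_means: Mapping[str, float] = field(
        default_factory=lambda: {"autumn": 12.0, "winter": 6.0, "spring": 17.0}
    )
    #: Peak-to-trough diel temperature swing (degC), max near 14:00.
    diel_amplitude: float = 12.0
    temperature_daily_sd: float = 2.5
    temperature_noise_sd: float = 0.6

    #: Clear-sky midday PAR by season (umol m-2 s-1).
    par_max_by_season: Mapping[str, float] = field(
        default_factory=lambda: {"autumn": 1200.0, "winter": 900.0, "spring": 1800.0}
    )
    #: Half-amplitude of the annual day-length cycle (hours) at the site latitude.
    day_length_amplitude: float = 2.9

    #: Dry-state baseline relative moisture (%) and its coupling to the
    #: (control-basis) temperature anomaly; wet steps pull toward moisture_wet.
    moisture_base: float = 30.0
    moisture_temp_coupling: float = 1.2
    moisture_wet: float = 92.0
    moisture_noise_sd: float = 2.0

    #: Persistent per-sensor (microcosm) offsets: microsite and probe bias.
    #: These are what the models' random intercepts absorb.
    sensor_temperature_sd: float = 0.1
    sensor_moisture_sd: float = 1.0
    sensor_fvfm_sd: float = 0.015

    #: Healthy dark-adapted PSII efficiency (Fv/Fm) of hydrated thalli.
    fvfm_healthy: float = 0.6
    #: Exponential decline rate of efficiency per unit PAR.
    yield_light_sensitivity: float = 7e-4
    #: Heat stress: efficiency intact at or below the onset temperature (degC),
    #: then suppressed by exp(-rate * excess).
    heat_stress_onset: float = 23.0
    heat_stress_rate: float = 1.0

    #: Fluorescence generation (instrument units).
    fm_wet_level: float = 800.0
    noise_sd_ft: float = 5.0
    noise_sd_fm: float = 20.0
    dry_floor_ft: float = 4.0
    dry_floor_fm: float = 25.0

    #: Documentation constant: saturation-pulse intensity (umol m-2 s-1, ~1 s).
    saturation_pulse_par: float = 4000.0

    #: Fraction of records dropped at random (sensor dropout); 0 = complete.
    dropout_rate: float = 0.0

    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` listing every offending field."""
        bad: list[str] = []
        if self.start_date > self.end_date:
            bad.append("start_date > end_date")
        if self.n_control < 0 or self.n_warming < 0:
            bad.append("n_control/n_warming must be >= 0")
        if self.records_per_day <= 0 or (24 * 60) % self.records_per_day:
            bad.append("records_per_day must divide 24 h evenly")
        if not 0.0 <= self.dew_probability <= 1.0:
            bad.append("dew_probability not in [0, 1]")
        if not 0.0 < self.fvfm_healthy < 1.0:
            bad.append("fvfm_healthy not in (0, 1)")
        for name in (
            "dew_amplitude", "activation_fraction", "drying_time_constant",
            "drying_q10", "diel_amplitude", "temperature_daily_sd",
            "temperature_noise_sd", "day_length_amplitude", "moisture_noise_sd",
            "yield_light_sensitivity", "heat_stress_rate", "fm_wet_level",
            "noise_sd_ft", "noise_sd_fm", "dry_floor_ft", "dry_floor_fm",
            "sensor_temperature_sd", "sensor_moisture_sd", "sensor_fvfm_sd",
        ):
            if getattr(self, name) < 0:
                bad.append(f"{name} must be >= 0")
        for name in ("rain_event_rate", "warming_season_scale",
                     "seasonal_temperature_means", "par_max_by_season"):
            mapping = getattr(self, name)
            if any(s not in mapping for s in ("autumn", "winter", "spring")):
                bad.append(f"{name} must cover autumn, winter and spring")
        if any(r < 0 or r > 1 for r in self.rain_event_rate.values()):
            bad.append("rain_event_rate values not in [0, 1]")
        if not 0.0 <= self.dropout_rate < 1.0:
            bad.append("dropout_rate not in [0, 1)")
        if bad:
            raise ConfigurationError("invalid SimConfig: " + "; ".join(bad))

    def with_(self, **kwargs) -> "SimConfig":
        """Copy with fields replaced."""
        return replace(self, **kwargs)

    @property
    def sensor_ids(self) -> list[str]:
        return [f"control_{i + 1}" for i in range(self.n_control)] + [
            f"warming_{i + 1}" for i in range(self.n_warming)
        ]


# fixed stream keys so parameter changes never shift the noise draws
_STREAM_WEATHER = 1
_STREAM_SENSOR = 100


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, key)])


def day_length_hours(dates, amplitude: float = 2.9) -> np.ndarray:
    """Smooth annual day-length cycle (hours) centred on 12 h.

    A sinusoid with the configured half-amplitude, zero-crossing at the
    March equinox; adequate for mid-latitude sites.
    """
    idx = pd.DatetimeIndex(pd.to_datetime(dates))
    doy = idx.dayofyear.to_numpy()
    return 12.0 + amplitude * np.sin(2.0 * math.pi * (doy - 80) / 365.25)


def _dawn_dusk(timestamps: pd.DatetimeIndex, config: SimConfig):
    length = day_length_hours(timestamps.normalize(), config.day_length_amplitude)
    dawn = 12.0 - length / 2.0
    dusk = 12.0 + length / 2.0
    return dawn, dusk, length


def _season_values(timestamps: pd.DatetimeIndex, mapping: Mapping[str, float],
                   rule: SeasonRule) -> np.ndarray:
    seasons = rule.assign_many(timestamps.normalize())
    return seasons.map(mapping).to_numpy(dtype=float)


def _day_index(timestamps: pd.DatetimeIndex, config: SimConfig) -> np.ndarray:
    start = pd.Timestamp(config.start_date)
    return ((timestamps.normalize() - start) // pd.Timedelta(days=1)).to_numpy()


@dataclass(frozen=True)
class WettingEvents:
    """Campaign wetting schedule: step indices and amplitudes on the grid."""

    steps: np.ndarray      # int indices into the campaign grid
    amplitudes: np.ndarray  # target water status at each event

    @property
    def n_events(self) -> int:
        return len(self.steps)


def simulate_par(
    timestamps: pd.DatetimeIndex,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    season_rule: SeasonRule | None = None,
) -> np.ndarray:
    """Incident PAR on the grid: zero at night, a sunlit hump by day.

    PAR is exactly 0 outside the (dawn, dusk) window given by the seasonal
    day-length cycle; within it, a sine-power hump peaking near solar noon
    at the seasonal clear-sky maximum, scaled by a shared daily cloudiness
    factor in [0.25, 1].
    """
    rng = rng if rng is not None else _rng(config.seed, _STREAM_WEATHER, 1)
    rule = season_rule or SeasonRule()
    hours = hour_of_day(timestamps)
    dawn, dusk, length = _dawn_dusk(timestamps, config)
    par_max = _season_values(timestamps, config.par_max_by_season, rule)

    day_idx = _day_index(timestamps, config)
    n_days = int(day_idx.max()) + 1 if len(day_idx) else 0
    cloud_by_day = 0.25 + 0.75 * rng.beta(4.0, 1.5, size=n_days)

    daylit = (hours > dawn) & (hours < dusk)
    phase = np.zeros_like(hours)
    phase[daylit] = (hours[daylit] - dawn[daylit]) / length[daylit]
    hump = np.where(daylit, np.sin(math.pi * phase) ** 1.3, 0.0)
    return par_max * hump * cloud_by_day[day_idx]


def draw_wetting_events(
    timestamps: pd.DatetimeIndex,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    season_rule: SeasonRule | None = None,
) -> WettingEvents:
    """Draw the shared rain and dew schedule for a campaign.

    Rain: at most one event per day with the seasonal probability, at a
    uniform time of day, saturating the water status.  Dew: per night with
    ``dew_probability``, about an hour before dawn, reaching only
    ``dew_amplitude`` (dew is a brief, sub-saturating wetting).
    A fixed number of draws is consumed per day, so the schedule is stable
    under changes to unrelated parameters.
    """
    rng = rng if rng is not None else _rng(config.seed, _STREAM_WEATHER, 2)
    rule = season_rule or SeasonRule()
    rpd = config.records_per_day
    dates = pd.date_range(config.start_date, config.end_date, freq="D")
    rain_p = rule.assign_many(dates).map(config.rain_event_rate).to_numpy(float)
    dawn = 12.0 - day_length_hours(dates, config.day_length_amplitude) / 2.0

    steps: list[int] = []
    amps: list[float] = []
    step_h = 24.0 / rpd
    for d in range(len(dates)):
        u_rain, u_rain_t, u_dew, u_dew_t = rng.random(4)
        if u_rain < rain_p[d]:
            steps.append(d * rpd + int(u_rain_t * rpd))
            amps.append(1.0)
        if u_dew < config.dew_probability:
            dew_hour = max(0.0, dawn[d] - 1.5 + u_dew_t)
            steps.append(d * rpd + min(rpd - 1, int(dew_hour / step_h)))
            amps.append(config.dew_amplitude)
    order = np.argsort(steps, kind="stable")
    return WettingEvents(
        steps=np.asarray(steps, dtype=int)[order],
        amplitudes=np.asarray(amps, dtype=float)[order],
    )


def simulate_microclimate(
    timestamps: pd.DatetimeIndex,
    treatment: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    *,
    par: np.ndarray | None = None,
    events: WettingEvents | None = None,
    season_rule: SeasonRule | None = None,
    shared: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lichen-surface temperature and relative moisture for one sensor.

    Temperature = seasonal mean + diel sinusoid (peak 14:00) + shared daily
    weather anomaly + sensor noise, plus the chamber offset for warming
    sensors (diurnal offset while PAR > 0, scaled by season; nocturnal
    offset otherwise).  Moisture sits at a dry baseline anti-coupled to the
    temperature anomaly, is pulled toward saturation in proportion to the
    latent water status implied by the wetting schedule, and carries the
    chamber moisture offsets for warming sensors.  Moisture is clipped to
    [0, 100].

    Returns ``(temperature, moisture)``.  ``shared`` may carry a
    precomputed dict of campaign-level fields (daily anomaly, events, PAR)
    so all sensors see the same weather.
    """
    rng = rng if rng is not None else _rng(config.seed, _STREAM_SENSOR, 0)
    rule = season_rule or SeasonRule()
    n = len(timestamps)
    hours = hour_of_day(timestamps)
    day_idx = _day_index(timestamps, config)
    n_days = int(day_idx.max()) + 1 if n else 0

    if shared is None:
        shared = {}
    if "daily_anomaly" not in shared:
        wrng = _rng(config.seed, _STREAM_WEATHER, 3)
        shared["daily_anomaly"] = wrng.normal(0.0, 1.0, size=n_days)
    if par is None:
        par = shared.get("par")
        if par is None:
            par = simulate_par(timestamps, config, season_rule=rule)
            shared["par"] = par
    if events is None:
        events = shared.get("events")
        if events is None:
            events = draw_wetting_events(timestamps, config, season_rule=rule)
            shared["events"] = events

    season_mean = _season_values(timestamps, config.seasonal_temperature_means, rule)
    diel = (config.diel_amplitude / 2.0) * np.cos(2.0 * math.pi * (hours - 14.0) / 24.0)
    anomaly = diel + config.temperature_daily_sd * shared["daily_anomaly"][day_idx]
    off_t, off_m = rng.normal(0.0, 1.0, size=2)
    noise_t, noise_m = rng.normal(0.0, 1.0, size=(2, n))
    temperature = (
        season_mean + anomaly + config.temperature_noise_sd * noise_t
        + config.sensor_temperature_sd * off_t
    )

    daylit = par > 0
    if treatment == "warming":
        scale = _season_values(timestamps, config.warming_season_scale, rule)
        temperature = temperature + np.where(
            daylit,
            config.warming_offset_diurnal * scale,
            config.warming_offset_nocturnal,
        )
    elif treatment != "control":
        raise ConfigurationError(f"unknown treatment {treatment!r}")

    # latent water status from the shared schedule and this sensor's temperature
    water = _water_status(temperature, events, config, n)
    dry = config.moisture_base - config.moisture_temp_coupling * anomaly
    moisture = dry + (config.moisture_wet - dry) * water
    if treatment == "warming":
        moisture = moisture + np.where(
            daylit, config.moisture_offset_diurnal, config.moisture_offset_nocturnal
        )
    moisture = (
        moisture + config.moisture_noise_sd * noise_m
        + config.sensor_moisture_sd * off_m
    )
    return temperature, np.clip(moisture, 0.0, 100.0)


def _water_status(
    temperature: np.ndarray, events: WettingEvents, config: SimConfig, n: int
) -> np.ndarray:
    """Exponential-drying latent water status on the grid (0..1)."""
    step_h = 24.0 / config.records_per_day
    boost = np.zeros(n)
    boost[events.steps] = np.maximum(boost[events.steps], events.amplitudes)
    tau_ref = max(config.drying_time_constant, 1e-9)
    # drying time constant shortens with temperature (Q10-style)
    decay = np.exp(
        -step_h / (tau_ref * config.drying_q10 ** (-(temperature - 15.0) / 10.0))
    )
    water = np.empty(n)
    w = 0.0
    for i in range(n):
        w = max(w, boost[i])
        water[i] = w
        w *= decay[i]
    return water


def simulate_hydration(
    moisture: np.ndarray,
    temperature: np.ndarray,
    events: WettingEvents,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Latent hydration state of one thallus.

    Water status jumps to the event amplitude (1 for rain, partial for
    dew) and decays exponentially between events; the e-folding time is
    ``drying_time_constant`` hours at 15 degC, divided by
    ``drying_q10 ** (dT / 10)`` — warmer thalli dry faster, the
    evapotranspiration mechanism by which daytime chamber warming cuts
    hydrated time.  ``is_wet`` marks water status at or above
    ``activation_fraction``.  The moisture trace is accepted for grid
    alignment; the dynamics are driven by the event schedule and
    temperature.
    """
    if len(moisture) != len(temperature):
        raise ValueError("moisture and temperature traces must share the grid")
    water = _water_status(np.asarray(temperature, float), events, config, len(temperature))
    return pd.DataFrame(
        {"water_status": water, "is_wet": water >= config.activation_fraction}
    )


def simulate_fluorescence(
    hydration: pd.DataFrame,
    par: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Raw Ft / Fm traces plus the noise-free target efficiency.

    Hydrated steps: Fm is the wet-thallus level plus Gaussian pulse noise;
    the target PSII efficiency equals ``fvfm_healthy`` in darkness,
    declines exponentially with PAR, and is suppressed above the heat
    stress onset; Ft is back-computed as Fm * (1 - efficiency) plus
    measuring-light noise.  Dry steps emit floor readings strictly below
    the instrument noise thresholds (10 for Ft, 50 for Fm), so the
    downstream noise filter classifies them as inactive.
    """
    rng = rng if rng is not None else _rng(config.seed, _STREAM_SENSOR, 99)
    n = len(hydration)
    if len(par) != n:
        raise ValueError("hydration and PAR traces must share the grid")
    eps_fm, eps_ft, u_dry_ft, u_dry_fm = rng.normal(0.0, 1.0, size=(4, n))

    temperature = hydration["temperature"].to_numpy() if "temperature" in hydration else None
    eff = config.fvfm_healthy * np.exp(-config.yield_light_sensitivity * np.asarray(par))
    if temperature is not None:
        excess = np.maximum(0.0, temperature - config.heat_stress_onset)
        eff = eff * np.exp(-config.heat_stress_rate * excess)

    wet = hydration["is_wet"].to_numpy(bool)
    fm_wet = config.fm_wet_level + config.noise_sd_fm * eps_fm
    fm_wet = np.maximum(fm_wet, 51.0)  # a hydrated pulse always clears the noise floor
    ft_wet = np.maximum(0.0, fm_wet * (1.0 - eff) + config.noise_sd_ft * eps_ft)

    ft_dry = np.clip(config.dry_floor_ft * (1.0 + 0.3 * u_dry_ft), 0.0, 9.9)
    fm_dry = np.clip(config.dry_floor_fm * (1.0 + 0.3 * u_dry_fm), 0.0, 49.5)

    return pd.DataFrame(
        {
            "ft": np.where(wet, ft_wet, ft_dry),
            "fm": np.where(wet, fm_wet, fm_dry),
            "true_efficiency": np.where(wet, eff, 0.0),
        }
    )


def simulate_campaign(
    config: SimConfig | None = None,
    *,
    season_rule: SeasonRule | None = None,
    return_truth: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one full monitoring campaign.

    Weather (PAR, daily temperature anomaly, wetting schedule) is shared by
    all sensors; each sensor adds its own measurement noise and, for the
    warming group, the chamber offsets.  Deterministic given the config
    seed.  With the default config: 6 sensors x 247 days x 48 records =
    71,136 rows.

    Returns the monitoring table, plus a truth table (latent water status,
    hydration flag, noise-free efficiency per row) when ``return_truth``.
    """
    config = config or SimConfig()
    config.validate()
    rule = season_rule or SeasonRule()
    timestamps = campaign_grid(config.start_date, config.end_date, config.records_per_day)
    shared: dict = {}
    shared["par"] = simulate_par(timestamps, config, season_rule=rule)
    shared["events"] = draw_wetting_events(timestamps, config, season_rule=rule)

    frames = []
    truths = []
    for k, sensor in enumerate(config.sensor_ids):
        treatment = "control" if sensor.startswith("control") else "warming"
        srng = _rng(config.seed, _STREAM_SENSOR, k, 0)
        temperature, moisture = simulate_microclimate(
            timestamps, treatment, config, srng, shared=shared, season_rule=rule
        )
        hydration = simulate_hydration(
            moisture, temperature, shared["events"], config
        )
        hydration = hydration.assign(temperature=temperature)
        orng = _rng(config.seed, _STREAM_SENSOR, k, 3)
        fvfm_k = float(
            np.clip(
                config.fvfm_healthy + config.sensor_fvfm_sd * orng.normal(),
                0.05, 0.95,
            )
        )
        frng = _rng(config.seed, _STREAM_SENSOR, k, 1)
        fluor = simulate_fluorescence(
            hydration, shared["par"], config.with_(fvfm_healthy=fvfm_k), frng
        )
        frame = pd.DataFrame(
            {
                "timestamp": timestamps,
                "sensor_id": sensor,
                "treatment": treatment,
                "temperature_c": temperature,
                "moisture_pct": moisture,
                "par": shared["par"],
                "ft": fluor["ft"].to_numpy(),
                "fm": fluor["fm"].to_numpy(),
            }
        )
        if config.dropout_rate > 0.0:
            drng = _rng(config.seed, _STREAM_SENSOR, k, 2)
            keep = drng.random(len(frame)) >= config.dropout_rate
            frame = frame[keep].reset_index(drop=True)
            hydration = hydration[keep].reset_index(drop=True)
            fluor = fluor[keep].reset_index(drop=True)
        frames.append(frame)
        truths.append(
            pd.DataFrame(
                {
                    "timestamp": frame["timestamp"].to_numpy(),
                    "sensor_id": sensor,
                    "water_status": hydration["water_status"].to_numpy(),
                    "is_wet": hydration["is_wet"].to_numpy(),
                    "true_efficiency": fluor["true_efficiency"].to_numpy(),
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    if return_truth:
        return records, pd.concat(truths, ignore_index=True)
    return records
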