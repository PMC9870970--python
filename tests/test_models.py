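"""Mixed-model estimation: oracle equivalences, recovery, contrasts."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from crustpam.glmm import fit_binomial_glmm_arrays
from crustpam.models import (
    ModelSpec,
    compact_letter_display,
    fit_activity_microclimate_glmm,
    fit_binomial_glmm,
    fit_cell_means,
    fit_lmm,
    tukey_contrasts,
)


def _gaussian_data(effect=0.0, group_sd=0.0, seed=0, n_groups=6, n_per=40):
    rng = np.random.default_rng(seed)
    groups = np.repeat([f"s{i}" for i in range(n_groups)], n_per)
    treat = np.repeat(
        ["control"] * (n_groups // 2) + ["warming"] * (n_groups - n_groups // 2),
        n_per,
    )
    u = rng.normal(0.0, group_sd, n_groups)[
        np.repeat(np.arange(n_groups), n_per)
    ]
    y = 10.0 + effect * (treat == "warming") + u + rng.normal(0.0, 1.0, len(u))
    return pd.DataFrame(
        {"sensor_id": groups, "treatment": treat, "response": y,
         "period": "diurnal"}
    )


def test_lmm_matches_ols_without_group_variance():
    df = _gaussian_data(effect=1.5, group_sd=0.0, seed=3)
    res = fit_lmm(df, ModelSpec("response", "gaussian", fixed="treatment"))
    X = sm.add_constant((df["treatment"] == "warming").astype(float))
    ols = sm.OLS(df["response"], X).fit()
    assert res.coefficients["estimate"].to_numpy() == pytest.approx(
        np.asarray(ols.params), abs=1e-4
    )


def test_lmm_recovers_injected_treatment_effect():
    df = _gaussian_data(effect=2.0, group_sd=0.2, seed=7, n_groups=20, n_per=25)
    res = fit_lmm(df, ModelSpec("response", "gaussian", fixed="treatment"))
    est = res.coefficients.set_index("term")["estimate"]
    assert est.filter(like="warming").iloc[0] == pytest.approx(2.0, abs=0.3)


def test_lmm_constant_response_zero_slopes():
    df = _gaussian_data(seed=1)
    df["response"] = 5.0
    res = fit_lmm(df, ModelSpec("response", "gaussian", fixed="treatment"))
    est = res.coefficients.set_index("term")["estimate"]
    assert est["Intercept"] == pytest.approx(5.0, abs=1e-8)
    assert est.drop("Intercept").to_numpy() == pytest.approx(0.0, abs=1e-8)
    assert "singular random variance" in res.flags


def _binomial_data(effect=0.0, group_sd=0.0, seed=0, n_groups=10, n_per=20, m=24):
    rng = np.random.default_rng(seed)
    idx = np.repeat(np.arange(n_groups), n_per)
    treat = (idx >= n_groups // 2).astype(float)
    u = rng.normal(0.0, group_sd, n_groups)[idx]
    p = expit(-0.4 + effect * treat + u)
    y = rng.binomial(m, p)
    return pd.DataFrame(
        {
            "sensor_id": [f"s{i}" for i in idx],
            "treatment": np.where(treat > 0, "warming", "control"),
            "n_active": y,
            "n_records": m,
            "period": "diurnal",
        }
    )


def test_glmm_matches_glm_without_group_variance():
    df = _binomial_data(effect=-0.8, group_sd=0.0, seed=11)
    res = fit_binomial_glmm(
        df, ModelSpec(("n_active", "n_records"), "binomial", fixed="treatment")
    )
    X = sm.add_constant((df["treatment"] == "warming").astype(float))
    glm = sm.GLM(
        np.column_stack([df["n_active"], df["n_records"] - df["n_active"]]),
        X,
        family=sm.families.Binomial(),
    ).fit()
    assert res.coefficients["estimate"].to_numpy() == pytest.approx(
        np.asarray(glm.params), abs=1e-4
    )
    assert res.random_intercept_var < 1e-6
    assert res.loglik == pytest.approx(glm.llf, abs=1e-3)


def test_glmm_agrees_with_lme4(tmp_path):
    """Independent oracle: R lme4::glmer with adaptive quadrature."""
    rng = np.random.default_rng(17)
    G, nper, m = 12, 20, 30
    idx = np.repeat(np.arange(G), nper)
    x = rng.normal(size=G * nper)
    u = rng.normal(0.0, 0.6, G)[idx]
    y = rng.binomial(m, expit(-0.3 + 0.5 * x + u))
    df = pd.DataFrame({"y": y, "m": m, "x": x, "g": idx})
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = textwrap.dedent(
        f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        f <- glmer(cbind(y, m - y) ~ x + (1 | g), data = d,
                   family = binomial, nAGQ = 15)
        cat(fixef(f), sqrt(unlist(VarCorr(f))), sep = "\\n")
        """
    )
    out = subprocess.run(
        ["Rscript", "-"], input=script, capture_output=True, text=True, check=True
    )
    r_int, r_x, r_sigma = map(float, out.stdout.strip().splitlines())

    X = np.column_stack([np.ones_like(x), x])
    res = fit_binomial_glmm_arrays(
        y.astype(float), np.full(len(y), float(m)), X, idx, ["Intercept", "x"]
    )
    assert res.beta[0] == pytest.approx(r_int, abs=2e-3)
    assert res.beta[1] == pytest.approx(r_x, abs=2e-3)
    assert res.sigma == pytest.approx(r_sigma, abs=5e-3)


def test_glmm_recovers_negative_logit_effect():
    df = _binomial_data(effect=-1.0, group_sd=0.3, seed=23, n_groups=30, n_per=40)
    res = fit_binomial_glmm(
        df, ModelSpec(("n_active", "n_records"), "binomial", fixed="treatment")
    )
    est = res.coefficients.set_index("term")["estimate"]
    assert est.filter(like="warming").iloc[0] == pytest.approx(-1.0, abs=0.2)


def test_glmm_all_success_flagged_not_crashed():
    df = _binomial_data(seed=2)
    df["n_active"] = df["n_records"]
    res = fit_binomial_glmm(
        df, ModelSpec(("n_active", "n_records"), "binomial", fixed="treatment")
    )
    assert res.flags  # separation / degenerate fit is reported
    assert np.all(np.isfinite(res.coefficients["estimate"]))


def _climate_summaries(slope_t=-0.3, slope_m=0.15, interaction=0.0, seed=5):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(8):
        treat = "warming" if g >= 4 else "control"
        for _ in range(60):
            t = rng.uniform(5.0, 30.0)
            moist = rng.uniform(10.0, 90.0)
            eta = (
                2.0
                + (slope_t + (interaction if treat == "warming" else 0.0)) * t
                + slope_m * (moist - 50.0)
                + rng.normal(0.0, 0.2)
            )
            n = 24
            rows.append(
                {
                    "sensor_id": f"s{g}",
                    "treatment": treat,
                    "season": "spring",
                    "period": "diurnal",
                    "mean_temperature": t,
                    "mean_moisture": moist,
                    "n_active": rng.binomial(n, expit(eta)),
                    "n_records": n,
                }
            )
    return pd.DataFrame(rows)


def test_microclimate_glmm_sign_recovery():
    df = _climate_summaries()
    scope = {"season": "spring", "period": "diurnal"}
    res_t = fit_activity_microclimate_glmm(df, "mean_temperature", scope)
    assert res_t.coefficients["estimate"].iloc[1] < 0.0
    res_m = fit_activity_microclimate_glmm(df, "mean_moisture", scope)
    assert res_m.coefficients["estimate"].iloc[1] > 0.0


def test_microclimate_glmm_null_interaction():
    df = _climate_summaries(interaction=0.0, seed=9)
    res = fit_activity_microclimate_glmm(
        df, "mean_temperature", {"season": "spring", "period": "diurnal"}
    )
    inter = res.coefficients.iloc[2]
    assert abs(inter["estimate"]) < 3.0 * inter["se"] + 0.02


def test_microclimate_glmm_requires_full_scope():
    with pytest.raises(ValueError):
        fit_activity_microclimate_glmm(
            _climate_summaries(), "mean_temperature", {"season": "spring"}
        )


def _cells_data(offsets, seed=0, n_per=50, group_sd=0.2):
    rng = np.random.default_rng(seed)
    rows = []
    g = 0
    for (treat, season), off in offsets.items():
        for _ in range(2):  # two sensors per cell
            u = rng.normal(0.0, group_sd)
            rows += [
                {
                    "sensor_id": f"s{g}",
                    "treatment": treat,
                    "season": season,
                    "period": "diurnal",
                    "response": 10.0 + off + u + rng.normal(0.0, 1.0),
                }
                for _ in range(n_per)
            ]
            g += 1
    return pd.DataFrame(rows)


def test_tukey_identical_groups_share_letter():
    df = _cells_data({("control", "autumn"): 0.0, ("warming", "autumn"): 0.0}, seed=31)
    result, cells = fit_cell_means(
        df, ModelSpec("response", "gaussian"), ("treatment", "season")
    )
    table = tukey_contrasts(result, cells)
    assert table["p_adjusted"].iloc[0] > 0.2
    assert result.letters["control:autumn"] == result.letters["warming:autumn"]


def test_tukey_two_levels_adjusted_equals_raw():
    df = _cells_data({("control", "autumn"): 0.0, ("warming", "autumn"): 1.0}, seed=33)
    result, cells = fit_cell_means(
        df, ModelSpec("response", "gaussian"), ("treatment", "season")
    )
    table = tukey_contrasts(result, cells)
    assert len(table) == 1
    assert table["p_adjusted"].iloc[0] == pytest.approx(
        table["p_value"].iloc[0], abs=5e-3
    )


def test_tukey_adjusted_at_least_raw_and_letters_separate():
    offsets = {
        ("control", "autumn"): 0.0,
        ("control", "spring"): 0.1,
        ("warming", "autumn"): 2.0,
        ("warming", "spring"): 6.0,
    }
    df = _cells_data(offsets, seed=35)
    result, cells = fit_cell_means(
        df, ModelSpec("response", "gaussian"), ("treatment", "season")
    )
    table = tukey_contrasts(result, cells)
    assert (table["p_adjusted"] >= table["p_value"] - 1e-12).all()
    assert (table["p_adjusted"] <= 1.0).all()
    # clearly separated cells do not share letters
    assert not set(result.letters["control:autumn"]) & set(
        result.letters["warming:spring"]
    )


def test_compact_letter_display_blocks():
    names = ["a", "b", "c"]
    # a != c significant; a-b and b-c not
    pair_p = {(0, 1): 0.30, (0, 2): 0.01, (1, 2): 0.40}
    letters = compact_letter_display(names, pair_p)
    assert set(letters["a"]) & set(letters["b"])
    assert set(letters["b"]) & set(letters["c"])
    assert not set(letters["a"]) & set(letters["c"])
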