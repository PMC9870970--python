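"""Mixed-effects inference on daily summaries.

The repeated-measures design has six microcosms (the random-effect
grouping; one sensor each) observed daily over three seasons.  Three model
families cover the analyses:

- Gaussian LMMs (random intercept per microcosm) for daily-averaged
  microclimate and efficiency responses, with treatment, season and their
  interaction as fixed factors;
- binomial GLMMs on (active, total) daily record counts — the % activity
  with its known denominator — with a logit link and the same random
  structure;
- per season x period binomial GLMMs linking activity to one microclimate
  covariate and its interaction with treatment (the acclimation test),
  whose coefficient table is Intercept / covariate / covariate x treatment.

Post-hoc pairwise comparisons of treatment x season cell means use
single-step multiplicity adjustment over the fitted contrast covariance
(Tukey-style max-|z|), with a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import dmatrix

from .glmm import fit_binomial_glmm_arrays

__all__ = [
    "ModelSpec",
    "ModelResult",
    "fit_lmm",
    "fit_binomial_glmm",
    "fit_activity_microclimate_glmm",
    "tukey_contrasts",
]


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, family, fixed effects, grouping and scope.

    ``response`` is a DailySummary column for gaussian models or the
    ``(successes, trials)`` column pair for binomial models.  ``fixed`` is
    a patsy right-hand-side formula over ``treatment``, ``season`` and
    optionally one microclimate covariate.  ``scope`` filters summaries by
    column value before fitting, e.g. ``{"period": "diurnal"}``.
    """

    response: str | tuple[str, str]
    family: str = "gaussian"  # or "binomial"
    fixed: str = "treatment * season"
    group: str = "sensor_id"
    scope: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")
        if self.family == "binomial" and not (
            isinstance(self.response, tuple) and len(self.response) == 2
        ):
            raise ValueError(
                "binomial family needs a (successes, trials) response pair"
            )


@dataclass
class ModelResult:
    """Fitted mixed model: coefficients, variance component, diagnostics."""

    coefficients: pd.DataFrame   # term, estimate, se, statistic, p_value
    random_intercept_var: float
    converged: bool
    loglik: float
    n_obs: int
    n_groups: int
    family: str
    flags: list[str] = field(default_factory=list)
    #: fixed-effects covariance (for contrasts)
    cov_fixed: np.ndarray | None = None
    #: populated by :func:`tukey_contrasts`
    contrasts: pd.DataFrame | None = None
    letters: dict | None = None


def _apply_scope(summaries: pd.DataFrame, scope: dict) -> pd.DataFrame:
    df = summaries
    for col, value in scope.items():
        df = df[df[col] == value]
    if len(df) == 0:
        raise ValueError(f"scope {scope} selects no rows")
    return df.reset_index(drop=True)


def fit_lmm(summaries: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Gaussian random-intercept LMM (maximum likelihood).

    Rows with a missing response are dropped.  Non-convergence or a
    singular (boundary-zero) random variance is flagged, never silent.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_lmm requires a gaussian spec")
    df = _apply_scope(summaries, spec.scope).dropna(subset=[spec.response])
    formula = f"{spec.response} ~ {spec.fixed}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df[spec.group])
        try:
            res = model.fit(reml=False, method=["lbfgs", "bfgs", "cg"])
        except (np.linalg.LinAlgError, ValueError):
            res = None
    flags: list[str] = []
    names = model.exog_names
    k = len(names)
    loglik = np.nan
    converged = True
    boundary = res is None
    if res is not None:
        estimates = res.fe_params.to_numpy(float)
        cov = np.asarray(res.cov_params())[:k, :k]
        converged = bool(getattr(res, "converged", True))
        if not converged:
            flags.append("non-convergence")
        re_var = float(np.asarray(res.cov_re).ravel()[0])
        loglik = float(res.llf)
        boundary = (
            re_var < 1e-7 * max(res.scale, 1e-12)
            or not np.all(np.isfinite(cov))
            or np.any(np.diag(cov) <= 0)
        )
    if boundary:
        # at a boundary (zero) random variance the profiled information is
        # singular and the optimizer's GLS step is unreliable; the exact ML
        # solution there is ordinary least squares
        flags.append("singular random variance")
        ols = sm.OLS(
            np.asarray(model.endog, float), np.asarray(model.exog, float)
        ).fit()
        estimates = np.asarray(ols.params)
        cov = np.asarray(ols.cov_params())
        re_var = 0.0
        loglik = float(ols.llf) if np.isnan(loglik) else loglik
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = estimates / se
    table = pd.DataFrame(
        {
            "term": names,
            "estimate": estimates,
            "se": se,
            "statistic": z,
            "p_value": 2.0 * special.ndtr(-np.abs(z)),
        }
    )
    return ModelResult(
        coefficients=table,
        random_intercept_var=re_var,
        converged=converged,
        loglik=loglik,
        n_obs=len(df),
        n_groups=df[spec.group].nunique(),
        family="gaussian",
        flags=flags,
        cov_fixed=cov,
    )


def fit_binomial_glmm(summaries: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Random-intercept binomial GLMM on success/trial counts (logit link).

    The response is the count pair, not the percentage: a percentage with
    a known denominator is binomial information and modelling the counts
    keeps that weighting.  Estimated by adaptive Gauss-Hermite quadrature
    (see :mod:`crustpam.glmm`); complete separation and non-convergence
    are flagged on the result.
    """
    if spec.family != "binomial":
        raise ValueError("fit_binomial_glmm requires a binomial spec")
    df = _apply_scope(summaries, spec.scope)
    succ_col, trial_col = spec.response
    df = df.dropna(subset=[succ_col, trial_col])
    X = dmatrix(spec.fixed, df, return_type="dataframe")
    res = fit_binomial_glmm_arrays(
        df[succ_col].to_numpy(float),
        df[trial_col].to_numpy(float),
        X.to_numpy(float),
        df[spec.group].to_numpy(),
        term_names=list(X.columns),
    )
    return ModelResult(
        coefficients=res.params,
        random_intercept_var=res.random_intercept_var,
        converged=res.converged,
        loglik=res.loglik,
        n_obs=res.n_obs,
        n_groups=res.n_groups,
        family="binomial",
        flags=list(res.flags),
        cov_fixed=res.cov_fixed,
    )


def fit_activity_microclimate_glmm(
    summaries: pd.DataFrame,
    climate_var: str,
    scope: dict,
    group: str = "sensor_id",
) -> ModelResult:
    """Activity ~ microclimate GLMM for one season x period.

    ``climate_var`` is ``"mean_temperature"`` or ``"mean_moisture"`` (the
    daily per-sensor averages).  The fixed part is Intercept + covariate +
    covariate x treatment — the interaction asks whether warming-grown
    thalli respond to microclimate differently (acclimation); the model
    set in the source design is one per season x period combination.
    """
    if not {"season", "period"} <= set(scope):
        raise ValueError("scope must select one season and one period")
    spec = ModelSpec(
        response=("n_active", "n_records"),
        family="binomial",
        fixed=f"{climate_var} + {climate_var}:C(treatment, Treatment('control'))",
        group=group,
        scope=scope,
    )
    return fit_binomial_glmm(summaries, spec)


def fit_cell_means(
    summaries: pd.DataFrame,
    spec: ModelSpec,
    factors: tuple[str, str] = ("treatment", "season"),
) -> tuple[ModelResult, list[str]]:
    """Refit a spec with cell-means coding of an interaction factor.

    Returns the fitted result (one coefficient per factor-level
    combination, no intercept) and the cell labels, for use by
    :func:`tukey_contrasts`.
    """
    df = _apply_scope(summaries, spec.scope).copy()
    df["_cell"] = df[factors[0]].astype(str) + ":" + df[factors[1]].astype(str)
    cells = sorted(df["_cell"].unique())
    cell_spec = ModelSpec(
        response=spec.response,
        family=spec.family,
        fixed="0 + C(_cell)",
        group=spec.group,
        scope={},
    )
    if spec.family == "gaussian":
        result = fit_lmm(df, cell_spec)
    else:
        result = fit_binomial_glmm(df, cell_spec)
    result.coefficients["term"] = cells + list(
        result.coefficients["term"][len(cells):]
    )
    return result, cells


def tukey_contrasts(
    result: ModelResult,
    levels: list[str] | None = None,
    *,
    adjustment: str = "single-step",
    alpha: float = 0.05,
    n_mc: int = 200_000,
    mc_seed: int = 20160921,
) -> pd.DataFrame:
    """All pairwise comparisons of cell means with multiplicity adjustment.

    ``result`` must come from a cell-means fit (:func:`fit_cell_means`):
    every coefficient is one factor-level mean and ``cov_fixed`` its
    covariance.  The default ``single-step`` adjustment references the
    max-|z| distribution of the full contrast vector under its fitted
    multivariate-normal covariance (the Tukey-contrast construction for
    mixed models), evaluated by a fixed-seed Monte-Carlo sample so results
    are reproducible; ``holm`` is a covariance-free fallback.

    Populates ``result.contrasts`` and ``result.letters`` (compact letter
    display at ``alpha``: levels sharing a letter are not significantly
    different) and returns the contrast table.
    """
    est = result.coefficients["estimate"].to_numpy()
    names = levels if levels is not None else list(result.coefficients["term"])
    V = result.cov_fixed
    if V is None:
        raise ValueError("result carries no fixed-effects covariance")
    k = len(names)
    pairs = list(combinations(range(k), 2))
    L = np.zeros((len(pairs), k))
    for r, (i, j) in enumerate(pairs):
        L[r, i], L[r, j] = 1.0, -1.0
    diff = L @ est[:k]
    C = L @ V[:k, :k] @ L.T
    se = np.sqrt(np.clip(np.diag(C), 1e-300, None))
    z = diff / se
    raw = 2.0 * special.ndtr(-np.abs(z))

    if adjustment == "single-step":
        R = C / np.outer(se, se)
        evals, evecs = np.linalg.eigh((R + R.T) / 2.0)
        A = evecs * np.sqrt(np.clip(evals, 0.0, None))
        rng = np.random.default_rng(mc_seed)
        maxabs = np.abs(
            rng.standard_normal((n_mc, A.shape[1])) @ A.T
        ).max(axis=1)
        adj = np.array([(maxabs >= abs(zj)).mean() for zj in z])
        adj = np.maximum(adj, raw)
    elif adjustment == "holm":
        order = np.argsort(raw)
        adj = np.empty_like(raw)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (len(raw) - rank) * raw[idx])
            adj[idx] = min(1.0, running)
        adj = np.maximum(adj, raw)
    else:
        raise ValueError("adjustment must be 'single-step' or 'holm'")

    table = pd.DataFrame(
        {
            "contrast": [f"{names[i]} - {names[j]}" for i, j in pairs],
            "estimate": diff,
            "se": se,
            "statistic": z,
            "p_value": raw,
            "p_adjusted": adj,
        }
    )
    result.contrasts = table
    result.letters = compact_letter_display(
        names, {(i, j): adj[r] for r, (i, j) in enumerate(pairs)}, alpha
    )
    return table


def compact_letter_display(
    names: list[str], pair_p: dict, alpha: float = 0.05
) -> dict:
    """Insert-and-absorb compact letter display.

    Levels that are *not* significantly different share at least one
    letter; significantly different levels share none.
    """
    k = len(names)
    columns: list[set] = [set(range(k))]
    for (i, j), p in sorted(pair_p.items()):
        if p >= alpha:
            continue
        new_cols: list[set] = []
        for col in columns:
            if i in col and j in col:
                new_cols.extend([col - {i}, col - {j}])
            else:
                new_cols.append(col)
        # absorb: drop columns contained in another
        columns = [
            c
            for idx, c in enumerate(new_cols)
            if c and not any(
                c < other or (c == other and idx2 < idx)
                for idx2, other in enumerate(new_cols)
            )
        ]
    columns.sort(key=lambda c: (min(c), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in names}
    for pos, col in enumerate(columns):
        for i in sorted(col):
            letters[names[i]] += alphabet[pos % 26]
    return letters
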