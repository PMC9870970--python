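"""Maximum-likelihood binomial GLMM with a single random intercept.

Model: for observation i in group g,

    y_i ~ Binomial(m_i, p_i),   logit(p_i) = x_i' beta + u_g,
    u_g ~ N(0, sigma^2) iid across groups.

The marginal log-likelihood integrates the random intercept out per group
with adaptive Gauss-Hermite quadrature: each group's integrand is centred
at its posterior mode (found by Newton's method) and scaled by the
curvature there, which keeps the quadrature accurate even for the sharply
peaked integrands produced by many binomial trials per group.  At
sigma = 0 the integral collapses to the ordinary binomial GLM likelihood,
so the fit reduces exactly to a GLM when the data carry no between-group
variance.

Estimation maximises over (beta, sigma) with L-BFGS-B (sigma bounded at
zero); standard errors come from the numerical Hessian of the negative
log-likelihood at the optimum.  Wald statistics are normal-reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.tools.numdiff import approx_hess1

__all__ = ["BinomialGLMMResult", "fit_binomial_glmm_arrays"]

_GH_NODES = 15


@dataclass
class BinomialGLMMResult:
    """Fitted random-intercept binomial GLMM."""

    params: pd.DataFrame          # term, estimate, se, statistic, p_value
    sigma: float                  # random-intercept SD
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    flags: list[str] = field(default_factory=list)
    cov_fixed: np.ndarray | None = None

    @property
    def random_intercept_var(self) -> float:
        return self.sigma**2

    @property
    def beta(self) -> np.ndarray:
        return self.params["estimate"].to_numpy()


def _group_loglik(eta_base, sigma, y, m, nodes, weights):
    """Adaptive-GH log integral for one group; eta_base = X beta."""
    # posterior mode of u via Newton (concave in u)
    u = 0.0
    for _ in range(50):
        eta = eta_base + sigma * u
        p = special.expit(eta)
        g = sigma * np.sum(y - m * p) - u
        h = -(sigma**2) * np.sum(m * p * (1 - p)) - 1.0
        step = g / h
        u_new = u - step
        if abs(u_new - u) < 1e-10:
            u = u_new
            break
        u = u_new
    eta = eta_base + sigma * u
    p = special.expit(eta)
    h = (sigma**2) * np.sum(m * p * (1 - p)) + 1.0  # -d2/du2
    s = 1.0 / np.sqrt(h)

    t = u + np.sqrt(2.0) * s * nodes  # quadrature points in u
    eta_k = eta_base[:, None] + sigma * t[None, :]
    # binomial log-density without the constant term, plus N(0,1) log prior
    ll_k = np.sum(
        y[:, None] * eta_k - m[:, None] * np.logaddexp(0.0, eta_k), axis=0
    ) - 0.5 * t**2
    log_terms = np.log(weights) + nodes**2 + ll_k
    return (
        np.log(np.sqrt(2.0) * s)
        + special.logsumexp(log_terms)
        - 0.5 * np.log(2.0 * np.pi)
    )


def _marginal_loglik(theta, X, y, m, group_slices, nodes, weights):
    beta, sigma = theta[:-1], abs(theta[-1])
    eta = X @ beta
    total = 0.0
    for sl in group_slices:
        total += _group_loglik(eta[sl], sigma, y[sl], m[sl], nodes, weights)
    return total


def fit_binomial_glmm_arrays(
    y: np.ndarray,
    m: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    term_names: list[str] | None = None,
    *,
    start: np.ndarray | None = None,
    tol: float = 1e-9,
) -> BinomialGLMMResult:
    """Fit the random-intercept binomial GLMM on design arrays.

    Parameters
    ----------
    y, m
        Success and trial counts per observation (0 <= y <= m).
    X
        Fixed-effects design matrix, one column per term.
    groups
        Group labels (any hashable); one random intercept per group.
    """
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(y < 0) or np.any(y > m):
        raise ValueError("need 0 <= successes <= trials for every row")
    codes, _ = pd.factorize(np.asarray(groups))
    order = np.argsort(codes, kind="stable")
    y, m, X, codes = y[order], m[order], X[order], codes[order]
    bounds_idx = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate([[0], bounds_idx, [len(codes)]])
    group_slices = [slice(a, b) for a, b in zip(starts[:-1], starts[1:])]
    n_groups = len(group_slices)
    p = X.shape[1]
    term_names = term_names or [f"x{j}" for j in range(p)]

    nodes, weights = np.polynomial.hermite.hermgauss(_GH_NODES)

    flags: list[str] = []
    if start is None:
        # GLM warm start
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                glm = sm.GLM(
                    np.column_stack([y, m - y]), X, family=sm.families.Binomial()
                ).fit()
                beta0 = np.asarray(glm.params)
            except Exception:
                beta0 = np.zeros(p)
        if not np.all(np.isfinite(beta0)) or np.any(np.abs(beta0) > 12):
            flags.append("separation")
            beta0 = np.clip(np.nan_to_num(beta0), -12, 12)
        start = np.concatenate([beta0, [0.5]])

    def nll(theta):
        val = _marginal_loglik(theta, X, y, m, group_slices, nodes, weights)
        return -val if np.isfinite(val) else 1e12

    res = optimize.minimize(
        nll,
        start,
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [(0.0, None)],
        options={"maxiter": 500, "ftol": tol, "gtol": 1e-8},
    )
    theta = res.x
    beta, sigma = theta[:-1], abs(theta[-1])
    converged = bool(res.success)
    if not converged:
        flags.append("non-convergence")
    if np.any(np.abs(beta) > 12):
        if "separation" not in flags:
            flags.append("separation")

    # observed-information standard errors
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            H = approx_hess1(theta, nll)
            cov = np.linalg.pinv((H + H.T) / 2.0)
        except Exception:
            cov = np.full((p + 1, p + 1), np.nan)
    se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, np.inf))
    se = np.where(se > 0, se, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * special.ndtr(-np.abs(z))

    # include the binomial coefficient so loglik is comparable with GLM
    const = float(np.sum(special.gammaln(m + 1) - special.gammaln(y + 1)
                         - special.gammaln(m - y + 1)))
    table = pd.DataFrame(
        {
            "term": term_names,
            "estimate": beta,
            "se": se,
            "statistic": z,
            "p_value": pvals,
        }
    )
    return BinomialGLMMResult(
        params=table,
        sigma=float(sigma),
        loglik=float(-res.fun + const),
        converged=converged,
        n_obs=len(y),
        n_groups=n_groups,
        flags=flags,
        cov_fixed=cov[:p, :p],
    )
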