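"""Post-hoc per-feature mixed models and multiple-testing control.

After a significant omnibus pDFA, the individually important features are
tested one at a time: count features (numbers of elements per phase) with a
Poisson generalized linear mixed model with a random intercept per
individual, continuous features with the Gaussian analogue.  P-values from
one analysis batch are adjusted with the Benjamini-Hochberg step-up
procedure.

The Poisson mixed model maximizes the Laplace-approximated marginal
likelihood; an adaptive-free Gauss-Hermite quadrature evaluation of the same
marginal likelihood is available (``method="quadrature"``) and serves as the
exactness cross-check for the 1-D random effect.  Fixed-effect inference is
a Wald test (z-statistic) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.special import gammaln
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(30)


@dataclass
class PosthocResult:
    """One feature's mixed-model test, Table-style.

    ``beta_fixed`` is the fixed-effect contrast on the model's link scale
    (log scale for counts), oriented against the reference level (feed when
    present), so a positive value means "higher in the non-reference
    context".
    """

    feature: str
    family: str
    beta_fixed: float
    se: float
    p_raw: float
    p_adjusted: float | None = None
    group_means_sd: dict[str, tuple[float, float]] = field(default_factory=dict)
    sigma_individual: float = float("nan")
    converged: bool = True
    reference_level: str = ""

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "family": self.family,
            "beta_fixed": self.beta_fixed,
            "se": self.se,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "group_means_sd": {k: list(v) for k, v in self.group_means_sd.items()},
            "sigma_individual": self.sigma_individual,
            "converged": self.converged,
            "reference_level": self.reference_level,
        }


def _design(fixed, random, reference: str | None):
    fixed = np.asarray([str(v) for v in fixed])
    random = np.asarray([str(v) for v in random])
    levels = sorted(set(fixed))
    if len(levels) < 2:
        raise ValueError("need at least 2 fixed-effect levels")
    if reference is None:
        reference = "feed" if "feed" in levels else levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among {levels}")
    contrast_levels = [lv for lv in levels if lv != reference]
    X = np.column_stack(
        [np.ones(len(fixed))] + [(fixed == lv).astype(float) for lv in contrast_levels]
    )
    groups = pd.Categorical(random)
    if len(groups.categories) < 2:
        raise ValueError("need at least 2 random-effect groups (individuals)")
    return X, np.asarray(groups.codes), len(groups.categories), reference, contrast_levels, fixed


def _group_means_sd(values: np.ndarray, fixed: np.ndarray) -> dict[str, tuple[float, float]]:
    out = {}
    for lv in sorted(set(fixed)):
        v = values[fixed == lv]
        out[lv] = (float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0)
    return out


# ---------------------------------------------------------------------------
# Poisson GLMM with a 1-D random intercept
# ---------------------------------------------------------------------------


def _poisson_group_loglik_laplace(y, eta_fixed, sigma):
    """Laplace-approximated log integral over one group's random intercept."""
    if sigma < 1e-8:
        eta = eta_fixed
        return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1)))
    b = 0.0
    for _ in range(50):  # Newton for the conditional mode
        mu = np.exp(eta_fixed + b)
        grad = np.sum(y - mu) - b / sigma**2
        hess = -np.sum(mu) - 1.0 / sigma**2
        step = grad / hess
        b_new = b - step
        if abs(b_new - b) < 1e-10:
            b = b_new
            break
        b = b_new
    mu = np.exp(eta_fixed + b)
    g = np.sum(y * (eta_fixed + b) - mu - gammaln(y + 1)) - b**2 / (2 * sigma**2)
    return float(g - 0.5 * np.log(sigma**2 * np.sum(mu) + 1.0))


def _poisson_group_loglik_quadrature(y, eta_fixed, sigma):
    """Gauss-Hermite evaluation of the same marginal log-likelihood."""
    if sigma < 1e-8:
        eta = eta_fixed
        return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1)))
    b = np.sqrt(2.0) * sigma * _GH_NODES  # quadrature points on the b scale
    eta = eta_fixed[:, None] + b[None, :]
    log_integrand = np.sum(y[:, None] * eta - np.exp(eta) - gammaln(y + 1)[:, None], axis=0)
    m = log_integrand.max()
    return float(m + np.log(np.sum(_GH_WEIGHTS * np.exp(log_integrand - m)) / np.sqrt(np.pi)))


def _poisson_mixed_loglik(params, y, X, group_codes, n_groups, method):
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    eta_fixed = X @ beta
    fn = (
        _poisson_group_loglik_laplace
        if method == "laplace"
        else _poisson_group_loglik_quadrature
    )
    total = 0.0
    for g in range(n_groups):
        rows = group_codes == g
        total += fn(y[rows], eta_fixed[rows], sigma)
    return total


def _numerical_hessian(f, x, h=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def fit_mixed_count(
    values,
    fixed,
    random,
    feature: str = "",
    reference: str | None = None,
    method: str = "laplace",
) -> PosthocResult:
    """Poisson log-link mixed model with a random intercept per individual.

    ``values`` are non-negative integer counts; ``fixed`` the context labels
    (reference level feed, so the reported contrast is oriented travel vs
    feed); ``random`` the individual labels.  Wald test on the fixed-effect
    contrast.  Non-convergence is flagged on the result, never raised.
    """
    y = np.asarray(values, dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("count family requires non-negative integer values")
    if method not in ("laplace", "quadrature"):
        raise ValueError("method must be 'laplace' or 'quadrature'")
    X, codes, n_groups, ref, contrast_levels, fixed_arr = _design(fixed, random, reference)

    def negloglik(params):
        return -_poisson_mixed_loglik(params, y, X, codes, n_groups, method)

    # moment-based start: log group means
    beta0 = np.zeros(X.shape[1])
    beta0[0] = np.log(max(y.mean(), 0.1))
    x0 = np.concatenate([beta0, [np.log(0.5)]])
    opt = scipy.optimize.minimize(negloglik, x0, method="Nelder-Mead",
                                  options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    opt = scipy.optimize.minimize(negloglik, opt.x, method="BFGS",
                                  options={"gtol": 1e-7, "maxiter": 500})
    params = opt.x
    converged = bool(np.isfinite(opt.fun))

    H = _numerical_hessian(negloglik, params)
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(len(params), np.nan)
        converged = False

    beta1 = float(params[1])
    se1 = float(se_all[1])
    z = beta1 / se1 if se1 > 0 else np.nan
    p = float(2 * scipy.stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return PosthocResult(
        feature=feature,
        family="count",
        beta_fixed=beta1 if len(contrast_levels) == 1 else beta1,
        se=se1,
        p_raw=p,
        group_means_sd=_group_means_sd(y, fixed_arr),
        sigma_individual=float(np.exp(params[-1])),
        converged=converged,
        reference_level=ref,
    )


def fit_mixed_gaussian(
    values,
    fixed,
    random,
    feature: str = "",
    reference: str | None = None,
) -> PosthocResult:
    """Gaussian mixed model (random intercept per individual), same interface."""
    y = np.asarray(values, dtype=float)
    X, codes, n_groups, ref, contrast_levels, fixed_arr = _design(fixed, random, reference)
    model = MixedLM(y, X, groups=codes)
    converged = True
    try:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            fit = model.fit(reml=True)
        beta1 = float(np.asarray(fit.fe_params)[1])
        se1 = float(np.asarray(fit.bse_fe)[1])
        p = float(2 * scipy.stats.norm.sf(abs(beta1 / se1))) if se1 > 0 else float("nan")
        sigma_ind = float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0)))
    except Exception:
        beta1, se1, p, sigma_ind, converged = np.nan, np.nan, np.nan, np.nan, False
    return PosthocResult(
        feature=feature,
        family="continuous",
        beta_fixed=beta1,
        se=se1,
        p_raw=p,
        group_means_sd=_group_means_sd(y, fixed_arr),
        sigma_individual=sigma_ind,
        converged=converged,
        reference_level=ref,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adjusted_(i) = min_{j >= i} (m * p_(j) / j)`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def adjust_batch(results: list[PosthocResult]) -> list[PosthocResult]:
    """BH-adjust a batch of per-feature results in place and return it."""
    ps = [r.p_raw for r in results]
    if any(not np.isfinite(p) for p in ps):
        for r in results:
            r.p_adjusted = r.p_raw if np.isfinite(r.p_raw) else float("nan")
        return results
    adj = bh_adjust(ps)
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results
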