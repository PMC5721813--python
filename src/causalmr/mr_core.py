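"""Causal-effect estimators for two-sample Mendelian randomization.

Given J harmonized instruments with SNP-exposure effects ``beta_gp_j`` (SD
units, standard error ``se_gp_j``) and SNP-outcome effects ``beta_gd_j``
(log-odds, standard error ``se_gd_j``), the estimators here target the causal
log odds ratio per SD of exposure:

* **Wald ratio** — the single-SNP estimate beta_gd / beta_gp.
* **IVW** — the inverse-variance-weighted average of Wald ratios; also the
  closed-form limit of the likelihood estimator when the exposure effects are
  known without error, used as its initializer and reference.
* **Likelihood-based** — maximum likelihood under independent bivariate
  normals: observed (beta_gp_j, beta_gd_j) have means (xi_j, beta * xi_j) and
  SDs (se_gp_j, se_gd_j), with the per-SNP true effects xi_j profiled out.
  This accounts for measurement error on the exposure side.
* **Weighted median** — the 50th weighted percentile of ordered Wald ratios;
  consistent while valid instruments carry more than half the weight.
* **MR-Egger** — weighted regression of beta_gd on beta_gp with a free
  intercept; a nonzero intercept estimates directional pleiotropy and the
  slope is a pleiotropy-adjusted causal effect.

All p-values are two-sided against the standard normal reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .sumstats_io import HarmonizedInstrument

__all__ = [
    "Z95",
    "MREstimate",
    "MRConvergenceError",
    "wald_ratio",
    "ivw_estimate",
    "likelihood_mr",
    "weighted_median_mr",
    "egger_mr",
]

# Two-sided 95% normal quantile, carried to the precision at which printed
# confidence intervals round-trip through SE reconstruction.
Z95 = 1.959964


class MRConvergenceError(RuntimeError):
    """Likelihood optimization failed; carries the optimizer trace."""

    def __init__(self, message: str, trace: list[dict]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate: log-OR per SD with normal-theory uncertainty.

    ``intercept`` fields are populated by MR-Egger only; ``nuisance_means``
    holds the fitted per-SNP true exposure effects of the likelihood method.
    """

    method: str
    n_snps: int
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    pvalue: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_ci_low: float | None = None
    intercept_ci_high: float | None = None
    nuisance_means: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not self.se > 0:
            raise ValueError("se must be positive")
        if not (self.ci_low <= self.or_ <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")


def _finish(method: str, n_snps: int, beta: float, se: float, **extra) -> MREstimate:
    z = beta / se
    return MREstimate(
        method=method, n_snps=n_snps, beta=beta, se=se,
        or_=math.exp(beta),
        ci_low=math.exp(beta - Z95 * se), ci_high=math.exp(beta + Z95 * se),
        pvalue=float(2 * stats.norm.sf(abs(z))),
        **extra,
    )


def _arrays(hs: Sequence[HarmonizedInstrument]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([h.beta_gp for h in hs], dtype=float)
    sx = np.array([h.se_gp for h in hs], dtype=float)
    by = np.array([h.beta_gd for h in hs], dtype=float)
    sy = np.array([h.se_gd for h in hs], dtype=float)
    return bx, sx, by, sy


def wald_ratio(h: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate beta_gd / beta_gp.

    The standard error is the first-order delta-method value se_gd /
    \\|beta_gp\\| (exposure-side uncertainty neglected, as in the ratio's
    classical use).
    """
    if h.beta_gp == 0:
        raise ZeroDivisionError(f"{h.snp_id}: Wald ratio undefined for beta_gp = 0")
    beta = h.beta_gd / h.beta_gp
    se = h.se_gd / abs(h.beta_gp)
    return _finish("wald", 1, beta, se)


def ivw_estimate(hs: Sequence[HarmonizedInstrument]) -> MREstimate:
    """Inverse-variance-weighted average of Wald ratios (fixed effect).

    beta = sum(bx * by / sy^2) / sum(bx^2 / sy^2); se = sum(bx^2 / sy^2)^-1/2.
    Equals the Wald ratio exactly for a single instrument.
    """
    if not hs:
        raise ValueError("at least one instrument is required")
    bx, _, by, sy = _arrays(hs)
    info = float(np.sum(bx**2 / sy**2))
    if info == 0:
        raise ZeroDivisionError("all instruments have beta_gp = 0")
    beta = float(np.sum(bx * by / sy**2)) / info
    return _finish("ivw", len(hs), beta, info ** -0.5)


def _profile_xi(beta: float, bx, sx, by, sy) -> np.ndarray:
    # Conditional maximizer of the joint likelihood in the nuisance means.
    return (bx / sx**2 + beta * by / sy**2) / (1 / sx**2 + beta**2 / sy**2)


def _profile_loglik(beta: float, bx, sx, by, sy) -> float:
    xi = _profile_xi(beta, bx, sx, by, sy)
    return float(-0.5 * np.sum(((bx - xi) / sx) ** 2 + ((by - beta * xi) / sy) ** 2))


def likelihood_mr(hs: Sequence[HarmonizedInstrument], ci_method: str = "wald") -> MREstimate:
    """Likelihood-based causal estimate for summarized two-sample data.

    The joint likelihood over (beta, xi_1..xi_J) is maximized by profiling the
    nuisance means analytically and optimizing the resulting one-dimensional
    profile in beta, bracketed around the IVW start and widened on demand.
    The standard error comes from the observed information of the profile
    log-likelihood (central second difference); ``ci_method="profile"``
    replaces the Wald interval by the chi-square(1) profile-likelihood one.
    """
    if not hs:
        raise ValueError("at least one instrument is required")
    if ci_method not in ("wald", "profile"):
        raise ValueError("ci_method must be 'wald' or 'profile'")
    bx, sx, by, sy = _arrays(hs)
    start = ivw_estimate(hs)
    nll = lambda b: -_profile_loglik(b, bx, sx, by, sy)

    half_width = max(10 * start.se, 0.5)
    trace: list[dict] = []
    beta_hat = None
    for _ in range(8):  # bounded bracket-widening restarts
        lo, hi = start.beta - half_width, start.beta + half_width
        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-10})
        trace.append({"bounds": (lo, hi), "x": float(res.x), "fun": float(res.fun),
                      "success": bool(res.success)})
        interior = lo + 1e-6 * half_width < res.x < hi - 1e-6 * half_width
        if res.success and interior:
            beta_hat = float(res.x)
            break
        half_width *= 4
    if beta_hat is None:
        raise MRConvergenceError("profile-likelihood optimization did not converge "
                                 "to an interior maximum", trace)

    h = 1e-4 * max(1.0, abs(beta_hat))
    d2 = (-nll(beta_hat + h) + 2 * nll(beta_hat) - nll(beta_hat - h)) / h**2
    if not d2 < 0:
        raise MRConvergenceError("profile log-likelihood not locally concave at optimum", trace)
    se = (-d2) ** -0.5

    xi = _profile_xi(beta_hat, bx, sx, by, sy)
    est = _finish("likelihood", len(hs), beta_hat, se, nuisance_means=tuple(float(x) for x in xi))
    if ci_method == "profile":
        ll_max = _profile_loglik(beta_hat, bx, sx, by, sy)
        drop = stats.chi2.ppf(0.95, df=1) / 2
        g = lambda b: _profile_loglik(b, bx, sx, by, sy) - (ll_max - drop)
        lo = _bracket_root(g, beta_hat, -se)
        hi = _bracket_root(g, beta_hat, se)
        est = MREstimate(**{**est.__dict__, "ci_low": math.exp(lo), "ci_high": math.exp(hi),
                            "or_": est.or_})
    return est


def _bracket_root(g, start: float, step: float) -> float:
    """Walk outward from the maximum until g changes sign, then bisect."""
    a, b = start, start + step
    for _ in range(60):
        if g(b) < 0:
            return float(optimize.brentq(g, min(a, b), max(a, b), xtol=1e-10))
        a, b = b, b + step
    raise MRConvergenceError("profile-likelihood CI bound not bracketed", [])


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50th weighted percentile of the ordered ratios.

    Ratio j, sorted ascending, occupies percentile (cum_w_j - w_j/2) / sum_w;
    the estimate interpolates linearly between the bracketing percentiles.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    p = (np.cumsum(w) - w / 2) / np.sum(w)
    return float(np.interp(0.5, p, r))


def weighted_median_mr(hs: Sequence[HarmonizedInstrument], n_boot: int = 1000,
                       seed: int | None = None) -> MREstimate:
    """Weighted-median causal estimate with a parametric-bootstrap SE.

    Wald ratios are ordered and treated as percentiles of a distribution
    weighted by the inverse first-order ratio variance w_j = beta_gp_j^2 /
    se_gd_j^2; the estimate is the interpolated weighted median.  Each
    bootstrap replicate redraws beta_gp_j ~ N(beta_gp_j, se_gp_j^2) and
    beta_gd_j ~ N(beta_gd_j, se_gd_j^2) and recomputes the median; the SE is
    the SD over replicates and the CI is normal-approximation.  ``seed`` is
    required — there is no hidden global random state.
    """
    if len(hs) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if seed is None:
        raise ValueError("seed is required for the bootstrap")
    bx, sx, by, sy = _arrays(hs)
    if np.any(bx == 0):
        raise ZeroDivisionError("Wald ratio undefined for beta_gp = 0")
    beta = _weighted_median(by / bx, bx**2 / sy**2)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, len(hs)))
    by_star = rng.normal(by, sy, size=(n_boot, len(hs)))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = bx_star[i]
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        boots[i] = _weighted_median(by_star[i] / bxs, bxs**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return _finish("weighted_median", len(hs), beta, se)


def egger_mr(hs: Sequence[HarmonizedInstrument]) -> MREstimate:
    """MR-Egger: weighted regression of beta_gd on beta_gp with an intercept.

    Weights are 1/se_gd^2.  The slope is the pleiotropy-adjusted causal
    estimate; the intercept estimates the average directional pleiotropic
    effect (instruments must be oriented beta_gp >= 0, which harmonization
    enforces).  Standard errors carry a multiplicative residual-dispersion
    factor floored at 1 (no shrinkage under underdispersion).
    """
    if len(hs) < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    bx, _, by, sy = _arrays(hs)
    if np.ptp(bx) == 0:
        raise np.linalg.LinAlgError("zero variance in beta_gp: singular design")
    fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    # statsmodels' bse already scales by the estimated dispersion; re-floor it.
    dispersion = float(fit.scale)
    inflate = math.sqrt(max(dispersion, 1.0) / dispersion)
    (intercept, slope) = (float(b) for b in fit.params)
    (intercept_se, slope_se) = (float(s) * inflate for s in fit.bse)
    return _finish(
        "egger", len(hs), slope, slope_se,
        intercept=intercept, intercept_se=intercept_se,
        intercept_ci_low=intercept - Z95 * intercept_se,
        intercept_ci_high=intercept + Z95 * intercept_se,
    )


def egger_intercept_pvalue(est: MREstimate) -> float:
    """Two-sided p-value for the Egger directional-pleiotropy intercept."""
    if est.intercept is None or est.intercept_se is None:
        raise ValueError("estimate carries no intercept block")
    return float(2 * stats.norm.sf(abs(est.intercept / est.intercept_se)))
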