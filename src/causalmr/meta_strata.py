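"""Fixed-effect meta-analysis over strata and heterogeneity statistics.

Case-control GWAS are frequently analyzed within publication sets or sex
strata and then pooled; the same inverse-variance machinery also quantifies
whether a causal effect differs across strata.  Heterogeneity is summarized
by Cochran's Q (the weighted sum of squared deviations from the pooled
estimate, chi-square with strata-1 degrees of freedom under homogeneity) and
I^2 = max(0, (Q - df) / Q) * 100, the percentage of variation attributable to
between-stratum heterogeneity.

Printed odds ratios with 95% CIs can be converted back to (log-OR, SE) pairs
with :func:`se_from_ci`, which makes published stratified results directly
poolable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from scipy import stats

from .mr_core import Z95, MREstimate
from .sumstats_io import HarmonizedInstrument, OutcomeAssociation

__all__ = [
    "StratumEstimate",
    "MetaResult",
    "se_from_ci",
    "stratum_from_ci",
    "fixed_effect_meta",
    "stratified_mr",
    "pool_outcome_strata",
]


@dataclass(frozen=True)
class StratumEstimate:
    """One stratum's effect on the log-OR scale."""

    label: str
    beta: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.label}: se must be positive")


@dataclass(frozen=True)
class MetaResult:
    """Pooled fixed-effect estimate with heterogeneity statistics."""

    beta_pooled: float
    se_pooled: float
    q: float
    df: int
    i2: float
    p_het: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")

    @property
    def or_pooled(self) -> float:
        return math.exp(self.beta_pooled)

    @property
    def ci_pooled(self) -> tuple[float, float]:
        return (math.exp(self.beta_pooled - Z95 * self.se_pooled),
                math.exp(self.beta_pooled + Z95 * self.se_pooled))


def se_from_ci(or_point: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Reconstruct (log-OR, SE) from a printed odds ratio and 95% CI.

    Assumes the CI is symmetric on the log scale, i.e. exp(beta +/- z * se)
    with z = 1.959964; the reconstruction is exact for such intervals.
    """
    if not (0 < ci_low <= or_point <= ci_high):
        raise ValueError("require 0 < ci_low <= or_point <= ci_high")
    if ci_low == ci_high:
        raise ValueError("zero-width confidence interval")
    beta = math.log(or_point)
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * Z95)
    return beta, se


def stratum_from_ci(label: str, or_point: float, ci_low: float, ci_high: float) -> StratumEstimate:
    """Convenience wrapper building a StratumEstimate from printed OR and CI."""
    beta, se = se_from_ci(or_point, ci_low, ci_high)
    return StratumEstimate(label=label, beta=beta, se=se)


def fixed_effect_meta(strata: Sequence[StratumEstimate]) -> MetaResult:
    """Inverse-variance fixed-effect pooling with Q, I^2 and P_heterogeneity.

    Weights are 1/se^2; Q = sum w (beta - beta_pooled)^2 is referred to a
    chi-square with strata-1 degrees of freedom, and I^2 is truncated at 0.
    """
    if len(strata) < 2:
        raise ValueError("meta-analysis requires at least 2 strata")
    w = [1.0 / s.se**2 for s in strata]
    sw = sum(w)
    beta = sum(wi * s.beta for wi, s in zip(w, strata)) / sw
    q = sum(wi * (s.beta - beta) ** 2 for wi, s in zip(w, strata))
    df = len(strata) - 1
    i2 = max(0.0, (q - df) / q) * 100 if q > 0 else 0.0
    return MetaResult(
        beta_pooled=beta, se_pooled=sw**-0.5, q=q, df=df, i2=i2,
        p_het=float(stats.chi2.sf(q, df)),
    )


def stratified_mr(per_stratum_instruments: Mapping[str, Sequence[HarmonizedInstrument]],
                  method: Callable[..., MREstimate], **method_kwargs,
                  ) -> tuple[list[tuple[str, MREstimate]], MetaResult]:
    """Run an estimator within each stratum, then pool the stratum estimates.

    ``method`` is any mr_core estimator taking an instrument list (extra
    keyword arguments, e.g. a weighted-median seed, are passed through).
    Strata are processed in sorted-label order for determinism.
    """
    if len(per_stratum_instruments) < 2:
        raise ValueError("stratified analysis requires at least 2 strata")
    estimates: list[tuple[str, MREstimate]] = []
    for label in sorted(per_stratum_instruments):
        hs = per_stratum_instruments[label]
        if not hs:
            raise ValueError(f"stratum {label!r} has no instruments")
        estimates.append((label, method(hs, **method_kwargs)))
    meta = fixed_effect_meta([StratumEstimate(label, est.beta, est.se)
                              for label, est in estimates])
    return estimates, meta


def pool_outcome_strata(outcomes: Sequence[OutcomeAssociation], label: str = "overall",
                        ) -> list[OutcomeAssociation]:
    """Combine per-SNP outcome effects across strata by fixed-effect pooling.

    This mirrors the standard practice of meta-analyzing per-set GWAS results
    into one overall per-SNP (beta_gd, se_gd) before causal estimation.
    Alleles must agree across strata for a SNP (records are not re-oriented
    here); first-seen SNP order is preserved.
    """
    groups: dict[str, list[OutcomeAssociation]] = {}
    order: list[str] = []
    for rec in outcomes:
        if rec.snp_id not in groups:
            order.append(rec.snp_id)
        groups.setdefault(rec.snp_id, []).append(rec)
    pooled: list[OutcomeAssociation] = []
    for snp in order:
        recs = groups[snp]
        alleles = {(r.effect_allele, r.other_allele) for r in recs}
        if len(alleles) != 1:
            raise ValueError(f"{snp}: inconsistent allele coding across strata")
        w = [1.0 / r.se_gd**2 for r in recs]
        sw = sum(w)
        beta = sum(wi * r.beta_gd for wi, r in zip(w, recs)) / sw
        pooled.append(OutcomeAssociation(
            snp_id=snp, effect_allele=recs[0].effect_allele,
            other_allele=recs[0].other_allele,
            beta_gd=beta, se_gd=sw**-0.5, stratum=label,
        ))
    return pooled
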