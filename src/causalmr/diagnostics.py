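"""Pleiotropy diagnostics: funnel-plot data and pathway-subset testing.

A funnel plot displays each instrument's implied risk increase, the
exponentiated Wald ratio exp(beta_gd / beta_gp), against its instrumental
strength.  Under no pleiotropy the scatter is symmetric about the causal
estimate, with weak instruments fanning out at the bottom; asymmetry suggests
directional pleiotropy.  Instruments known to overlap another trait (e.g.
SNPs also robustly associated with BMI) can be flagged so they render with a
distinct marker.

Pathway-subset testing splits a trait's instruments by the mechanistic
pathway they were annotated to in the source GWAS and re-estimates the causal
effect within each sufficiently large subset, with a Bonferroni threshold
shared across every subset tested in the analysis (all traits jointly).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .mr_core import MREstimate, _weighted_median, likelihood_mr
from .sumstats_io import HarmonizedInstrument

__all__ = [
    "FunnelPoint",
    "FunnelData",
    "PathwayResult",
    "funnel_data",
    "pathway_subset_mr",
    "plot_funnel",
]


@dataclass(frozen=True)
class FunnelPoint:
    """One instrument's funnel coordinates.

    risk_increase = exp(beta_gd / beta_gp); strength defaults to
    beta_gp / se_gd.  ``bmi_overlap`` marks instruments also associated with
    the overlapping trait supplied to :func:`funnel_data`.
    """

    snp_id: str
    risk_increase: float
    strength: float
    bmi_overlap: bool = False

    def __post_init__(self) -> None:
        if not self.risk_increase > 0:
            raise ValueError("risk_increase must be positive")


@dataclass(frozen=True)
class FunnelData:
    """Funnel points plus the overlay estimates drawn as reference lines."""

    points: tuple[FunnelPoint, ...]
    likelihood_or: float
    weighted_median_or: float


def funnel_data(hs: Sequence[HarmonizedInstrument], overlap: Iterable[str] = (),
                strength_definition: str = "exposure_over_outcome_se") -> FunnelData:
    """Compute funnel-plot coordinates and overlay lines for an instrument set.

    ``strength_definition`` selects the x... strength formula:
    ``"exposure_over_outcome_se"`` (default) uses beta_gp / se_gd;
    ``"outcome_over_exposure_se"`` uses beta_gd / se_gp, the variant sometimes
    described in figure captions.  Overlays are the likelihood-based and
    weighted-median odds ratios (point estimates; no bootstrap is run here).
    Instruments with beta_gp = 0 are skipped with a warning.
    """
    if strength_definition not in ("exposure_over_outcome_se", "outcome_over_exposure_se"):
        raise ValueError(f"unknown strength_definition {strength_definition!r}")
    overlap = set(overlap)
    points: list[FunnelPoint] = []
    usable: list[HarmonizedInstrument] = []
    for h in hs:
        if h.beta_gp == 0:
            warnings.warn(f"{h.snp_id}: beta_gp = 0, skipped in funnel data", stacklevel=2)
            continue
        usable.append(h)
        strength = (h.beta_gp / h.se_gd if strength_definition == "exposure_over_outcome_se"
                    else h.beta_gd / h.se_gp)
        points.append(FunnelPoint(
            snp_id=h.snp_id,
            risk_increase=math.exp(h.beta_gd / h.beta_gp),
            strength=strength,
            bmi_overlap=h.snp_id in overlap,
        ))
    if not usable:
        raise ValueError("no usable instruments (all beta_gp = 0)")
    likelihood_or = likelihood_mr(usable).or_
    import numpy as np

    bx = np.array([h.beta_gp for h in usable])
    by = np.array([h.beta_gd for h in usable])
    sy = np.array([h.se_gd for h in usable])
    median_or = math.exp(_weighted_median(by / bx, bx**2 / sy**2))
    return FunnelData(points=tuple(points), likelihood_or=likelihood_or,
                      weighted_median_or=median_or)


@dataclass(frozen=True)
class PathwayResult:
    """Causal estimate for one mechanistic-pathway subset of instruments."""

    pathway: str
    n_snps: int
    estimate: MREstimate
    bonferroni_threshold: float
    significant: bool

    def __post_init__(self) -> None:
        if self.n_snps < 5:
            raise ValueError("tested pathways must contain at least 5 SNPs")
        if self.significant != (self.estimate.pvalue < self.bonferroni_threshold):
            raise ValueError("significance flag inconsistent with threshold")


def pathway_subset_mr(hs: Sequence[HarmonizedInstrument], min_size: int = 5,
                      alpha: float = 0.05, n_tests_global: int | None = None,
                      ) -> tuple[list[PathwayResult], dict[str, int]]:
    """Likelihood-based MR within each mechanistic-pathway subset.

    Subsets smaller than ``min_size`` SNPs are skipped (returned in the
    second element as label -> count).  ``n_tests_global`` is the total
    number of subsets tested across the whole analysis — all traits jointly —
    and sets the Bonferroni threshold alpha / n_tests_global; it is an
    explicit input and never inferred from one trait's labels.  Results are
    sorted by ascending p-value.
    """
    labelled = [h for h in hs if h.pathway is not None]
    if not labelled:
        warnings.warn("no pathway labels present; nothing to test", stacklevel=2)
        return [], {}
    if n_tests_global is None or n_tests_global < 1:
        raise ValueError("n_tests_global (total subsets tested across traits) is required")
    threshold = alpha / n_tests_global

    groups: dict[str, list[HarmonizedInstrument]] = {}
    for h in labelled:
        groups.setdefault(h.pathway, []).append(h)

    results: list[PathwayResult] = []
    skipped: dict[str, int] = {}
    for label in sorted(groups):
        subset = groups[label]
        if len(subset) < min_size:
            skipped[label] = len(subset)
            continue
        est = likelihood_mr(subset)
        results.append(PathwayResult(
            pathway=label, n_snps=len(subset), estimate=est,
            bonferroni_threshold=threshold,
            significant=est.pvalue < threshold,
        ))
    results.sort(key=lambda r: (r.estimate.pvalue, r.pathway))
    return results, skipped


def plot_funnel(data: FunnelData, path, title: str = "") -> None:
    """Render a funnel plot (log-scaled risk-increase axis) to an image file.

    Circles are ordinary instruments, triangles those flagged as overlapping;
    dashed/dotted vertical lines mark the likelihood and weighted-median
    odds ratios.  Purely presentational — nothing downstream depends on it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for marker, flag in (("o", False), ("^", True)):
        xs = [p.risk_increase for p in data.points if p.bmi_overlap is flag]
        ys = [p.strength for p in data.points if p.bmi_overlap is flag]
        if xs:
            ax.scatter(xs, ys, marker=marker, s=18, alpha=0.7,
                       label="overlap SNPs" if flag else "instruments")
    ax.axvline(data.likelihood_or, linestyle="--", color="tab:red", label="likelihood OR")
    ax.axvline(data.weighted_median_or, linestyle=":", color="tab:blue", label="weighted median OR")
    ax.axvline(1.0, color="0.6", linewidth=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("per-SNP risk increase, exp(beta_gd / beta_gp)")
    ax.set_ylabel("instrument strength")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
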