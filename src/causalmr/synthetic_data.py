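"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator emulates the data regime of a two-sample MR study: J
independent SNPs whose true per-allele effects gamma_j on a standardized
exposure jointly explain a target fraction R^2 of its variance, an exposure
GWAS of n_exposure individuals, and a case-control outcome GWAS (n_cases /
n_controls) on the log-odds scale with true causal effect ``causal_beta`` per
SD of exposure.  Optional per-SNP direct (pleiotropic) effects alpha_j on the
outcome can be injected — none, balanced (zero mean), or directional
(nonzero mean) — to probe estimator robustness to invalid instruments.

Summary statistics are simulated directly: for allele frequency f_j,

    se_gp_j = 1 / sqrt(2 f_j (1 - f_j) * n_exposure)
    se_gd_j = 1 / sqrt(2 f_j (1 - f_j) * N * K * (1 - K)),  K = n_cases / N

and the observed effects are independent normal draws around gamma_j and
causal_beta * gamma_j + alpha_j respectively (no sample overlap).  The raw
gamma_j are rescaled so the realized instrument variance explained,
sum_j 2 f_j (1 - f_j) gamma_j^2, hits r2_target exactly.

All randomness flows from the single explicit ``seed``; a given config is
byte-for-byte reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import mr_core
from .mr_core import MREstimate, Z95
from .sumstats_io import (
    ExposureInstrument,
    HarmonizedInstrument,
    OutcomeAssociation,
    harmonize,
    write_summary_table,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedStudy",
    "SimulationConfigError",
    "simulate_two_sample",
    "write_study",
    "benchmark_estimators",
]

# Non-palindromic allele codings cycled over SNPs needing unambiguous strands.
_SAFE_ALLELES = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T"))
_PALINDROMIC_ALLELES = (("A", "T"), ("C", "G"), ("T", "A"), ("G", "C"))


class SimulationConfigError(ValueError):
    """The requested configuration cannot be generated."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generative truth and study dimensions for one simulated MR study.

    Defaults mirror a BMI-scale analysis: 96 instruments explaining 2.7% of
    exposure variance, an exposure GWAS of 300k (large-consortium scale), an
    outcome study of 7110 cases / 7264 controls, and a true odds ratio of
    1.34 per SD (causal_beta = ln 1.34).
    """

    n_snps: int = 96
    r2_target: float = 0.027
    causal_beta: float = math.log(1.34)
    n_exposure: int = 300_000
    n_cases: int = 7110
    n_controls: int = 7264
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_fraction: float = 0.0
    seed: int = 0
    # Optional per-stratum outcome studies: label -> (n_cases, n_controls).
    # When given, the outcome table carries one row per SNP per stratum and no
    # pooled row (pooling across strata is a downstream choice).
    outcome_strata: Mapping[str, tuple[int, int]] | None = None
    # Per-stratum causal effects overriding causal_beta (heterogeneity studies).
    stratum_causal_beta: Mapping[str, float] | None = None
    n_pathways: int = 0
    trait_id: str = "sim_trait"

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise SimulationConfigError("n_snps must be >= 1")
        if not (0 < self.r2_target < 1):
            raise SimulationConfigError("r2_target must lie in (0, 1)")
        if self.n_exposure <= 0 or self.n_cases <= 0 or self.n_controls <= 0:
            raise SimulationConfigError("sample sizes must be positive")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise SimulationConfigError("pleiotropy_mode must be none/balanced/directional")
        if not (0 <= self.invalid_fraction <= 1):
            raise SimulationConfigError("invalid_fraction must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise SimulationConfigError("maf_range bounds must satisfy 0 < lo <= hi < 1")
        if not (0 <= self.palindromic_fraction <= 1):
            raise SimulationConfigError("palindromic_fraction must lie in [0, 1]")
        if self.stratum_causal_beta and not self.outcome_strata:
            raise SimulationConfigError("stratum_causal_beta requires outcome_strata")
        if self.outcome_strata:
            for label, (nca, nco) in self.outcome_strata.items():
                if nca <= 0 or nco <= 0:
                    raise SimulationConfigError(f"stratum {label!r}: sample sizes must be positive")


@dataclass(frozen=True)
class SimulationTruth:
    """The generative parameters realized in one study."""

    gamma: tuple[float, ...]
    alpha: tuple[float, ...]
    causal_beta: float
    maf: tuple[float, ...]


@dataclass(frozen=True)
class SimulatedStudy:
    """Emitted two-sample tables plus the truth that generated them."""

    exposure_table: tuple[ExposureInstrument, ...]
    outcome_table: tuple[OutcomeAssociation, ...]
    truth: SimulationTruth
    seed_used: int
    config: SimulationConfig

    def harmonized(self, stratum: str | None = None) -> list[HarmonizedInstrument]:
        """Convenience: harmonize the emitted tables (one stratum if named)."""
        outcomes = [o for o in self.outcome_table
                    if stratum is None or o.stratum == stratum]
        hs, _ = harmonize(list(self.exposure_table), outcomes)
        return hs


def _outcome_se(maf: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    n_total = n_cases + n_controls
    k = n_cases / n_total
    return 1.0 / np.sqrt(2 * maf * (1 - maf) * n_total * k * (1 - k))


def simulate_two_sample(config: SimulationConfig) -> SimulatedStudy:
    """Draw one two-sample summary-statistics study from the generative model."""
    rng = np.random.default_rng(config.seed)
    j = config.n_snps

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=j)
    het = 2 * maf * (1 - maf)

    gamma = np.abs(rng.standard_normal(j))
    gamma *= math.sqrt(config.r2_target / float(np.sum(het * gamma**2)))
    if not math.isclose(float(np.sum(het * gamma**2)), config.r2_target, rel_tol=1e-12):
        raise SimulationConfigError("variance-explained rescaling failed")

    alpha = np.zeros(j)
    if config.pleiotropy_mode != "none" and config.invalid_fraction > 0:
        n_invalid = math.ceil(config.invalid_fraction * j)
        invalid = rng.choice(j, size=n_invalid, replace=False)
        mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        alpha[invalid] = rng.normal(mean, config.pleiotropy_sd, size=n_invalid)

    se_gp = 1.0 / np.sqrt(het * config.n_exposure)
    beta_gp = rng.normal(gamma, se_gp)
    pvals = np.clip(2 * stats.norm.sf(np.abs(beta_gp / se_gp)), np.finfo(float).tiny, 1.0)

    n_pal = int(round(config.palindromic_fraction * j))
    pal_flags = np.zeros(j, dtype=bool)
    if n_pal:
        pal_flags[rng.choice(j, size=n_pal, replace=False)] = True

    snp_ids = [f"rs{k + 1:06d}" for k in range(j)]
    width = len(str(max(config.n_pathways, 1)))
    exposure: list[ExposureInstrument] = []
    pal_counter = safe_counter = 0
    for k in range(j):
        if pal_flags[k]:
            ea, oa = _PALINDROMIC_ALLELES[pal_counter % len(_PALINDROMIC_ALLELES)]
            pal_counter += 1
        else:
            ea, oa = _SAFE_ALLELES[safe_counter % len(_SAFE_ALLELES)]
            safe_counter += 1
        exposure.append(ExposureInstrument(
            snp_id=snp_ids[k], effect_allele=ea, other_allele=oa,
            beta_gp=float(beta_gp[k]), se_gp=float(se_gp[k]), pvalue=float(pvals[k]),
            eaf=float(maf[k]),
            pathway=f"pw{k % config.n_pathways:0{width}d}" if config.n_pathways else None,
            trait_id=config.trait_id,
        ))

    strata = config.outcome_strata or {"overall": (config.n_cases, config.n_controls)}
    overrides = dict(config.stratum_causal_beta or {})
    outcome: list[OutcomeAssociation] = []
    for label in strata:  # insertion order: deterministic given the mapping
        nca, nco = strata[label]
        se_gd = _outcome_se(maf, nca, nco)
        beta_here = overrides.get(label, config.causal_beta)
        beta_gd = rng.normal(beta_here * gamma + alpha, se_gd)
        for k in range(j):
            outcome.append(OutcomeAssociation(
                snp_id=snp_ids[k],
                effect_allele=exposure[k].effect_allele,
                other_allele=exposure[k].other_allele,
                beta_gd=float(beta_gd[k]), se_gd=float(se_gd[k]), stratum=label,
            ))

    return SimulatedStudy(
        exposure_table=tuple(exposure), outcome_table=tuple(outcome),
        truth=SimulationTruth(gamma=tuple(map(float, gamma)), alpha=tuple(map(float, alpha)),
                              causal_beta=config.causal_beta, maf=tuple(map(float, maf))),
        seed_used=config.seed, config=config,
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write exposure/outcome tables, a truth sidecar, and a run manifest.

    The tables use the exact sumstats_io dialect; the truth sidecar has
    columns (snp, gamma, alpha, f) and the manifest records the full config
    including the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": write_summary_table(list(study.exposure_table), outdir / "exposure.tsv"),
        "outcome": write_summary_table(list(study.outcome_table), outdir / "outcome.tsv"),
    }
    truth_df = pd.DataFrame({
        "snp": [e.snp_id for e in study.exposure_table],
        "gamma": [repr(g) for g in study.truth.gamma],
        "alpha": [repr(a) for a in study.truth.alpha],
        "f": [repr(f) for f in study.truth.maf],
    })
    paths["truth"] = outdir / "truth.tsv"
    truth_df.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")

    cfg = dataclasses.asdict(study.config)
    cfg["outcome_strata"] = ({k: list(v) for k, v in study.config.outcome_strata.items()}
                             if study.config.outcome_strata else None)
    cfg["stratum_causal_beta"] = (dict(study.config.stratum_causal_beta)
                                  if study.config.stratum_causal_beta else None)
    cfg["maf_range"] = list(study.config.maf_range)
    paths["manifest"] = outdir / "manifest.yaml"
    paths["manifest"].write_text(
        yaml.safe_dump({"config": cfg, "seed_used": study.seed_used}, sort_keys=True))
    return paths


_DEFAULT_ESTIMATORS: dict[str, Callable[..., MREstimate]] = {
    "ivw": mr_core.ivw_estimate,
    "likelihood": mr_core.likelihood_mr,
    "weighted_median": mr_core.weighted_median_mr,
    "egger": mr_core.egger_mr,
}


def benchmark_estimators(scenarios: Mapping[str, SimulationConfig], n_reps: int,
                         seed: int, estimators: Sequence[str] = ("ivw", "likelihood",
                                                                 "weighted_median", "egger"),
                         n_boot: int = 200) -> pd.DataFrame:
    """Operating characteristics of the estimators over simulated scenarios.

    For each scenario x estimator, runs ``n_reps`` independent replicates
    (replicate seeds derived deterministically from ``seed``) and reports
    bias, empirical SD, mean reported SE, 95% CI coverage of the true causal
    effect, two-sided rejection rate at alpha = 0.05, and the count of
    replicates where the estimator failed (failures are recorded, not fatal).
    """
    if n_reps < 50:
        raise ValueError("n_reps must be >= 50 for stable operating characteristics")
    unknown = set(estimators) - set(_DEFAULT_ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimator(s): {sorted(unknown)}")

    master = np.random.default_rng(seed)
    rows = []
    for name in scenarios:
        config = scenarios[name]
        rep_seeds = master.integers(0, 2**31 - 1, size=n_reps)
        per_est: dict[str, dict[str, list]] = {e: {"beta": [], "se": []} for e in estimators}
        failures = {e: 0 for e in estimators}
        truth_beta = config.causal_beta
        for r in range(n_reps):
            study = simulate_two_sample(replace(config, seed=int(rep_seeds[r])))
            hs = study.harmonized()
            for est_name in estimators:
                try:
                    if est_name == "weighted_median":
                        est = mr_core.weighted_median_mr(hs, n_boot=n_boot,
                                                         seed=int(rep_seeds[r]) + 1)
                    else:
                        est = _DEFAULT_ESTIMATORS[est_name](hs)
                except Exception:
                    failures[est_name] += 1
                    continue
                per_est[est_name]["beta"].append(est.beta)
                per_est[est_name]["se"].append(est.se)
        for est_name in estimators:
            betas = np.array(per_est[est_name]["beta"])
            ses = np.array(per_est[est_name]["se"])
            if betas.size == 0:
                rows.append({"scenario": name, "estimator": est_name, "n_reps": n_reps,
                             "n_fail": failures[est_name], "bias": np.nan, "emp_sd": np.nan,
                             "mean_se": np.nan, "coverage": np.nan, "rejection_rate": np.nan})
                continue
            cover = np.mean((betas - Z95 * ses <= truth_beta) & (truth_beta <= betas + Z95 * ses))
            reject = np.mean(2 * stats.norm.sf(np.abs(betas / ses)) < 0.05)
            rows.append({
                "scenario": name, "estimator": est_name, "n_reps": n_reps,
                "n_fail": failures[est_name],
                "bias": float(np.mean(betas) - truth_beta),
                "emp_sd": float(np.std(betas, ddof=1)),
                "mean_se": float(np.mean(ses)),
                "coverage": float(cover),
                "rejection_rate": float(reject),
            })
    return pd.DataFrame(rows)
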