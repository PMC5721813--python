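"""End-to-end analysis orchestration: curate, harmonize, estimate, pool.

The full workflow per exposure trait is: read the exposure summary table,
keep genome-wide-significant independent instruments, resolve
strand-ambiguous SNPs, harmonize against the outcome table, estimate the
causal effect by every configured method on the pooled outcome, repeat the
likelihood analysis within each publication-set and sex stratum with
fixed-effect pooling and heterogeneity statistics, rerun excluding
overlapping (e.g. BMI-associated) SNPs, and emit funnel and pathway-subset
tables.  Every filtering action is logged as a machine-readable event, and
the whole run is deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import mr_core
from .diagnostics import funnel_data, pathway_subset_mr
from .meta_strata import MetaResult, StratumEstimate, fixed_effect_meta, pool_outcome_strata
from .mr_core import MREstimate
from .power import PowerQuery, mr_power_binary
from .sumstats_io import (
    HarmonizedInstrument,
    LdMatrix,
    exclude_snps,
    harmonize,
    read_ld_table,
    read_proxy_table,
    read_summary_table,
    resolve_ambiguous_alleles,
    select_instruments,
)

__all__ = ["TraitConfig", "AnalysisConfig", "ResultBundle", "run_full_analysis"]

RESULT_COLUMNS = [
    "trait", "stratum", "method", "n_snps", "beta", "se", "or", "ci_low", "ci_high",
    "pvalue", "intercept", "intercept_se", "intercept_ci_low", "intercept_ci_high",
    "q", "df", "i2", "p_het",
]


@dataclass(frozen=True)
class TraitConfig:
    """One exposure trait: its summary table and optional exclusion list."""

    name: str
    exposure_path: str
    exclusion_snps: tuple[str, ...] = ()  # e.g. instruments overlapping BMI


@dataclass(frozen=True)
class AnalysisConfig:
    """Full pipeline configuration (mirrors the YAML config file)."""

    traits: tuple[TraitConfig, ...]
    outcome_path: str
    output_dir: str
    publication_strata: tuple[str, ...] = ()
    sex_strata: tuple[str, ...] = ()
    ld_path: str | None = None
    proxy_path: str | None = None
    proxy_records_path: str | None = None
    methods: tuple[str, ...] = ("likelihood", "weighted_median", "egger", "ivw")
    p_threshold: float = 5e-8
    r2_threshold: float = 0.2
    min_pathway_size: int = 5
    alpha: float = 0.05
    n_tests_global: int | None = None
    n_boot: int = 1000
    seed: int = 0
    power_queries: tuple[Mapping[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.traits:
            raise ValueError("at least one trait is required")
        if not (0 < self.p_threshold <= 1) or not (0 < self.r2_threshold <= 1):
            raise ValueError("thresholds out of range")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        known = {"likelihood", "weighted_median", "egger", "ivw"}
        if set(self.methods) - known:
            raise ValueError(f"unknown method(s): {sorted(set(self.methods) - known)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        traits = tuple(
            TraitConfig(name=t["name"], exposure_path=t["exposure_path"],
                        exclusion_snps=tuple(t.get("exclusion_snps", ())))
            for t in raw.pop("traits")
        )
        for key in ("publication_strata", "sex_strata", "methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "power_queries" in raw:
            raw["power_queries"] = tuple(raw["power_queries"])
        return cls(traits=traits, **raw)


@dataclass
class ResultBundle:
    """Everything one run produces, plus stage-count bookkeeping."""

    results: pd.DataFrame          # tidy estimate rows incl. meta rows
    funnel_tables: dict[str, pd.DataFrame]
    pathway_table: pd.DataFrame
    power_table: pd.DataFrame
    counts: dict[str, dict[str, int]]   # trait -> stage counts
    log_events: list[dict]


def _missing_paths(config: AnalysisConfig) -> list[str]:
    paths = [t.exposure_path for t in config.traits] + [config.outcome_path]
    for p in (config.ld_path, config.proxy_path, config.proxy_records_path):
        if p is not None:
            paths.append(p)
    return [p for p in paths if not Path(p).exists()]


def _estimate_row(trait: str, stratum: str, est: MREstimate) -> dict:
    return {
        "trait": trait, "stratum": stratum, "method": est.method, "n_snps": est.n_snps,
        "beta": est.beta, "se": est.se, "or": est.or_, "ci_low": est.ci_low,
        "ci_high": est.ci_high, "pvalue": est.pvalue,
        "intercept": est.intercept, "intercept_se": est.intercept_se,
        "intercept_ci_low": est.intercept_ci_low, "intercept_ci_high": est.intercept_ci_high,
        "q": None, "df": None, "i2": None, "p_het": None,
    }


def _meta_row(trait: str, group: str, meta: MetaResult) -> dict:
    lo, hi = meta.ci_pooled
    return {
        "trait": trait, "stratum": f"meta_{group}", "method": "fixed_effect_meta",
        "n_snps": None, "beta": meta.beta_pooled, "se": meta.se_pooled,
        "or": meta.or_pooled, "ci_low": lo, "ci_high": hi, "pvalue": None,
        "intercept": None, "intercept_se": None, "intercept_ci_low": None,
        "intercept_ci_high": None,
        "q": meta.q, "df": meta.df, "i2": meta.i2, "p_het": meta.p_het,
    }


def _run_method(method: str, hs: Sequence[HarmonizedInstrument],
                config: AnalysisConfig) -> MREstimate:
    if method == "likelihood":
        return mr_core.likelihood_mr(hs)
    if method == "ivw":
        return mr_core.ivw_estimate(hs)
    if method == "egger":
        return mr_core.egger_mr(hs)
    if method == "weighted_median":
        return mr_core.weighted_median_mr(hs, n_boot=config.n_boot, seed=config.seed)
    raise ValueError(method)


def run_full_analysis(config: AnalysisConfig) -> ResultBundle:
    """Execute the configured workflow and write all output tables.

    Outputs under ``config.output_dir``: ``results.tsv`` (estimate and meta
    rows), ``funnel_<trait>.tsv``, ``pathways.tsv``, ``power.tsv`` and
    ``run_log.jsonl``.  Missing input paths fail before any computation;
    per-trait estimator failures are recorded as log events and the run
    continues.
    """
    missing = _missing_paths(config)
    if missing:
        raise FileNotFoundError(f"missing input path(s): {', '.join(missing)}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log: list[dict] = []

    def event(kind: str, **data) -> None:
        log.append({"event": kind, **data})

    ld = read_ld_table(config.ld_path) if config.ld_path else LdMatrix()
    proxies = (read_proxy_table(config.proxy_path, config.proxy_records_path)
               if config.proxy_path and config.proxy_records_path else None)

    outcome_all = read_summary_table(config.outcome_path, "outcome")
    by_stratum: dict[str, list] = {}
    for rec in outcome_all:
        by_stratum.setdefault(rec.stratum, []).append(rec)
    if "overall" in by_stratum:
        outcome_overall = by_stratum["overall"]
    elif config.publication_strata:
        # Default order of operations: pool the per-set beta_gd first, then MR.
        outcome_overall = pool_outcome_strata(
            [r for s in config.publication_strata for r in by_stratum.get(s, [])])
        event("pooled_outcome", strata=list(config.publication_strata),
              n_snps=len(outcome_overall))
    else:
        raise ValueError("outcome table has no 'overall' stratum and no "
                         "publication_strata configured to pool")

    rows: list[dict] = []
    counts: dict[str, dict[str, int]] = {}
    funnel_tables: dict[str, pd.DataFrame] = {}
    pathway_rows: list[dict] = []

    for trait in config.traits:
        exposures = read_summary_table(trait.exposure_path, "exposure", trait_id=trait.name)
        n_in = len(exposures)
        selected = select_instruments(exposures, config.p_threshold, ld, config.r2_threshold)
        event("selected_instruments", trait=trait.name, n_in=n_in, n_kept=len(selected))
        curated, actions = resolve_ambiguous_alleles(selected, proxies)
        for a in actions:
            event("ambiguous_allele", trait=trait.name, snp=a.snp_id, action=a.action,
                  reason=a.reason, proxy=a.proxy_id)

        hs, drops = harmonize(curated, outcome_overall)
        for d in drops:
            event("harmonization_drop", trait=trait.name, snp=d.snp_id, reason=d.reason)
        counts[trait.name] = {
            "input": n_in,
            "failed_selection": n_in - len(selected),
            "ambiguous_dropped": sum(a.action == "dropped" for a in actions),
            "harmonization_dropped": len(drops),
            "analyzed": len(hs),
        }
        if not hs:
            event("trait_skipped", trait=trait.name, reason="no harmonized instruments")
            continue

        for method in config.methods:
            try:
                est = _run_method(method, hs, config)
            except Exception as exc:  # recorded, not fatal
                event("estimator_failure", trait=trait.name, stratum="overall",
                      method=method, error=str(exc))
                continue
            rows.append(_estimate_row(trait.name, "overall", est))

        for group, labels in (("publication", config.publication_strata),
                              ("sex", config.sex_strata)):
            stratum_ests: list[StratumEstimate] = []
            for label in labels:
                outcome_s = by_stratum.get(label, [])
                hs_s, _ = harmonize(curated, outcome_s)
                if not hs_s:
                    event("stratum_skipped", trait=trait.name, stratum=label,
                          reason="no harmonized instruments")
                    continue
                try:
                    est = mr_core.likelihood_mr(hs_s)
                except Exception as exc:
                    event("estimator_failure", trait=trait.name, stratum=label,
                          method="likelihood", error=str(exc))
                    continue
                rows.append(_estimate_row(trait.name, label, est))
                stratum_ests.append(StratumEstimate(label, est.beta, est.se))
            if len(stratum_ests) >= 2:
                rows.append(_meta_row(trait.name, group, fixed_effect_meta(stratum_ests)))

        if trait.exclusion_snps:
            kept, removed = exclude_snps(hs, trait.exclusion_snps)
            event("overlap_exclusion", trait=trait.name, n_removed=len(removed),
                  removed=sorted(removed))
            if kept:
                try:
                    est = mr_core.likelihood_mr(kept)
                    row = _estimate_row(trait.name, "overall_excl_overlap", est)
                    rows.append(row)
                except Exception as exc:
                    event("estimator_failure", trait=trait.name,
                          stratum="overall_excl_overlap", method="likelihood",
                          error=str(exc))

        fdata = funnel_data(hs, overlap=trait.exclusion_snps)
        funnel_tables[trait.name] = pd.DataFrame({
            "snp": [p.snp_id for p in fdata.points],
            "risk_increase": [p.risk_increase for p in fdata.points],
            "strength": [p.strength for p in fdata.points],
            "bmi_overlap": [p.bmi_overlap for p in fdata.points],
        })

        if config.n_tests_global and any(h.pathway for h in hs):
            presults, skipped = pathway_subset_mr(
                hs, min_size=config.min_pathway_size, alpha=config.alpha,
                n_tests_global=config.n_tests_global)
            for label, n in skipped.items():
                event("pathway_skipped", trait=trait.name, pathway=label, n_snps=n)
            for pr in presults:
                pathway_rows.append({
                    "trait": trait.name, "pathway": pr.pathway, "n_snps": pr.n_snps,
                    "or": pr.estimate.or_, "ci_low": pr.estimate.ci_low,
                    "ci_high": pr.estimate.ci_high, "pvalue": pr.estimate.pvalue,
                    "threshold": pr.bonferroni_threshold, "significant": pr.significant,
                })

    power_rows = []
    for query in config.power_queries:
        q = PowerQuery(**query)
        power_rows.append({**query, "power": mr_power_binary(q)})

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    pathway_table = pd.DataFrame(
        pathway_rows, columns=["trait", "pathway", "n_snps", "or", "ci_low",
                               "ci_high", "pvalue", "threshold", "significant"])
    power_table = pd.DataFrame(power_rows)

    results.to_csv(outdir / "results.tsv", sep="\t", index=False, lineterminator="\n")
    pathway_table.to_csv(outdir / "pathways.tsv", sep="\t", index=False, lineterminator="\n")
    power_table.to_csv(outdir / "power.tsv", sep="\t", index=False, lineterminator="\n")
    for name, table in funnel_tables.items():
        table.to_csv(outdir / f"funnel_{name}.tsv", sep="\t", index=False, lineterminator="\n")
    event("run_complete", n_traits=len(config.traits), n_result_rows=len(results))
    with open(outdir / "run_log.jsonl", "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")

    return ResultBundle(results=results, funnel_tables=funnel_tables,
                        pathway_table=pathway_table, power_table=power_table,
                        counts=counts, log_events=log)
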