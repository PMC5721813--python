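"""Summary-statistics I/O, instrument curation and allele harmonization.

Two-sample Mendelian randomization works from per-SNP association summary
statistics: for each candidate instrument, the SNP-to-exposure effect
``beta_gp`` (per allele, in standard-deviation units of the trait) with its
standard error, and the SNP-to-disease effect ``beta_gd`` (per allele, on the
log-odds scale) with its standard error.  Before any causal estimation the two
tables must be curated — genome-wide-significant, mutually independent SNPs
only, strand-ambiguous (palindromic) variants replaced by tight proxies or
removed — and harmonized so that both effects refer to the same allele,
conventionally the trait-increasing one.

This module provides the record types, tab-separated table readers/writers,
LD-based instrument selection, palindromic-SNP resolution, unit recalibration,
and pairwise harmonization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ExposureInstrument",
    "OutcomeAssociation",
    "HarmonizedInstrument",
    "LdMatrix",
    "ProxyInstrument",
    "CurationAction",
    "HarmonizationDrop",
    "SchemaError",
    "RowParseError",
    "read_summary_table",
    "write_summary_table",
    "read_ld_table",
    "read_proxy_table",
    "select_instruments",
    "resolve_ambiguous_alleles",
    "rescale_to_sd_units",
    "harmonize_pair",
    "harmonize",
    "exclude_snps",
]

_VALID_ALLELES = frozenset({"A", "C", "G", "T"})
_PALINDROMIC_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))

EXPOSURE_COLUMNS = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")
EXPOSURE_OPTIONAL = ("eaf", "pathway")
OUTCOME_COLUMNS = ("snp", "effect_allele", "other_allele", "beta", "se")
OUTCOME_OPTIONAL = ("stratum",)


class SchemaError(ValueError):
    """A mapped column is missing from the table header."""


class RowParseError(ValueError):
    """A data row violates a type invariant; the message names the row."""


def _check_allele(value: str, name: str) -> str:
    allele = str(value).strip().upper()
    if allele not in _VALID_ALLELES:
        raise ValueError(f"{name} must be one of A/C/G/T, got {value!r}")
    return allele


@dataclass(frozen=True)
class ExposureInstrument:
    """Per-SNP exposure association from the discovery GWAS.

    ``beta_gp`` is the per-allele effect in SD units of the trait; ``pathway``
    is an optional mechanistic-pathway label carried through to subset tests.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_gp: float
    se_gp: float
    pvalue: float
    eaf: float | None = None
    pathway: str | None = None
    trait_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", _check_allele(self.effect_allele, "effect_allele"))
        object.__setattr__(self, "other_allele", _check_allele(self.other_allele, "other_allele"))
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not math.isfinite(self.beta_gp):
            raise ValueError(f"{self.snp_id}: beta_gp must be finite")
        if not (self.se_gp > 0 and math.isfinite(self.se_gp)):
            raise ValueError(f"{self.snp_id}: se_gp must be positive")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.snp_id}: pvalue must lie in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.snp_id}: eaf must lie in [0, 1]")

    @property
    def is_palindromic(self) -> bool:
        return frozenset({self.effect_allele, self.other_allele}) in _PALINDROMIC_PAIRS


@dataclass(frozen=True)
class OutcomeAssociation:
    """Per-SNP disease association (log odds ratio per effect allele)."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_gd: float
    se_gd: float
    stratum: str = "overall"

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", _check_allele(self.effect_allele, "effect_allele"))
        object.__setattr__(self, "other_allele", _check_allele(self.other_allele, "other_allele"))
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not math.isfinite(self.beta_gd):
            raise ValueError(f"{self.snp_id}: beta_gd must be finite")
        if not (self.se_gd > 0 and math.isfinite(self.se_gd)):
            raise ValueError(f"{self.snp_id}: se_gd must be positive")

    @property
    def is_palindromic(self) -> bool:
        return frozenset({self.effect_allele, self.other_allele}) in _PALINDROMIC_PAIRS


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Allele-aligned (beta_gp, beta_gd) pair oriented to the trait-increasing allele."""

    snp_id: str
    beta_gp: float
    se_gp: float
    beta_gd: float
    se_gd: float
    flipped: bool = False
    pathway: str | None = None

    def __post_init__(self) -> None:
        if self.beta_gp < 0:
            raise ValueError(f"{self.snp_id}: harmonized beta_gp must be >= 0 (trait-increasing allele)")
        if not (self.se_gp > 0 and self.se_gd > 0):
            raise ValueError(f"{self.snp_id}: standard errors must be positive")


@dataclass(frozen=True)
class ProxyInstrument:
    """A replacement instrument in tight LD with a strand-ambiguous SNP."""

    record: ExposureInstrument
    r2: float

    def __post_init__(self) -> None:
        if not (0 <= self.r2 <= 1):
            raise ValueError("proxy LD r2 must lie in [0, 1]")


@dataclass(frozen=True)
class CurationAction:
    """One logged curation event (drop / replace / keep) with its reason."""

    snp_id: str
    action: str  # "dropped" | "replaced" | "kept"
    reason: str
    proxy_id: str | None = None


@dataclass(frozen=True)
class HarmonizationDrop:
    """Signal that an exposure/outcome pair could not be allele-aligned."""

    snp_id: str
    reason: str


class LdMatrix:
    """Symmetric pairwise LD R-squared lookup over a set of SNPs.

    Backed by a sparse pair dictionary; pairs absent from the table are
    treated as unlinked (R^2 = 0), matching the convention of published GWAS
    instrument lists that arrive already pruned.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset[str], float] = {}
        snp_ids: set[str] = set()
        for (a, b), val in (pairs or {}).items():
            if not (0 <= val <= 1):
                raise ValueError(f"LD r2 for ({a}, {b}) outside [0, 1]: {val}")
            if a == b:
                if val != 1:
                    raise ValueError(f"diagonal LD r2 for {a} must be 1")
                continue
            key = frozenset({a, b})
            prev = self._r2.get(key)
            if prev is not None and abs(prev - val) > 1e-12:
                raise ValueError(f"conflicting LD r2 entries for pair ({a}, {b})")
            self._r2[key] = val
            snp_ids.update((a, b))
        self.snp_ids = sorted(snp_ids)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset({a, b}), 0.0)


def _resolve_schema(columns: Sequence[str], required: Sequence[str],
                    optional: Sequence[str], schema: Mapping[str, str] | None) -> dict[str, str]:
    mapping = {name: name for name in (*required, *optional)}
    if schema:
        mapping.update(schema)
    missing = [mapping[name] for name in required if mapping[name] not in columns]
    if missing:
        raise SchemaError(f"required column(s) missing from table: {', '.join(missing)}")
    return mapping


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    return text or None


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    out = float(value)
    return None if math.isnan(out) else out


def read_summary_table(path: str | Path, kind: str = "exposure",
                       schema: Mapping[str, str] | None = None, sep: str = "\t",
                       trait_id: str = "") -> list[ExposureInstrument] | list[OutcomeAssociation]:
    """Read a delimited summary-statistics table into typed records.

    Parameters
    ----------
    path : file location of a delimited text table with a header row.
    kind : ``"exposure"`` or ``"outcome"``.
    schema : optional mapping from canonical field names (``snp``, ``beta``,
        ``se`` ...) to the column names actually present in the file.
    sep : field delimiter; tab by default.
    trait_id : exposure name stamped onto every record (exposure tables only).

    Rows violating a type invariant are rejected with a row-addressed message.
    """
    path = Path(path)
    if kind not in ("exposure", "outcome"):
        raise ValueError(f"kind must be 'exposure' or 'outcome', got {kind!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = EXPOSURE_COLUMNS if kind == "exposure" else OUTCOME_COLUMNS
    optional = EXPOSURE_OPTIONAL if kind == "exposure" else OUTCOME_OPTIONAL
    cols = _resolve_schema(list(df.columns), required, optional, schema)

    records: list = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # row 1 is the header
        get = lambda name: getattr(row, cols[name]) if cols[name] in df.columns else ""
        try:
            if kind == "exposure":
                records.append(ExposureInstrument(
                    snp_id=str(get("snp")).strip(),
                    effect_allele=get("effect_allele"),
                    other_allele=get("other_allele"),
                    beta_gp=float(get("beta")),
                    se_gp=float(get("se")),
                    pvalue=float(get("pval")),
                    eaf=_opt_float(get("eaf")),
                    pathway=_opt_str(get("pathway")),
                    trait_id=trait_id,
                ))
            else:
                records.append(OutcomeAssociation(
                    snp_id=str(get("snp")).strip(),
                    effect_allele=get("effect_allele"),
                    other_allele=get("other_allele"),
                    beta_gd=float(get("beta")),
                    se_gd=float(get("se")),
                    stratum=_opt_str(get("stratum")) or "overall",
                ))
        except (TypeError, ValueError) as exc:
            raise RowParseError(f"{path.name}, row {i}: {exc}") from exc
    return records


def write_summary_table(records: Sequence[ExposureInstrument] | Sequence[OutcomeAssociation],
                        path: str | Path, kind: str | None = None, sep: str = "\t") -> Path:
    """Write records as a delimited table with a deterministic column order.

    Byte-wise reproducible given the same input.  ``kind`` is only needed for
    an empty record list (header-only file); otherwise it is inferred.
    """
    path = Path(path)
    if records:
        kind = "exposure" if isinstance(records[0], ExposureInstrument) else "outcome"
    elif kind is None:
        raise ValueError("kind must be given to write an empty table")

    if kind == "exposure":
        columns = (*EXPOSURE_COLUMNS, *EXPOSURE_OPTIONAL)
        rows = [
            {
                "snp": r.snp_id, "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "beta": repr(r.beta_gp), "se": repr(r.se_gp), "pval": repr(r.pvalue),
                "eaf": "" if r.eaf is None else repr(r.eaf),
                "pathway": r.pathway or "",
            }
            for r in records
        ]
    else:
        columns = (*OUTCOME_COLUMNS, *OUTCOME_OPTIONAL)
        rows = [
            {
                "snp": r.snp_id, "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "beta": repr(r.beta_gd), "se": repr(r.se_gd), "stratum": r.stratum,
            }
            for r in records
        ]
    df = pd.DataFrame(rows, columns=list(columns))
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")
    return path


def read_ld_table(path: str | Path, sep: str = "\t") -> LdMatrix:
    """Read a long-format LD table with columns snp_a, snp_b, r2."""
    df = pd.read_csv(path, sep=sep)
    for col in ("snp_a", "snp_b", "r2"):
        if col not in df.columns:
            raise SchemaError(f"LD table missing column {col!r}")
    pairs = {(str(a), str(b)): float(v) for a, b, v in zip(df["snp_a"], df["snp_b"], df["r2"])}
    return LdMatrix(pairs)


def read_proxy_table(path: str | Path, proxy_records_path: str | Path,
                     sep: str = "\t", trait_id: str = "") -> dict[str, ProxyInstrument]:
    """Read a (snp, proxy_snp, r2) table plus the proxies' own summary stats."""
    df = pd.read_csv(path, sep=sep)
    for col in ("snp", "proxy_snp", "r2"):
        if col not in df.columns:
            raise SchemaError(f"proxy table missing column {col!r}")
    proxies = {r.snp_id: r for r in read_summary_table(proxy_records_path, "exposure", trait_id=trait_id)}
    out: dict[str, ProxyInstrument] = {}
    for snp, proxy_snp, r2 in zip(df["snp"], df["proxy_snp"], df["r2"]):
        if str(proxy_snp) not in proxies:
            raise SchemaError(f"proxy {proxy_snp} has no record in {proxy_records_path}")
        out[str(snp)] = ProxyInstrument(record=proxies[str(proxy_snp)], r2=float(r2))
    return out


def select_instruments(records: Sequence[ExposureInstrument], p_threshold: float = 5e-8,
                       ld: LdMatrix | None = None, r2_threshold: float = 0.2,
                       ) -> list[ExposureInstrument]:
    """Keep genome-wide-significant, mutually independent instruments.

    SNPs with ``pvalue >= p_threshold`` are discarded; the rest are greedily
    pruned so that no retained pair has LD R^2 >= ``r2_threshold``, the
    smaller-p member of each conflicting pair winning (ties broken by
    lexicographic snp_id).  Output order is deterministic regardless of input
    order.
    """
    ld = ld or LdMatrix()
    significant = [r for r in records if r.pvalue < p_threshold]
    significant.sort(key=lambda r: (r.pvalue, r.snp_id))
    kept: list[ExposureInstrument] = []
    for rec in significant:
        if all(ld.r2(rec.snp_id, k.snp_id) < r2_threshold for k in kept):
            kept.append(rec)
    return kept


def resolve_ambiguous_alleles(records: Sequence[ExposureInstrument],
                              proxy_table: Mapping[str, ProxyInstrument] | None = None,
                              ) -> tuple[list[ExposureInstrument], list[CurationAction]]:
    """Replace or remove strand-ambiguous (A/T, C/G) instruments.

    A palindromic SNP is replaced by its proxy only when the proxy is in tight
    LD (R^2 > 0.8) and is not itself palindromic; otherwise it is dropped.
    Every action is logged in the returned report.
    """
    proxy_table = proxy_table or {}
    kept: list[ExposureInstrument] = []
    report: list[CurationAction] = []
    for rec in records:
        if not rec.is_palindromic:
            kept.append(rec)
            continue
        alleles = f"{rec.effect_allele}/{rec.other_allele}"
        proxy = proxy_table.get(rec.snp_id)
        if proxy is not None and proxy.record.is_palindromic:
            proxy = None  # an ambiguous proxy is no proxy at all
        if proxy is not None and proxy.r2 > 0.8:
            kept.append(proxy.record)
            report.append(CurationAction(rec.snp_id, "replaced",
                                         f"strand-ambiguous {alleles}; proxy in LD r2={proxy.r2:g}",
                                         proxy_id=proxy.record.snp_id))
        else:
            why = "no proxy available" if proxy is None else f"proxy LD r2={proxy.r2:g} <= 0.8"
            report.append(CurationAction(rec.snp_id, "dropped",
                                         f"strand-ambiguous {alleles}; {why}"))
    return kept, report


def rescale_to_sd_units(beta_raw: float, se_raw: float,
                        study_sds: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Recalibrate a per-allele effect from trait units to SD units.

    ``study_sds`` holds (SD, sample size) pairs for the contributing samples;
    the pooled SD is the sample-size-weighted mean of the study SDs, and both
    the effect and its SE are divided by it.
    """
    if not study_sds:
        raise ValueError("at least one (sd, sample_size) pair is required")
    for sd, n in study_sds:
        if sd <= 0 or n <= 0:
            raise ValueError("study SDs and sample sizes must be positive")
    total_n = sum(n for _, n in study_sds)
    pooled_sd = sum(sd * n for sd, n in study_sds) / total_n
    return beta_raw / pooled_sd, se_raw / pooled_sd


def harmonize_pair(exposure: ExposureInstrument, outcome: OutcomeAssociation,
                   ) -> HarmonizedInstrument | HarmonizationDrop:
    """Align an exposure/outcome record pair to the trait-increasing allele.

    If the outcome's alleles are the exposure's swapped, the outcome effect's
    sign is flipped.  If the exposure effect is negative, both effects are
    negated so the harmonized ``beta_gp`` is non-negative.  Irreconcilable
    allele sets yield a :class:`HarmonizationDrop` rather than an exception.
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValueError(f"snp_id mismatch: {exposure.snp_id} vs {outcome.snp_id}")
    if exposure.is_palindromic or outcome.is_palindromic:
        return HarmonizationDrop(exposure.snp_id, "strand-ambiguous alleles; resolve before harmonizing")

    beta_gd = outcome.beta_gd
    flipped = False
    if (outcome.effect_allele, outcome.other_allele) == (exposure.effect_allele, exposure.other_allele):
        pass
    elif (outcome.effect_allele, outcome.other_allele) == (exposure.other_allele, exposure.effect_allele):
        beta_gd = -beta_gd
        flipped = True
    else:
        return HarmonizationDrop(exposure.snp_id, "allele mismatch")

    beta_gp = exposure.beta_gp
    if beta_gp < 0:
        beta_gp, beta_gd = -beta_gp, -beta_gd
    return HarmonizedInstrument(
        snp_id=exposure.snp_id, beta_gp=beta_gp, se_gp=exposure.se_gp,
        beta_gd=beta_gd, se_gd=outcome.se_gd, flipped=flipped, pathway=exposure.pathway,
    )


def harmonize(exposures: Sequence[ExposureInstrument], outcomes: Sequence[OutcomeAssociation],
              ) -> tuple[list[HarmonizedInstrument], list[HarmonizationDrop]]:
    """Harmonize all exposure records against an outcome table keyed by snp_id.

    Exposure SNPs absent from the outcome table are reported as drops.
    """
    by_id = {o.snp_id: o for o in outcomes}
    harmonized: list[HarmonizedInstrument] = []
    drops: list[HarmonizationDrop] = []
    for exp in exposures:
        out = by_id.get(exp.snp_id)
        if out is None:
            drops.append(HarmonizationDrop(exp.snp_id, "absent from outcome table"))
            continue
        result = harmonize_pair(exp, out)
        (harmonized if isinstance(result, HarmonizedInstrument) else drops).append(result)
    return harmonized, drops


def exclude_snps(instruments: Sequence[HarmonizedInstrument], exclusion: Iterable[str],
                 ) -> tuple[list[HarmonizedInstrument], list[str]]:
    """Drop instruments in the exclusion set (e.g. known BMI-associated SNPs).

    Returns the retained instruments in their original order plus the ids
    actually removed.
    """
    exclusion = set(exclusion)
    kept = [h for h in instruments if h.snp_id not in exclusion]
    removed = [h.snp_id for h in instruments if h.snp_id in exclusion]
    return kept, removed
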