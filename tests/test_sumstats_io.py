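"""Curation and harmonization of summary-statistics tables."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causalmr.sumstats_io import (
    CurationAction,
    ExposureInstrument,
    HarmonizationDrop,
    HarmonizedInstrument,
    LdMatrix,
    OutcomeAssociation,
    ProxyInstrument,
    RowParseError,
    SchemaError,
    exclude_snps,
    harmonize_pair,
    read_summary_table,
    rescale_to_sd_units,
    resolve_ambiguous_alleles,
    select_instruments,
    write_summary_table,
)
from conftest import make_exposure, make_harmonized, make_outcome


class TestReadWrite:
    def test_two_row_table_gives_two_records(self, tmp_path):
        path = tmp_path / "exp.tsv"
        path.write_text("snp\teffect_allele\tother_allele\tbeta\tse\tpval\n"
                        "rs1\tA\tG\t0.1\t0.01\t1e-9\n"
                        "rs2\tC\tT\t-0.2\t0.02\t1e-12\n")
        records = read_summary_table(path, "exposure")
        assert len(records) == 2
        assert records[1].beta_gp == -0.2

    def test_missing_se_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("snp\teffect_allele\tother_allele\tbeta\tpval\nrs1\tA\tG\t0.1\t1e-9\n")
        with pytest.raises(SchemaError, match="se"):
            read_summary_table(path, "exposure")

    def test_non_numeric_effect_names_the_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("snp\teffect_allele\tother_allele\tbeta\tse\tpval\n"
                        "rs1\tA\tG\t0.1\t0.01\t1e-9\n"
                        "rs2\tA\tG\tnot_a_number\t0.01\t1e-9\n")
        with pytest.raises(RowParseError, match="row 3"):
            read_summary_table(path, "exposure")

    def test_schema_mapping_renames_columns(self, tmp_path):
        path = tmp_path / "alt.tsv"
        path.write_text("rsid\tEA\tOA\tb\tstderr\tp\nrs1\tA\tG\t0.1\t0.01\t1e-9\n")
        records = read_summary_table(path, "exposure", schema={
            "snp": "rsid", "effect_allele": "EA", "other_allele": "OA",
            "beta": "b", "se": "stderr", "pval": "p"})
        assert records[0].snp_id == "rs1"

    @pytest.mark.parametrize("kind,records", [
        ("exposure", [make_exposure("rs1", eaf=0.3, pathway="adipo"),
                      make_exposure("rs2", beta=-0.04, pval=2e-8)]),
        ("outcome", [make_outcome("rs1", stratum="men"), make_outcome("rs2")]),
    ])
    def test_round_trip_identity(self, tmp_path, kind, records):
        path = write_summary_table(records, tmp_path / "t.tsv")
        assert read_summary_table(path, kind) == records

    def test_write_is_byte_deterministic(self, tmp_path):
        records = [make_exposure("rs1", eaf=0.25), make_exposure("rs2")]
        p1 = write_summary_table(records, tmp_path / "a.tsv")
        p2 = write_summary_table(records, tmp_path / "b.tsv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_list_writes_header_only(self, tmp_path):
        path = write_summary_table([], tmp_path / "empty.tsv", kind="exposure")
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("snp\t")
        assert read_summary_table(path, "exposure") == []

    def test_absent_optional_fields_survive_round_trip_as_absent(self, tmp_path):
        records = [make_exposure("rs1")]  # no eaf, no pathway
        path = write_summary_table(records, tmp_path / "t.tsv")
        back = read_summary_table(path, "exposure")
        assert back[0].eaf is None and back[0].pathway is None


class TestRecordInvariants:
    @pytest.mark.parametrize("kwargs", [
        {"se": -0.01}, {"pval": 0.0}, {"pval": 1.5}, {"ea": "A", "oa": "A"},
        {"ea": "N"}, {"beta": float("nan")},
    ])
    def test_invalid_exposure_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_exposure("rs1", **kwargs)

    def test_harmonized_requires_nonnegative_beta_gp(self):
        with pytest.raises(ValueError):
            make_harmonized("rs1", -0.1, 0.01, 0.05, 0.02)


class TestSelectInstruments:
    def test_threshold_filters_unlinked_snps(self):
        recs = [make_exposure("rs1", pval=1e-9), make_exposure("rs2", pval=1e-7),
                make_exposure("rs3", pval=1e-10)]
        kept = select_instruments(recs, 5e-8, LdMatrix(), 0.2)
        assert {r.snp_id for r in kept} == {"rs1", "rs3"}

    def test_linked_pair_keeps_smaller_p(self):
        recs = [make_exposure("rs1", pval=1e-9), make_exposure("rs2", pval=1e-10)]
        ld = LdMatrix({("rs1", "rs2"): 0.3})
        kept = select_instruments(recs, 5e-8, ld, 0.2)
        assert [r.snp_id for r in kept] == ["rs2"]

    def test_empty_input_empty_output(self):
        assert select_instruments([], 5e-8, LdMatrix(), 0.2) == []

    def test_pruning_matches_exhaustive_pair_check(self):
        # Independent oracle: the output must satisfy the postcondition against
        # every pair, and every discarded significant SNP must conflict with a
        # kept SNP of smaller (p, id).
        recs = [make_exposure(f"rs{k}", pval=p) for k, p in
                enumerate([1e-9, 3e-9, 1e-12, 5e-10, 2e-8, 4e-8])]
        pairs = {("rs0", "rs1"): 0.5, ("rs2", "rs3"): 0.25, ("rs0", "rs4"): 0.9,
                 ("rs1", "rs5"): 0.1}
        ld = LdMatrix(pairs)
        kept = select_instruments(recs, 5e-8, ld, 0.2)
        kept_ids = [r.snp_id for r in kept]
        for a, b in itertools.combinations(kept_ids, 2):
            assert ld.r2(a, b) < 0.2
        by_id = {r.snp_id: r for r in recs}
        for rec in recs:
            if rec.snp_id in kept_ids or rec.pvalue >= 5e-8:
                continue
            conflicts = [k for k in kept_ids if ld.r2(rec.snp_id, k) >= 0.2]
            assert conflicts, f"{rec.snp_id} discarded without a conflicting kept SNP"
            assert any((by_id[k].pvalue, k) < (rec.pvalue, rec.snp_id) for k in conflicts)

    def test_output_invariant_to_input_order(self):
        recs = [make_exposure(f"rs{k}", pval=p) for k, p in
                enumerate([1e-9, 1e-9, 1e-12, 5e-10])]
        ld = LdMatrix({("rs0", "rs1"): 0.4})
        baseline = select_instruments(recs, 5e-8, ld, 0.2)
        for perm in itertools.permutations(recs):
            assert select_instruments(list(perm), 5e-8, ld, 0.2) == baseline


class TestAmbiguousAlleles:
    def test_palindromic_without_proxy_dropped_and_logged(self):
        recs = [make_exposure("rs1", ea="A", oa="T")]
        kept, report = resolve_ambiguous_alleles(recs)
        assert kept == []
        assert report[0].action == "dropped" and "A/T" in report[0].reason

    def test_palindromic_with_tight_proxy_replaced(self):
        recs = [make_exposure("rs1", ea="C", oa="G")]
        proxy = ProxyInstrument(record=make_exposure("rs9", ea="A", oa="G"), r2=0.9)
        kept, report = resolve_ambiguous_alleles(recs, {"rs1": proxy})
        assert [r.snp_id for r in kept] == ["rs9"]
        assert report[0].action == "replaced" and report[0].proxy_id == "rs9"

    def test_loose_proxy_not_used(self):
        recs = [make_exposure("rs1", ea="C", oa="G")]
        proxy = ProxyInstrument(record=make_exposure("rs9"), r2=0.8)  # not > 0.8
        kept, report = resolve_ambiguous_alleles(recs, {"rs1": proxy})
        assert kept == [] and report[0].action == "dropped"

    def test_ambiguous_proxy_treated_as_unavailable(self):
        recs = [make_exposure("rs1", ea="A", oa="T")]
        proxy = ProxyInstrument(record=make_exposure("rs9", ea="C", oa="G"), r2=0.95)
        kept, report = resolve_ambiguous_alleles(recs, {"rs1": proxy})
        assert kept == [] and report[0].action == "dropped"

    def test_unambiguous_snp_retained_unchanged(self):
        recs = [make_exposure("rs1", ea="A", oa="G")]
        kept, report = resolve_ambiguous_alleles(recs)
        assert kept == recs and report == []


class TestRescale:
    def test_single_study_division(self):
        beta, se = rescale_to_sd_units(0.5, 0.05, [(4.6, 1000)])
        assert beta == pytest.approx(0.5 / 4.6)
        assert se == pytest.approx(0.05 / 4.6)

    def test_sample_size_weighted_pooled_sd(self):
        beta, _ = rescale_to_sd_units(1.0, 0.1, [(4, 100), (5, 300)])
        assert beta == pytest.approx(1.0 / 4.75)

    def test_identity_when_already_sd_units(self):
        assert rescale_to_sd_units(0.3, 0.02, [(1.0, 500)]) == pytest.approx((0.3, 0.02))

    def test_empty_study_list_errors(self):
        with pytest.raises(ValueError):
            rescale_to_sd_units(0.5, 0.05, [])

    @given(c=st.floats(0.1, 100), beta=st.floats(-2, 2), se=st.floats(0.001, 1),
           sd=st.floats(0.5, 50))
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, c, beta, se, sd):
        base = rescale_to_sd_units(beta, se, [(sd, 100)])
        scaled = rescale_to_sd_units(beta * c, se * c, [(sd * c, 100)])
        assert scaled[0] == pytest.approx(base[0], rel=1e-9)
        assert scaled[1] == pytest.approx(base[1], rel=1e-9)


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_sign(self):
        exp = make_exposure("rs1", beta=0.1, ea="A", oa="G")
        out = make_outcome("rs1", beta=0.10, ea="G", oa="A")
        h = harmonize_pair(exp, out)
        assert isinstance(h, HarmonizedInstrument)
        assert h.beta_gd == pytest.approx(-0.10) and h.flipped

    def test_negative_exposure_effect_reorients_both(self):
        exp = make_exposure("rs1", beta=-0.05, ea="A", oa="G")
        out = make_outcome("rs1", beta=0.02, ea="A", oa="G")
        h = harmonize_pair(exp, out)
        assert (h.beta_gp, h.beta_gd) == pytest.approx((0.05, -0.02))
        assert not h.flipped

    def test_irreconcilable_alleles_drop(self):
        exp = make_exposure("rs1", ea="A", oa="G")
        out = make_outcome("rs1", ea="C", oa="T")
        result = harmonize_pair(exp, out)
        assert isinstance(result, HarmonizationDrop)
        assert result.reason == "allele mismatch"

    def test_palindromic_input_refused(self):
        exp = make_exposure("rs1", ea="A", oa="T")
        out = make_outcome("rs1", ea="A", oa="T")
        assert isinstance(harmonize_pair(exp, out), HarmonizationDrop)

    def test_harmonization_is_idempotent(self):
        exp = make_exposure("rs1", beta=-0.07, ea="T", oa="C")
        out = make_outcome("rs1", beta=0.03, ea="C", oa="T")
        h1 = harmonize_pair(exp, out)
        # Re-express the harmonized pair as records and harmonize again.
        exp2 = make_exposure("rs1", beta=h1.beta_gp, se=h1.se_gp, ea="A", oa="G")
        out2 = make_outcome("rs1", beta=h1.beta_gd, se=h1.se_gd, ea="A", oa="G")
        h2 = harmonize_pair(exp2, out2)
        assert (h2.beta_gp, h2.beta_gd) == (h1.beta_gp, h1.beta_gd)
        assert not h2.flipped

    @given(flip_exposure=st.booleans(), flip_outcome=st.booleans(),
           beta=st.floats(0.01, 0.5), gd=st.floats(-0.3, 0.3))
    @settings(max_examples=60, derandomize=True)
    def test_wald_ratio_invariant_to_allele_encoding(self, flip_exposure, flip_outcome,
                                                     beta, gd):
        """The causal ratio must not depend on which allele either study
        chose to report: allele A truly raises the trait by ``beta`` and the
        log-odds by ``gd``, and each study independently encodes A or G as
        its effect allele."""
        exp_beta, exp_ea, exp_oa = (-beta, "G", "A") if flip_exposure else (beta, "A", "G")
        out_beta, out_ea, out_oa = (-gd, "G", "A") if flip_outcome else (gd, "A", "G")
        h = harmonize_pair(
            make_exposure("rs1", beta=exp_beta, ea=exp_ea, oa=exp_oa),
            make_outcome("rs1", beta=out_beta, ea=out_ea, oa=out_oa))
        # Reference: both studies report allele A.
        h0 = harmonize_pair(make_exposure("rs1", beta=beta, ea="A", oa="G"),
                            make_outcome("rs1", beta=gd, ea="A", oa="G"))
        assert h.beta_gd / h.beta_gp == pytest.approx(h0.beta_gd / h0.beta_gp, rel=1e-12)


class TestExclude:
    def test_exclusion_counts_reported(self):
        hs = [make_harmonized(f"rs{k}", 0.1, 0.01, 0.05, 0.02) for k in range(17)]
        kept, removed = exclude_snps(hs, {"rs1", "rs5", "rs9"})
        assert len(kept) == 14 and sorted(removed) == ["rs1", "rs5", "rs9"]
        assert [h.snp_id for h in kept] == [f"rs{k}" for k in range(17)
                                            if k not in (1, 5, 9)]

    def test_empty_exclusion_is_identity(self):
        hs = [make_harmonized("rs1", 0.1, 0.01, 0.05, 0.02)]
        assert exclude_snps(hs, set()) == (hs, [])


class TestLdMatrix:
    def test_symmetry_and_defaults(self):
        ld = LdMatrix({("a", "b"): 0.5})
        assert ld.r2("b", "a") == 0.5
        assert ld.r2("a", "c") == 0.0
        assert ld.r2("a", "a") == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            LdMatrix({("a", "b"): 1.2})
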