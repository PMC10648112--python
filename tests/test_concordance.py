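"""Orthogonal-assay pairing, PPA, VAF regression, timepoint comparison."""

import pytest

from ctdnaval import concordance as conc
from ctdnaval.concordance import (
    Llods,
    PairClass,
    PanelSpec,
    build_pairs,
    classify_variant_table,
    compare_timepoints,
    ppa,
    ppa_from_variant_table,
    vaf_correlation,
    variant_table_correlation,
)
from ctdnaval.metrics import UndefinedMetricError
from ctdnaval.variants import (
    Classification,
    VariantCall,
    VariantKey,
    VariantModelError,
)

C = Classification


def call(pos=100, vaf=10.0, gene="TP53", cls=C.PATHOGENIC, sample=""):
    return VariantCall(
        key=VariantKey("chr1", pos, "A", "G"),
        sample_id=sample,
        gene=gene,
        vaf_percent=vaf,
        alt_reads=int(vaf * 10),
        depth=1000,
        classification=cls,
    )


class TestBuildPairs:
    def test_concordant_positive(self):
        pairs = build_pairs({"P1": [call(vaf=17.07)]}, {"P1": [call(vaf=19.8)]})
        assert pairs[0].concordance_class is PairClass.CONCORDANT_POSITIVE

    def test_test_only_when_comparator_missed(self):
        pairs = build_pairs({"P1": [call(vaf=14.3)]}, {"P1": []})
        assert pairs[0].concordance_class is PairClass.TEST_ONLY

    def test_ortho_only_requires_ortho_above_llod(self):
        pairs = build_pairs({"P1": []}, {"P1": [call(vaf=0.2)]})
        assert pairs[0].concordance_class is PairClass.EXCLUDED_BELOW_LLOD
        pairs = build_pairs({"P1": []}, {"P1": [call(vaf=0.3)]})
        assert pairs[0].concordance_class is PairClass.ORTHO_ONLY

    def test_off_panel_gene_excluded(self):
        pairs = build_pairs({"P1": []}, {"P1": [call(gene="POLE", vaf=5.0)]})
        assert pairs[0].concordance_class is PairClass.EXCLUDED_OFF_PANEL

    def test_duplicate_key_per_patient_is_error(self):
        with pytest.raises(VariantModelError):
            build_pairs({"P1": [call(), call()]}, {})

    def test_classes_partition_all_candidates(self):
        test = {"P1": [call(pos=1, vaf=5), call(pos=2, vaf=0.1)], "P2": [call(pos=3, vaf=2)]}
        ortho = {"P1": [call(pos=1, vaf=5), call(pos=4, vaf=1)], "P2": []}
        pairs = build_pairs(test, ortho)
        seen = {(p.patient_id, p.key) for p in pairs}
        assert len(seen) == len(pairs) == 4  # every candidate exactly once

    def test_panel_spec_shared_excludes_uncovered(self):
        spec = PanelSpec()
        assert len(spec.test_genes) == 33
        assert {"BRIP1", "CSF1R", "POLD1", "POLE"} & spec.shared_genes == set()


class TestPpa:
    def test_counts(self):
        pairs = build_pairs(
            {"P1": [call(pos=i, vaf=10) for i in range(1, 41)]},
            {"P1": [call(pos=i, vaf=10) for i in range(1, 49)]},
        )
        res = ppa(pairs)
        assert (res.concordant, res.ortho_only) == (40, 8)
        assert res.percent == pytest.approx(83.3, abs=0.05)

    def test_no_misses_gives_unity(self):
        pairs = build_pairs({"P1": [call(vaf=5)]}, {"P1": [call(vaf=5)]})
        assert ppa(pairs).ratio == 1.0

    def test_undefined_without_ortho_positives(self):
        pairs = build_pairs({"P1": [call(vaf=5)]}, {"P1": []})
        with pytest.raises(UndefinedMetricError):
            ppa(pairs)

    def test_restrict_clinical_drops_vus(self):
        pairs = build_pairs({"P1": []}, {"P1": [call(vaf=5, cls=C.VUS), call(pos=7, vaf=5)]})
        res = ppa(pairs, restrict_clinical=True)
        assert res.denominator == 1


class TestVariantTable:
    def test_printed_ppa_both_pipelines(self, table3_rows):
        std = ppa_from_variant_table(table3_rows, "standard")
        ldt = ppa_from_variant_table(table3_rows, "ldt")
        assert (std.concordant, std.ortho_only) == (40, 8)
        assert (ldt.concordant, ldt.ortho_only) == (44, 4)
        assert round(std.percent, 1) == 83.3
        assert round(ldt.percent, 1) == 91.7

    def test_matches_packaged_summary(self, table3_rows):
        from ctdnaval.fixtures import load_table4

        table4 = load_table4()
        for mode in ("standard", "ldt"):
            res = ppa_from_variant_table(table3_rows, mode)
            assert (res.concordant, res.ortho_only) == (
                table4[mode].concordant,
                table4[mode].ortho_only,
            )

    def test_rescue_only_improves_ppa(self, table3_rows):
        std = ppa_from_variant_table(table3_rows, "standard")
        ldt = ppa_from_variant_table(table3_rows, "ldt")
        assert ldt.ratio >= std.ratio - 1e-12 or ldt.concordant >= std.concordant

    def test_rescued_rows_flip_to_concordant(self, table3_rows):
        """The germline/repeat/complex/unspecified-filtered clinically
        significant rows are comparator-only under the standard pipeline and
        concordant under the LDT pipeline."""
        std = dict(
            ((r.patient_id, r.cdna_change), pc)
            for r, pc in classify_variant_table(table3_rows, "standard")
        )
        ldt = dict(
            ((r.patient_id, r.cdna_change), pc)
            for r, pc in classify_variant_table(table3_rows, "ldt")
        )
        rescued = [
            r
            for r in table3_rows
            if r.filter_reason
            and r.classification in {C.PATHOGENIC, C.LIKELY_PATHOGENIC}
            and (r.filter_reason == "G" or (r.test_vaf_unfiltered_percent or 0) >= 10)
        ]
        assert len(rescued) == 6
        for r in rescued:
            key = (r.patient_id, r.cdna_change)
            assert std[key] is PairClass.ORTHO_ONLY
            assert ldt[key] is PairClass.CONCORDANT_POSITIVE

    def test_below_cutoff_rows_lost_by_ldt(self, table3_rows):
        ldt = classify_variant_table(table3_rows, "ldt")
        blues = [(r, pc) for r, pc in ldt if r.below_ldt_cutoff]
        assert len(blues) == 2
        assert all(pc is PairClass.ORTHO_ONLY for _, pc in blues)

    def test_correlation_reproduces_reported_fit(self, table3_rows):
        fit = variant_table_correlation(table3_rows)
        assert fit.n_points == 67
        assert fit.slope == pytest.approx(0.9626, abs=0.02)
        assert fit.r_squared == pytest.approx(0.9676, abs=0.01)


class TestVafCorrelation:
    def test_identical_vafs(self):
        fit = vaf_correlation([(1.0, 1.0), (5.0, 5.0), (20.0, 20.0)])
        assert fit.slope == pytest.approx(1.0) and fit.r_squared == pytest.approx(1.0)

    def test_anticorrelated_negative_slope(self):
        assert vaf_correlation([(1.0, 30.0), (10.0, 20.0), (30.0, 1.0)]).slope < 0

    def test_order_invariant(self):
        pairs = [(1.0, 2.0), (5.0, 4.5), (20.0, 21.0)]
        assert vaf_correlation(pairs).slope == vaf_correlation(pairs[::-1]).slope

    def test_too_few_pairs(self):
        with pytest.raises(VariantModelError):
            vaf_correlation([(1.0, 1.0)])


class TestCompareTimepoints:
    def test_paired_deltas(self):
        pre = [call(pos=1, vaf=73.48, gene="APC", sample="MM-015"),
               call(pos=2, vaf=69.0, gene="BRAF", sample="MM-015")]
        post = [call(pos=1, vaf=0.94, gene="APC", sample="MM-015"),
                call(pos=2, vaf=2.19, gene="BRAF", sample="MM-015")]
        deltas = {d.gene: d for d in compare_timepoints(pre, post)}
        assert deltas["APC"].pre_vaf_percent == 73.48
        assert deltas["APC"].post_vaf_percent == 0.94
        assert deltas["APC"].absolute_change == pytest.approx(-72.54)

    def test_one_sided_detection_kept_with_zero(self):
        pre = [call(pos=1, vaf=38.0, gene="EGFR", sample="HN-008")]
        deltas = compare_timepoints(pre, [], patient_id="HN-008")
        assert deltas[0].post_vaf_percent == 0.0
        assert deltas[0].relative_change == pytest.approx(-1.0)

    def test_identical_reports_zero_deltas(self):
        pre = [call(pos=1, vaf=5.0, sample="X")]
        assert all(d.absolute_change == 0 for d in compare_timepoints(pre, pre))

    def test_patient_mismatch_is_error(self):
        with pytest.raises(VariantModelError):
            compare_timepoints([call(sample="A")], [call(sample="B")])
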