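"""Tiered performance metrics: counts, LoD-95, linearity, ANOVA."""

import numpy as np
import pytest
from scipy import stats

from ctdnaval.metrics import (
    NOT_REACHED,
    DetectionCount,
    UndefinedMetricError,
    detection_probability,
    input_anova,
    linearity_fit,
    lod95,
    ppv,
    replicate_concordance,
    sensitivity,
    specificity,
    tally_detections,
)
from ctdnaval.variants import (
    Classification,
    FilterStatus,
    LibraryRun,
    VariantCall,
    VariantKey,
    VariantModelError,
    VariantType,
)


def dc(detected, total, vt=VariantType.SNV, tier=0.5, ng=50):
    return DetectionCount(vt, tier, ng, detected, total)


class TestCountRatios:
    @pytest.mark.parametrize(
        "detected,total,expected",
        [(43, 45, 43 / 45), (19, 27, 19 / 27), (0, 45, 0.0), (45, 45, 1.0)],
    )
    def test_sensitivity_exact_fraction(self, detected, total, expected):
        assert sensitivity(dc(detected, total)) == expected

    def test_sensitivity_zero_total_undefined(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(dc(0, 0))

    @pytest.mark.parametrize(
        "tp,fp,expected", [(252, 7, 252 / 259), (249, 9, 249 / 258), (5, 0, 1.0)]
    )
    def test_ppv(self, tp, fp, expected):
        assert ppv(tp, fp) == expected

    def test_ppv_undefined(self):
        with pytest.raises(UndefinedMetricError):
            ppv(0, 0)


class TestLod95:
    def test_snv_profile_selects_half_percent(self):
        prof = {0.125: 0.355, 0.25: 0.733, 0.5: 0.955, 1: 1.0, 2: 1.0}
        assert lod95(prof) == 0.5

    def test_indels_not_reached(self):
        prof = {0.125: 0.185, 0.25: 0.333, 0.5: 0.593, 1: 0.704, 2: 0.778}
        assert lod95(prof) == NOT_REACHED

    def test_all_tiers_pass_returns_smallest(self):
        assert lod95({0.125: 1.0, 0.5: 1.0, 2: 1.0}) == 0.125

    def test_non_monotone_profile_requires_all_larger_tiers(self):
        # a dip at 1% invalidates the passing 0.5% tier
        assert lod95({0.5: 0.96, 1: 0.90, 2: 1.0}) == 2

    def test_accepts_detection_count_rows(self):
        rows = [dc(45, 45, tier=2), dc(45, 45, tier=1), dc(43, 45, tier=0.5), dc(33, 45, tier=0.25)]
        assert lod95(rows) == 0.5

    def test_empty_is_error(self):
        with pytest.raises(VariantModelError):
            lod95({})


def make_run(panel, detected_keys, tier, ng=50, library_id="lib"):
    """Construct a run where exactly ``detected_keys`` are reportable PASS
    calls; homopolymer indels are always emitted RPT-filtered (undetectable)."""
    calls = []
    for tv in panel:
        if tv.homopolymer_context:
            calls.append(
                VariantCall(
                    key=tv.key, gene=tv.gene, vaf_percent=max(tier, 0.25), alt_reads=50,
                    depth=5000, filter_status=FilterStatus.RPT,
                )
            )
        elif tv.key in detected_keys:
            calls.append(
                VariantCall(
                    key=tv.key, gene=tv.gene, vaf_percent=max(tier, 0.25), alt_reads=50,
                    depth=5000, filter_status=FilterStatus.PASS,
                )
            )
    return LibraryRun(library_id=library_id, input_ng=ng, tier_vaf_percent=tier, calls=calls)


class TestTallyDetections:
    def test_full_detection_over_three_replicates(self, truth_panel):
        keys = {tv.key for tv in truth_panel}
        runs = [make_run(truth_panel, keys, 1.0, library_id=f"r{i}") for i in range(3)]
        rows = {r.variant_type: r for r in tally_detections(runs, truth_panel)}
        assert rows[VariantType.SNV].detected == 45 and rows[VariantType.SNV].total == 45
        # the two homopolymer indels are RPT-filtered: ceiling 7/9 per run
        assert rows[VariantType.INDEL].detected == 21 and rows[VariantType.INDEL].total == 27

    def test_engineered_misses_counted(self, truth_panel):
        snv_keys = [tv.key for tv in truth_panel if tv.variant_type is VariantType.SNV]
        all_keys = {tv.key for tv in truth_panel}
        runs = [
            make_run(truth_panel, all_keys - set(snv_keys[:2]), 0.5, library_id="r0"),
            make_run(truth_panel, all_keys, 0.5, library_id="r1"),
            make_run(truth_panel, all_keys, 0.5, library_id="r2"),
        ]
        rows = {r.variant_type: r for r in tally_detections(runs, truth_panel)}
        assert (rows[VariantType.SNV].detected, rows[VariantType.SNV].total) == (43, 45)

    def test_conservation(self, truth_panel):
        keys = {tv.key for tv in truth_panel if tv.variant_type is VariantType.SNV}
        runs = [make_run(truth_panel, keys, 0.25, library_id=f"r{i}") for i in range(4)]
        for row in tally_detections(runs, truth_panel):
            assert 0 <= row.detected <= row.total
            n_type = sum(1 for tv in truth_panel if tv.variant_type is row.variant_type)
            assert row.total == n_type * 4

    def test_missing_tier_is_error(self, truth_panel):
        run = LibraryRun(library_id="x", tier_vaf_percent=None)
        with pytest.raises(VariantModelError):
            tally_detections([run], truth_panel)

    def test_zero_runs_empty_table(self, truth_panel):
        assert tally_detections([], truth_panel) == []


class TestSpecificity:
    def wt_run(self, truth_panel, fps, library_id="wt"):
        calls = [
            VariantCall(
                key=VariantKey("chr20", 1_000_000 + i, "A", "G"),
                gene="TP53",
                vaf_percent=0.5,
                alt_reads=25,
                depth=5000,
                classification=cls,
            )
            for i, cls in enumerate(fps)
        ]
        return LibraryRun(library_id=library_id, tier_vaf_percent=0.0, calls=calls)

    def test_printed_count_ratios(self, truth_panel):
        # 3 wild-type libraries, 6 FPs total -> 72/(72+6)
        runs = [
            self.wt_run(truth_panel, [Classification.VUS] * 2, "wt1"),
            self.wt_run(truth_panel, [Classification.PATHOGENIC] * 3, "wt2"),
            self.wt_run(truth_panel, [Classification.VUS], "wt3"),
        ]
        res = specificity(runs, truth_panel)
        assert (res.tn, res.fp) == (72, 6)
        assert res.ratio == pytest.approx(72 / 78)

    def test_benign_calls_not_counted_as_fp(self, truth_panel):
        runs = [self.wt_run(truth_panel, [Classification.BENIGN, Classification.LIKELY_BENIGN])]
        res = specificity(runs, truth_panel)
        assert res.fp == 0 and res.ratio == 1.0

    def test_requires_wild_type_runs(self, truth_panel):
        with pytest.raises(UndefinedMetricError):
            specificity([], truth_panel)


class TestReplicateConcordance:
    def test_identical_runs(self, truth_panel):
        keys = {tv.key for tv in truth_panel}
        a = make_run(truth_panel, keys, 2.0, library_id="a")
        b = make_run(truth_panel, keys, 2.0, library_id="b")
        assert replicate_concordance(a, b, truth_panel) == 1.0

    def test_one_of_24_discordant_gives_958(self, truth_panel):
        keys = {tv.key for tv in truth_panel}
        snv = next(tv.key for tv in truth_panel if tv.variant_type is VariantType.SNV)
        a = make_run(truth_panel, keys, 0.5, library_id="a")
        b = make_run(truth_panel, keys - {snv}, 0.5, library_id="b")
        assert replicate_concordance(a, b, truth_panel) == pytest.approx(23 / 24)

    def test_fully_discordant(self, truth_panel):
        # a detects exactly the non-homopolymer variants, b none of them;
        # the 2 homopolymer indels are undetected in both (concordant)
        keys = {tv.key for tv in truth_panel if not tv.homopolymer_context}
        a = make_run(truth_panel, keys, 0.5, library_id="a")
        b = make_run(truth_panel, set(), 0.5, library_id="b")
        assert replicate_concordance(a, b, truth_panel) == pytest.approx(2 / 24)

    def test_tier_mismatch_is_error(self, truth_panel):
        a = make_run(truth_panel, set(), 0.5, library_id="a")
        b = make_run(truth_panel, set(), 1.0, library_id="b")
        with pytest.raises(VariantModelError):
            replicate_concordance(a, b, truth_panel)


class TestLinearity:
    TIERS = [0.125, 0.25, 0.5, 1.0, 2.0]

    def test_perfect_observations(self):
        fit = linearity_fit(self.TIERS, self.TIERS)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_observed_zero_slope(self):
        fit = linearity_fit([0.4] * 5, self.TIERS)
        assert fit.slope == pytest.approx(0.0)

    def test_binomial_noise_recovers_unit_slope(self):
        """Simulation oracle: per-tier mean VAFs from 10 replicate libraries
        at depth 5000 fit with slope within [0.9, 1.1] across 200 seeds."""
        rng = np.random.default_rng(42)
        depth, reps = 5000, 10
        slopes = []
        for _ in range(200):
            observed = [
                float(np.mean(100 * rng.binomial(depth, t / 100, size=reps) / depth))
                for t in self.TIERS
            ]
            slopes.append(linearity_fit(observed, self.TIERS).slope)
        assert all(0.9 <= s <= 1.1 for s in slopes)

    def test_too_few_points_is_error(self):
        with pytest.raises(VariantModelError):
            linearity_fit([1.0], [1.0])


class TestInputAnova:
    def test_degenerate_identical_groups(self):
        res = input_anova({30: [1.0, 1.0], 50: [1.0, 1.0]})
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_type_one_error_calibrated(self):
        """Under the null (all groups from one distribution) the rejection
        rate at alpha = 0.05 is ~5% over 1000 simulations."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = {ng: rng.normal(0.5, 0.1, size=4) for ng in (30, 40, 50, 60)}
            if input_anova(groups).p_value < 0.05:
                rejections += 1
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < 3 * se + 1e-9

    def test_mean_shift_detected(self):
        """A 3-SD mean shift in one group yields p < 0.01 in >= 95% of runs."""
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            groups = {ng: rng.normal(0.5, 0.1, size=6) for ng in (40, 50, 60)}
            groups[30] = rng.normal(0.8, 0.1, size=6)
            if input_anova(groups).p_value < 0.01:
                hits += 1
        assert hits / n_sim >= 0.95

    def test_degenerate_group_sizes_rejected(self):
        with pytest.raises(VariantModelError):
            input_anova({30: [1.0], 50: [1.0, 2.0]})
        with pytest.raises(VariantModelError):
            input_anova({30: [1.0, 2.0]})


class TestDetectionProbability:
    def test_matches_empirical_binomial(self):
        depth, tier = 5069, 0.5
        p_theory = detection_probability(tier, depth)
        rng = np.random.default_rng(3)
        draws = rng.binomial(depth, tier / 100, size=20000)
        k_min = max(2, int(np.ceil(0.25 * depth / 100)))
        p_emp = float(np.mean(draws >= k_min))
        assert p_emp == pytest.approx(p_theory, abs=3 * np.sqrt(p_theory * (1 - p_theory) / 20000))

    def test_two_percent_tier_near_certain(self):
        assert detection_probability(2.0, 5069) >= 0.999

    def test_zero_tier_zero(self):
        assert detection_probability(0.0, 5069) == 0.0
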