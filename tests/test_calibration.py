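"""Likelihood-ratio estimation, strength mapping and cut-off optimization."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicecodes.calibration import (BinCounts, DegenerateInputError,
                                     EvidenceStrength, SpliceScoreCalibration,
                                     StrengthThresholds, TruthRecord, band_lrs,
                                     bin_dataset, compute_lr, map_lr_to_strength,
                                     optimize_cutoffs,
                                     sensitivity_and_specificity,
                                     stratified_calibration)
from splicecodes.simulate import (generate_from_bin_probs, representative_region,
                                  curated_truth_fixture)
from splicecodes.transcript import RegionCategory


def rec(key, score, label, category=RegionCategory.OUTSIDE):
    return TruthRecord(key, score, label, representative_region(category))


class TestComputeLR:
    @pytest.mark.parametrize("counts, lr, ci", [
        (BinCounts(381, 491, 109, 2246), 15.99, (13.23, 19.32)),
        (BinCounts(72, 491, 1962, 2246), 0.17, (0.14, 0.21)),
        (BinCounts(38, 491, 175, 2246), 0.99, (0.71, 1.39)),
    ])
    def test_published_counts_reproduce_lr_and_ci(self, counts, lr, ci):
        res = compute_lr(counts)
        assert round(res.lr, 2) == lr
        assert round(res.ci_low, 2) == ci[0]
        assert round(res.ci_high, 2) == ci[1]
        assert not res.continuity_corrected

    def test_equal_proportions_give_unit_lr(self):
        res = compute_lr(BinCounts(10, 100, 10, 100))
        assert res.lr == pytest.approx(1.0)

    def test_zero_cell_triggers_continuity_correction(self):
        res = compute_lr(BinCounts(0, 50, 10, 100))
        assert res.continuity_corrected
        assert res.lr == pytest.approx((0.5 / 51) / (10.5 / 101))
        assert math.isfinite(res.ci_low) and math.isfinite(res.ci_high)

    def test_degenerate_totals_rejected(self):
        with pytest.raises(DegenerateInputError):
            BinCounts(0, 0, 5, 10)

    def test_ci_contains_lr(self):
        res = compute_lr(BinCounts(30, 60, 20, 80))
        assert res.ci_low <= res.lr <= res.ci_high

    @given(npi=st.integers(1, 50), nni=st.integers(1, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_label_swap_reciprocity(self, npi, nni):
        """Swapping class labels inverts the LR and mirrors the CI."""
        a = compute_lr(BinCounts(npi, 60, nni, 90))
        b = compute_lr(BinCounts(nni, 90, npi, 60))
        assert b.lr == pytest.approx(1.0 / a.lr)
        assert b.ci_low == pytest.approx(1.0 / a.ci_high)
        assert b.ci_high == pytest.approx(1.0 / a.ci_low)


class TestStrengthMapping:
    T = StrengthThresholds()

    @pytest.mark.parametrize("lr, expected", [
        (15.99, EvidenceStrength.MODERATE),
        (0.17, EvidenceStrength.MODERATE_BENIGN),
        (1.00, EvidenceStrength.UNINFORMATIVE),
        (400.0, EvidenceStrength.VERY_STRONG),
        (20.0, EvidenceStrength.STRONG),
        (2.2, EvidenceStrength.SUPPORTING),
        (0.4, EvidenceStrength.SUPPORTING_BENIGN),
        (0.05, EvidenceStrength.STRONG_BENIGN),
        (0.002, EvidenceStrength.VERY_STRONG_BENIGN),
    ])
    def test_category_assignment(self, lr, expected):
        assert map_lr_to_strength(lr, self.T) is expected

    def test_boundaries_inclusive(self):
        assert map_lr_to_strength(self.T.odds_moderate, self.T) is \
            EvidenceStrength.MODERATE
        assert map_lr_to_strength(1.0 / self.T.odds_moderate, self.T) is \
            EvidenceStrength.MODERATE_BENIGN

    def test_benign_bounds_are_reciprocal(self):
        assert self.T.benign_bound(EvidenceStrength.MODERATE_BENIGN) == \
            pytest.approx(1.0 / self.T.odds_moderate)

    def test_ci_gate_demotes_one_level(self):
        # LR in the moderate band but lower CI below the supporting bound
        s = map_lr_to_strength(5.0, self.T, use_ci_bound=True, ci=(1.5, 16.0))
        assert s is EvidenceStrength.SUPPORTING
        s2 = map_lr_to_strength(5.0, self.T, use_ci_bound=True, ci=(2.5, 16.0))
        assert s2 is EvidenceStrength.MODERATE

    def test_ci_gate_requires_ci(self):
        with pytest.raises(ValueError):
            map_lr_to_strength(5.0, self.T, use_ci_bound=True)

    @given(st.floats(min_value=0.0, max_value=1000.0,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_mapping_is_total_and_monotone(self, lr):
        """Every LR maps to exactly one category, and a higher LR never maps
        to a weaker pathogenic (or stronger benign) category."""
        order = [EvidenceStrength.VERY_STRONG_BENIGN, EvidenceStrength.STRONG_BENIGN,
                 EvidenceStrength.MODERATE_BENIGN, EvidenceStrength.SUPPORTING_BENIGN,
                 EvidenceStrength.UNINFORMATIVE, EvidenceStrength.SUPPORTING,
                 EvidenceStrength.MODERATE, EvidenceStrength.STRONG,
                 EvidenceStrength.VERY_STRONG]
        a = map_lr_to_strength(lr, self.T)
        b = map_lr_to_strength(lr * 1.5 + 1e-9, self.T)
        assert order.index(b) >= order.index(a)


class TestBinning:
    def test_published_table_counts(self, curated_records):
        low, mid, high = bin_dataset(curated_records, 0.1, 0.2)
        assert (low.n_neg_in, mid.n_neg_in, high.n_neg_in) == (1962, 175, 109)
        assert (low.n_pos_in, mid.n_pos_in, high.n_pos_in) == (72, 38, 381)

    def test_partition_is_exhaustive_and_disjoint(self, curated_records):
        low, mid, high = bin_dataset(curated_records, 0.1, 0.2)
        assert low.n_pos_in + mid.n_pos_in + high.n_pos_in == low.n_pos_total
        assert low.n_neg_in + mid.n_neg_in + high.n_neg_in == low.n_neg_total

    def test_boundary_scores_go_to_outer_bins(self):
        records = [rec("a", 0.1, False), rec("b", 0.2, True), rec("c", 0.15, False)]
        low, mid, high = bin_dataset(records, 0.1, 0.2)
        assert low.n_neg_in == 1 and high.n_pos_in == 1 and mid.n_neg_in == 1

    def test_all_zero_scores_fall_in_low_bin(self):
        records = [rec(f"r{i}", 0.0, i % 2 == 0) for i in range(10)]
        low, mid, high = bin_dataset(records, 0.1, 0.2)
        assert low.n_pos_in == low.n_pos_total and low.n_neg_in == low.n_neg_total

    def test_invalid_cuts_rejected(self, curated_records):
        with pytest.raises(ValueError):
            bin_dataset(curated_records, 0.3, 0.2)


class TestSensitivitySpecificity:
    def test_published_values(self, curated_records):
        sens, spec = sensitivity_and_specificity(curated_records)
        assert sens == pytest.approx(381 / 491)
        assert spec == pytest.approx(1962 / 2246)
        assert round(sens * 100) == 78 and round(spec * 100) == 87

    def test_perfect_separation(self):
        records = [rec(f"p{i}", 0.95, True) for i in range(5)] + \
                  [rec(f"n{i}", 0.02, False) for i in range(5)]
        sens, spec = sensitivity_and_specificity(records, 0.5, 0.1)
        assert sens == 1.0 and spec == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            sensitivity_and_specificity([rec("p", 0.9, True)])


class TestOptimizeCutoffs:
    def test_separable_data_yields_zero_error(self):
        records = [rec(f"p{i}", 0.92 + i * 0.001, True) for i in range(20)] + \
                  [rec(f"n{i}", 0.001 + i * 0.002, False) for i in range(20)]
        low, high, diag = optimize_cutoffs(records)
        assert diag["fn_rate"] == 0.0 and diag["fp_rate"] == 0.0
        assert max(r.score for r in records if not r.spliceogenic) <= low
        assert high <= min(r.score for r in records if r.spliceogenic)

    def test_matches_brute_force_oracle(self):
        """Independent oracle: re-enumerate every grid pair with plain loops."""
        rng = np.random.default_rng(7)
        records = [rec(f"p{i}", s, True) for i, s in
                   enumerate(rng.beta(2.0, 0.8, 80))] + \
                  [rec(f"n{i}", s, False) for i, s in
                   enumerate(rng.beta(0.5, 3.0, 120))]
        low, high, diag = optimize_cutoffs(records, grid_step=0.05)
        grid = [round(0.05 * k, 10) for k in range(21)]
        best = None
        for lo in grid:
            for hi in grid:
                if hi <= lo:
                    continue
                pos = [r.score for r in records if r.spliceogenic]
                neg = [r.score for r in records if not r.spliceogenic]
                fn = sum(s <= lo for s in pos) / len(pos)
                fp = sum(s >= hi for s in neg) / len(neg)
                uninf = (sum(lo < s < hi for s in pos + neg)) / len(records)
                obj = fn + fp + 0.5 * uninf
                if best is None or obj < best[0] - 1e-12 or (
                        abs(obj - best[0]) <= 1e-12
                        and (-(hi - lo), lo) < (-(best[2] - best[1]), best[1])):
                    best = (obj, lo, hi)
        assert (low, high) == (best[1], best[2])
        assert diag["objective"] == pytest.approx(best[0])

    def test_recovers_published_cuts_on_curated_truth_fixture(self, curated_records):
        low, high, _ = optimize_cutoffs(curated_records)
        assert (low, high) == (0.1, 0.2)

    def test_removing_high_scoring_positives_never_raises_high_cut(self,
                                                                   curated_records):
        _, high_full, _ = optimize_cutoffs(curated_records)
        truncated = [r for r in curated_records
                     if not (r.spliceogenic and r.score > 0.5)]
        _, high_trunc, _ = optimize_cutoffs(truncated)
        assert high_trunc <= high_full

    def test_too_few_records_rejected(self):
        with pytest.raises(DegenerateInputError):
            optimize_cutoffs([rec("p", 0.9, True), rec("n", 0.1, False)])


class TestBandLRs:
    def test_whole_range_band_is_unit_lr(self, curated_records):
        (res,) = band_lrs(curated_records, [(0.0, 1.0)])
        assert res.lr == pytest.approx(1.0)

    def test_complementary_bands_conserve_counts(self, curated_records):
        results = band_lrs(curated_records, [(0.0, 0.15), (0.15, 1.0)])
        assert sum(r.counts.n_pos_in for r in results) == 491
        assert sum(r.counts.n_neg_in for r in results) == 2246

    def test_empty_band_is_flagged_undefined(self):
        records = [rec("p", 0.9, True), rec("n", 0.1, False)]
        res = band_lrs(records, [(0.4, 0.5)])[0]
        assert not res.defined and math.isnan(res.lr)

    def test_overlapping_bands_rejected(self, curated_records):
        with pytest.raises(ValueError):
            band_lrs(curated_records, [(0.0, 0.3), (0.2, 0.5)])


class TestStratified:
    def test_constant_stratum_reproduces_pooled_result(self, curated_records):
        pooled = compute_lr(bin_dataset(curated_records, 0.1, 0.2)[2])
        strat = stratified_calibration(curated_records, key=lambda r: "all")
        assert strat["all"][2].lr == pytest.approx(pooled.lr)

    def test_two_strata_match_per_stratum_oracle(self):
        """Brute force: compute each stratum's LR from its own records."""
        rng = np.random.default_rng(11)
        records = []
        for stratum, (pa, na) in {"A": (2.5, 0.4), "B": (1.2, 1.2)}.items():
            cat = (RegionCategory.STANDARD_SPLICE_REGION if stratum == "A"
                   else RegionCategory.OUTSIDE)
            records += [rec(f"{stratum}p{i}", s, True, cat)
                        for i, s in enumerate(rng.beta(pa, 0.8, 60))]
            records += [rec(f"{stratum}n{i}", s, False, cat)
                        for i, s in enumerate(rng.beta(0.5, na, 90))]
        strat = stratified_calibration(records)
        for cat in (RegionCategory.STANDARD_SPLICE_REGION, RegionCategory.OUTSIDE):
            sub = [r for r in records if r.region.category is cat]
            pos_in = sum(1 for r in sub if r.spliceogenic and r.score >= 0.2)
            neg_in = sum(1 for r in sub if not r.spliceogenic and r.score >= 0.2)
            n_pos = sum(1 for r in sub if r.spliceogenic)
            n_neg = len(sub) - n_pos
            expect = (pos_in / n_pos) / (neg_in / n_neg)
            assert strat[cat][2].lr == pytest.approx(expect)

    def test_permuting_labels_leaves_result_multiset_invariant(self):
        records = [rec(f"p{i}", 0.3 + 0.01 * i, True,
                       RegionCategory.OUTSIDE if i % 2 else
                       RegionCategory.STANDARD_SPLICE_REGION) for i in range(40)]
        records += [rec(f"n{i}", 0.01 * i, False,
                        RegionCategory.OUTSIDE if i % 2 else
                        RegionCategory.STANDARD_SPLICE_REGION) for i in range(40)]
        a = stratified_calibration(records)
        b = stratified_calibration(list(reversed(records)))
        assert {k: tuple(round(r.lr, 9) for r in v) for k, v in a.items()} == \
               {k: tuple(round(r.lr, 9) for r in v) for k, v in b.items()}

    def test_missing_stratum_warns_and_skips(self, curated_records):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            out = stratified_calibration(
                curated_records, strata=[RegionCategory.OUTSIDE,
                                        RegionCategory.CANONICAL_DINUCLEOTIDE])
        assert RegionCategory.CANONICAL_DINUCLEOTIDE not in out
        assert any("no records" in str(x.message) for x in w)


class TestCoverage:
    def test_ci_covers_generating_lr_at_nominal_rate(self):
        """95% CI coverage of the known generating LR across seeded replicates
        (a scaled-down check; the full-size run lives in the acceptance suite)."""
        edges = [0.0, 0.1, 0.2, 1.0]
        pos_p = [72 / 491, 38 / 491, 381 / 491]
        neg_p = [1962 / 2246, 175 / 2246, 109 / 2246]
        hits = total = 0
        for seed in range(60):
            records, true_lr = generate_from_bin_probs(edges, pos_p, neg_p,
                                                       900, 4100, seed=seed)
            for k, res in enumerate(bin_dataset(records, 0.1, 0.2)):
                out = compute_lr(res)
                total += 1
                hits += out.ci_low <= true_lr[k] <= out.ci_high
        assert 0.90 <= hits / total <= 0.99

    def test_model_results_summary_reports_published_table(self, curated_records):
        model = SpliceScoreCalibration(curated_records)
        res = model.fit(0.1, 0.2)
        text = res.summary()
        assert "15.99" in text and "13.23" in text and "19.32" in text
        assert "78%" in text and "87%" in text
        frame = res.to_frame()
        assert list(frame["n_neg"]) == [1962, 175, 109]
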