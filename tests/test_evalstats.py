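"""Benchmark statistics: matching, fold change, CV, marker logic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from peakcloud.evalstats import (accurate_quant, consensus_features, cv,
                                 detection_metrics, fold_change, is_marker,
                                 marker_accuracy, match_features)

DESIGN_RATIOS = (1 / 16, 1 / 4, 1 / 2, 1.0, 2.0, 4.0, 16.0)


def table(rows):
    return pd.DataFrame(rows, columns=["mz", "rt"])


class TestMatchFeatures:
    def test_identical_lists_fully_matched(self):
        t = table([(100.0, 1.0), (200.0, 2.0)])
        m = match_features(t, t, 0.01, 0.5)
        assert m.n_matched == 2
        assert np.all(m.delta_mz == 0) and np.all(m.delta_rt == 0)

    def test_beyond_tolerance_unmatched(self):
        det = table([(100.02, 1.0)])
        tru = table([(100.0, 1.0)])
        m = match_features(det, tru, 0.01, 0.5)
        assert m.n_matched == 0
        assert m.unmatched_truth == [0] and m.unmatched_detected == [0]

    def test_nearer_of_two_detections_wins(self):
        det = table([(100.002, 1.0), (100.005, 1.0)])
        tru = table([(100.0, 1.0)])
        m = match_features(det, tru, 0.01, 0.5)
        assert m.pairs == [(0, 0)]
        assert m.unmatched_detected == [1]

    def test_greedy_matches_brute_force_on_toy_case(self):
        # oracle: brute-force over all one-to-one assignments of a 3x3 case
        # with well-separated truths (no ambiguity, so greedy is optimal)
        rng = np.random.default_rng(0)
        tru = table([(100.0, 1.0), (100.05, 2.2), (100.1, 0.3)])
        det = table([(mz + rng.uniform(-0.005, 0.005),
                      rt + rng.uniform(-0.2, 0.2))
                     for mz, rt in tru.itertuples(index=False)])
        m = match_features(det, tru, 0.01, 0.5)
        best, best_pairs = 0, None
        for perm in itertools.permutations(range(3)):
            ok = [(i, j) for i, j in enumerate(perm)
                  if abs(det.mz[i] - tru.mz[j]) <= 0.01
                  and abs(det.rt[i] - tru.rt[j]) <= 0.5]
            if len(ok) > best:
                best, best_pairs = len(ok), ok
        assert m.n_matched == best == 3
        assert sorted(m.pairs) == sorted(best_pairs)

    def test_tolerance_scaling_invariance(self):
        det = table([(100.006, 1.2)])
        tru = table([(100.0, 1.0)])
        m1 = match_features(det, tru, 0.01, 0.5)
        det2 = table([(100.012, 1.4)])
        m2 = match_features(det2, tru, 0.02, 1.0)
        assert m1.n_matched == m2.n_matched == 1

    def test_invalid_tolerances_raise(self):
        with pytest.raises(ValueError):
            match_features(table([]), table([(1, 1)]), 0.0, 0.5)


class TestFoldChange:
    def test_hand_values(self):
        assert fold_change([2.0, 2.0], [1.0, 1.0]) == pytest.approx(2.0)
        assert fold_change([3.0, 5.0], [3.0, 5.0]) == pytest.approx(1.0)

    def test_noisy_groups_recover_true_ratio(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            a = 100.0 * (1 + rng.normal(0, 0.05, 5))
            b = 400.0 * (1 + rng.normal(0, 0.05, 5))
            if 3.6 <= fold_change(b, a) <= 4.4:
                hits += 1
        assert hits >= 95

    def test_zero_mean_flagged(self):
        with pytest.raises(ValueError):
            fold_change([0.0, 0.0], [1.0, 1.0])


class TestAccurateQuant:
    def test_exact_agreement_true(self):
        assert accurate_quant(2.0, 2.0, 2.0)

    def test_hand_boundary_case(self):
        # theo = measured = 2 -> envelope [1.6, 2.4]; 2.5 is out
        assert not accurate_quant(2.5, 2.0, 2.0)
        assert accurate_quant(2.4, 2.0, 2.0)

    def test_zero_tolerance_is_range_membership(self):
        assert accurate_quant(1.5, 1.0, 2.0, tol=0.0)
        assert not accurate_quant(2.1, 1.0, 2.0, tol=0.0)

    def test_monotone_in_tolerance(self):
        for fc in (0.3, 0.9, 1.7, 2.6):
            inside = [accurate_quant(fc, 1.0, 2.0, tol=t)
                      for t in (0.0, 0.1, 0.2, 0.5)]
            assert inside == sorted(inside)   # loosening never flips to False


class TestCV:
    def test_constant_values_zero(self):
        assert cv([5.0, 5.0, 5.0]) == 0.0

    def test_hand_value(self):
        assert cv([1.0, 3.0]) == pytest.approx(np.sqrt(2.0) / 2.0)

    def test_scale_invariance(self):
        x = [2.0, 3.0, 4.5, 3.3]
        assert cv([7 * v for v in x]) == pytest.approx(cv(x), rel=1e-12)

    def test_single_replicate_undefined(self):
        with pytest.raises(ValueError):
            cv([1.0])


class TestMarkers:
    def test_unit_fold_change_not_marker(self):
        assert not is_marker(1.0)

    def test_boundary_at_2_4(self):
        assert not is_marker(2.4)
        assert is_marker(2.41)
        assert not is_marker(0.4)
        assert is_marker(0.399)

    def test_design_ratios_exact_quant(self):
        # with exact quantification, markers are exactly the |log2 FC| >= 2
        # groups of the standard-mixture design
        called = [is_marker(r) for r in DESIGN_RATIOS]
        expected = [abs(np.log2(r)) >= 2 for r in DESIGN_RATIOS]
        assert called == expected
        t, f, acc = marker_accuracy(DESIGN_RATIOS, DESIGN_RATIOS)
        assert (t, f) == (4, 0)   # 1/16, 1/4, 4/1 and 16/1
        assert acc == 1.0

    def test_false_marker_counted(self):
        # measured far out of band while theoretically unchanged
        t, f, acc = marker_accuracy([3.0], [1.0])
        assert (t, f) == (0, 1)
        assert acc == 0.0

    def test_monotone_in_tolerance(self):
        for fc in (0.35, 0.45, 2.3, 2.7):
            flags = [is_marker(fc, tol=t) for t in (0.0, 0.1, 0.2, 0.4)]
            assert flags == sorted(flags, reverse=True)  # loosening never adds


class TestDetectionMetrics:
    def test_perfect_detection(self):
        t = table([(100.0, 1.0), (200.0, 2.0)])
        m = match_features(t, t, 0.01, 0.5)
        assert detection_metrics(m, 2) == (1.0, 1.0)

    def test_half_recall_full_precision(self):
        det = table([(100.0, 1.0)])
        tru = table([(100.0, 1.0), (200.0, 2.0)])
        m = match_features(det, tru, 0.01, 0.5)
        assert detection_metrics(m, 2) == (0.5, 1.0)

    def test_counts_match_enumeration_on_toy_case(self):
        rng = np.random.default_rng(2)
        tru = table([(100.0 + 0.1 * i, 1.0 + 0.05 * i) for i in range(10)])
        jitter = rng.uniform(-0.004, 0.004, size=(10, 2))
        det_rows = [(tru.mz[i] + jitter[i, 0], tru.rt[i] + jitter[i, 1])
                    for i in range(8)] + [(300.0, 9.0)]
        m = match_features(table(det_rows), tru, 0.01, 0.5)
        recall, precision = detection_metrics(m, 10)
        assert recall == pytest.approx(8 / 10)
        assert precision == pytest.approx(8 / 9)


class TestConsensus:
    def test_intersection_across_replicates(self):
        r1 = table([(100.0, 1.0), (200.0, 2.0), (300.0, 3.0)])
        r2 = table([(100.001, 1.01), (300.002, 3.02)])
        r3 = table([(100.002, 0.99), (200.001, 2.0)])
        keep = consensus_features([r1, r2, r3], 0.01, 0.5)
        assert keep == [0]   # only the 100 Da feature is in all runs
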