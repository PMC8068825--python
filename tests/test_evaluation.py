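import numpy as np
import pytest

from trapcount.evaluation import (
    UndefinedMetricError,
    average_precision,
    average_precision_pooled,
    calibrate_threshold,
    counting_error,
    match,
    pr_curve,
    precision_recall,
)
from trapcount.geometry import BoundingBox, Detection

from _reference import brute_force_ap, random_boxes, random_detections


def det(x0, y0, x1, y1, score):
    return Detection(BoundingBox(x0, y0, x1, y1), score)


class TestMatch:
    def test_exact_detection_is_tp(self):
        t = BoundingBox(10, 10, 40, 40)
        m = match([Detection(t, 0.9)], [t], 0.5)
        assert (m.TP, m.FP, m.FN) == (1, 0, 0)
        assert m.matches[0][:2] == (0, 0)

    def test_no_detections_all_truths_missed(self):
        truths = random_boxes(np.random.default_rng(0), 5)
        m = match([], truths, 0.5)
        assert (m.TP, m.FP, m.FN) == (0, 0, 5)

    def test_double_detection_higher_score_takes_the_match(self):
        t = BoundingBox(0, 0, 10, 10)
        exact_low = det(0, 0, 10, 10, 0.6)  # IoU 1.0, lower score
        loose_high = det(0, 0, 10, 7.5, 0.9)  # IoU 0.75, higher score
        m = match([exact_low, loose_high], [t], 0.5)
        assert (m.TP, m.FP, m.FN) == (1, 1, 0)
        assert m.matches == ((1, 0, 0.75),)  # detection index 1 won

    @pytest.mark.parametrize("seed", range(10))
    def test_bookkeeping_identities(self, seed):
        rng = np.random.default_rng(seed)
        dets = random_detections(rng, int(rng.integers(0, 15)))
        truths = random_boxes(rng, int(rng.integers(0, 10)))
        m = match(dets, truths, 0.3)
        assert m.TP + m.FP == len(dets)
        assert m.TP + m.FN == len(truths)
        assert len({i for i, _, _ in m.matches}) == m.TP
        assert len({j for _, j, _ in m.matches}) == m.TP


class TestPrecisionRecall:
    def test_worked_example(self):
        m = match(
            [det(i * 20, 0, i * 20 + 10, 10, 0.9) for i in range(10)],
            [BoundingBox(i * 20, 0, i * 20 + 10, 10) for i in range(9)],
            0.5,
        )
        assert (m.TP, m.FP, m.FN) == (9, 1, 0)
        p, r = precision_recall(m)
        assert (p, r) == (90.0, 100.0)

    def test_direct_arithmetic(self):
        from trapcount.evaluation import MatchResult

        m = MatchResult(TP=50, FP=10, FN=25, matches=(), iou_threshold=0.5)
        p, r = precision_recall(m)
        assert p == pytest.approx(83.3333, abs=1e-3)
        assert r == pytest.approx(66.6667, abs=1e-3)

    def test_empty_denominators_signalled(self):
        from trapcount.evaluation import MatchResult

        with pytest.raises(UndefinedMetricError):
            precision_recall(MatchResult(0, 0, 3, (), 0.5))
        with pytest.raises(UndefinedMetricError):
            precision_recall(MatchResult(0, 2, 0, (), 0.5))


class TestAveragePrecision:
    def test_perfect_single_detection(self):
        t = BoundingBox(0, 0, 10, 10)
        assert average_precision([Detection(t, 0.8)], [t], 0.5) == 1.0

    def test_all_disjoint_gives_zero(self):
        dets = [det(0, 0, 10, 10, 0.9), det(20, 20, 30, 30, 0.7)]
        truths = [BoundingBox(50, 50, 60, 60)]
        assert average_precision(dets, truths, 0.5) == 0.0

    def test_no_truth_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            average_precision([det(0, 0, 10, 10, 0.9)], [], 0.5)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dets = random_detections(rng, int(rng.integers(1, 11)), max_side=40)
        truths = random_boxes(rng, int(rng.integers(1, 6)), max_side=40)
        thr = float(rng.choice([0.3, 0.5]))
        assert average_precision(dets, truths, thr) == pytest.approx(
            brute_force_ap(dets, truths, thr)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_to_monotone_score_transform(self, seed):
        rng = np.random.default_rng(50 + seed)
        dets = random_detections(rng, 10, max_side=40)
        truths = random_boxes(rng, 5, max_side=40)
        squashed = [Detection(d.box, d.score**2, d.label) for d in dets]
        assert average_precision(dets, truths, 0.5) == pytest.approx(
            average_precision(squashed, truths, 0.5)
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_looser_iou_never_hurts(self, seed):
        rng = np.random.default_rng(100 + seed)
        dets = random_detections(rng, 12, max_side=40)
        truths = random_boxes(rng, 6, max_side=40)
        assert average_precision(dets, truths, 0.3) >= average_precision(
            dets, truths, 0.5
        )

    def test_pooled_ap_equals_single_image_case(self):
        rng = np.random.default_rng(7)
        dets = random_detections(rng, 8, max_side=40)
        truths = random_boxes(rng, 4, max_side=40)
        assert average_precision_pooled([(dets, truths)], 0.5) == average_precision(
            dets, truths, 0.5
        )

    def test_recall_non_decreasing_along_curve(self):
        rng = np.random.default_rng(9)
        curve = pr_curve(
            random_detections(rng, 15, max_side=40), random_boxes(rng, 8, max_side=40), 0.3
        )
        assert list(curve.recall) == sorted(curve.recall)


class TestCountingError:
    def test_perfect_counts_give_zero(self):
        assert counting_error([(100, 100), (250, 250)]) == 0.0

    def test_single_trap_worked_example(self):
        assert counting_error([(100, 90)]) == pytest.approx(10.0)

    def test_mean_over_traps(self):
        assert counting_error([(200, 190), (400, 420), (600, 570)]) == pytest.approx(5.0)

    def test_scale_invariance(self):
        pairs = [(120, 110), (300, 330), (50, 45)]
        scaled = [(3 * c, 3 * p) for c, p in pairs]
        assert counting_error(pairs) == pytest.approx(counting_error(scaled))

    def test_signed_variant_lets_errors_cancel(self):
        pairs = [(100, 90), (100, 110)]
        assert counting_error(pairs) == pytest.approx(10.0)
        assert counting_error(pairs, signed=True) == pytest.approx(0.0)

    def test_zero_manual_count_rejected(self):
        with pytest.raises(ValueError):
            counting_error([(0, 5)])
        with pytest.raises(ValueError):
            counting_error([])


class TestCalibration:
    @staticmethod
    def separated_trap(rng, n_true=50, n_fp=10):
        """Stitched detections with scores >= 0.9 (true) and <= 0.3 (spurious)."""
        dets = [
            Detection(b, float(rng.uniform(0.9, 1.0)))
            for b in random_boxes(rng, n_true, frame=(0, 0, 1000, 1000))
        ]
        dets += [
            Detection(b, float(rng.uniform(0.05, 0.3)))
            for b in random_boxes(rng, n_fp, frame=(0, 0, 1000, 1000))
        ]
        return dets, n_true

    def test_recovers_separating_threshold(self):
        rng = np.random.default_rng(1)
        calib = [self.separated_trap(rng) for _ in range(5)]
        t, err = calibrate_threshold(calib)
        assert 0.3 < t <= 0.9
        assert err == 0.0
        held_out = [self.separated_trap(rng) for _ in range(5)]
        held_err = counting_error(
            [(c, sum(1 for d in dets if d.score >= t)) for dets, c in held_out]
        )
        assert held_err == 0.0

    def test_single_candidate_returned_unchanged(self):
        rng = np.random.default_rng(2)
        calib = [self.separated_trap(rng)]
        t, _ = calibrate_threshold(calib, thresholds=[0.42])
        assert t == 0.42

    def test_ties_broken_toward_higher_threshold(self):
        dets = [det(0, 0, 10, 10, 0.95), det(20, 0, 30, 10, 0.95)]
        t, err = calibrate_threshold([( dets, 2)], thresholds=[0.2, 0.5, 0.8])
        assert t == 0.8 and err == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([([det(0, 0, 10, 10, 0.9)], 1)], thresholds=[])
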