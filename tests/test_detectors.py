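import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from trapcount.detectors import (
    BlobConfig,
    BlobDetector,
    Detector,
    NoisyOracleConfig,
    NoisyOracleDetector,
    blob_detect,
    oracle_detect,
)
from trapcount.geometry import BoundingBox, iou
from trapcount.tiling import Window

YELLOW = (205, 185, 60)


def yellow_tile(h=200, w=200, noise_seed=0):
    rng = np.random.default_rng(noise_seed)
    img = np.empty((h, w, 3), float)
    img[:] = YELLOW
    img += rng.normal(0, 5, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def paint_ellipse(img, cy, cx, a, b, color=(45, 35, 25)):
    rr, cc = draw_ellipse(cy, cx, a, b, shape=img.shape[:2])
    img[rr, cc] = color
    return BoundingBox(cc.min(), rr.min(), cc.max() + 1, rr.max() + 1)


class TestBlobDetector:
    def test_blank_tile_yields_nothing(self):
        assert blob_detect(yellow_tile()) == []

    def test_blank_tile_with_otsu_threshold_yields_nothing(self):
        assert blob_detect(yellow_tile(), BlobConfig(threshold=None)) == []

    def test_single_dark_ellipse_detected_with_good_localization(self):
        img = yellow_tile()
        truth = paint_ellipse(img, 100, 100, 30, 25)
        dets = blob_detect(img)
        assert len(dets) == 1
        assert iou(dets[0].box, truth) >= 0.5
        assert 0.0 <= dets[0].score <= 1.0

    def test_two_separated_ellipses_give_two_detections(self):
        img = yellow_tile()
        t1 = paint_ellipse(img, 50, 50, 20, 15)
        t2 = paint_ellipse(img, 150, 150, 20, 15)
        dets = blob_detect(img)
        assert len(dets) == 2
        matched = {max(range(2), key=lambda k: iou(d.box, [t1, t2][k])) for d in dets}
        assert matched == {0, 1}

    def test_touching_pair_split_into_two(self):
        img = yellow_tile()
        paint_ellipse(img, 100, 90, 15, 12)
        paint_ellipse(img, 100, 110, 15, 12)  # overlaps the first
        assert len(blob_detect(img)) == 2
        assert len(blob_detect(img, BlobConfig(split_touching=False))) == 1

    def test_min_area_filters_speckles(self):
        img = yellow_tile()
        img[100:102, 100:102] = (10, 10, 10)  # 4-px speck
        assert blob_detect(img, BlobConfig(min_area=20)) == []
        assert len(blob_detect(img, BlobConfig(min_area=1))) == 1

    def test_translation_equivariance(self):
        img1 = yellow_tile(noise_seed=1)
        img2 = img1.copy()
        paint_ellipse(img1, 60, 60, 15, 12)
        paint_ellipse(img2, 110, 90, 15, 12)  # same shape, shifted by (50, 30)
        d1, d2 = blob_detect(img1), blob_detect(img2)
        assert len(d1) == len(d2) == 1
        b1, b2 = d1[0].box, d2[0].box
        assert (b2.xmin - b1.xmin, b2.ymin - b1.ymin) == (30, 50)
        assert (b1.width, b1.height) == (b2.width, b2.height)

    def test_deterministic_and_honours_contract(self):
        img = yellow_tile()
        paint_ellipse(img, 100, 100, 30, 25)
        det = BlobDetector()
        assert isinstance(det, Detector)
        out1, out2 = det.detect(img), det.detect(img)
        assert out1 == out2
        h, w = img.shape[:2]
        for d in out1:
            assert 0 <= d.box.xmin and d.box.xmax <= w
            assert 0 <= d.box.ymin and d.box.ymax <= h


class TestNoisyOracle:
    def test_perfect_oracle_reproduces_truth_with_score_one(self):
        tile = yellow_tile()
        truth = [BoundingBox(10, 10, 40, 40), BoundingBox(100, 60, 130, 90)]
        dets = oracle_detect(tile, truth)
        assert [d.box for d in dets] == truth or sorted(
            d.box.as_tuple() for d in dets
        ) == sorted(t.as_tuple() for t in truth)
        assert all(d.score == 1.0 for d in dets)

    def test_total_miss_rate_gives_empty_output(self):
        tile = yellow_tile()
        truth = [BoundingBox(10, 10, 40, 40)]
        cfg = NoisyOracleConfig(miss_rate=1.0)
        assert oracle_detect(tile, truth, cfg) == []

    def test_miss_rate_matches_binomial_expectation(self):
        # 1000 truths at miss rate 0.1: emitted count within the 99% interval
        tile = yellow_tile(400, 400)
        rng = np.random.default_rng(5)
        truth = []
        for _ in range(1000):
            x, y = rng.uniform(0, 360, 2)
            truth.append(BoundingBox(x, y, x + 30, y + 30))
        cfg = NoisyOracleConfig(miss_rate=0.1, seed=42)
        emitted = len(oracle_detect(tile, truth, cfg))
        assert 875 <= emitted <= 925  # 900 +/- 2.58 * sqrt(1000 * 0.9 * 0.1)

    def test_false_positives_have_configured_scores(self):
        tile = yellow_tile()
        cfg = NoisyOracleConfig(
            false_positive_rate_per_tile=5.0, fp_score_range=(0.05, 0.3), fp_box_size=30,
            seed=3,
        )
        dets = oracle_detect(tile, [], cfg)
        assert len(dets) > 0
        assert all(0.05 <= d.score <= 0.3 for d in dets)

    def test_jittered_boxes_stay_in_tile(self):
        tile = yellow_tile()
        truth = [BoundingBox(0.5, 0.5, 30, 30), BoundingBox(170, 170, 199.5, 199.5)]
        cfg = NoisyOracleConfig(localization_jitter=10.0, seed=1)
        for d in oracle_detect(tile, truth, cfg):
            assert 0 <= d.box.xmin and d.box.xmax <= 200
            assert 0 <= d.box.ymin and d.box.ymax <= 200

    def test_detector_clips_truth_to_window(self):
        # truth straddling the window edge is emitted clipped, as a real
        # detector would see the visible part of a cut insect
        truth = [BoundingBox(110, 40, 140, 70)]
        det = NoisyOracleDetector(truth)
        tile = np.zeros((125, 125, 3), np.uint8)
        w = Window(0, 0, 0, 0, 125, 125)
        out = det.detect(tile, w)
        assert len(out) == 1
        assert out[0].box.as_tuple() == (110.0, 40.0, 125.0, 70.0)
        assert det.detect(tile, w) == out  # deterministic per window

    def test_partial_emission_can_be_disabled(self):
        truth = [BoundingBox(110, 40, 140, 70)]
        det = NoisyOracleDetector(truth, emit_partial=False)
        tile = np.zeros((125, 125, 3), np.uint8)
        assert det.detect(tile, Window(0, 0, 0, 0, 125, 125)) == []
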