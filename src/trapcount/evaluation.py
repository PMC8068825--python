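"""Detection and counting metrics: matching, precision/recall, AP, counting error.

Detections are matched to ground truth greedily in score-descending
order at a fixed IoU threshold; precision and recall are
``TP / (TP + FP)`` and ``TP / (TP + FN)`` in percent, and average
precision (AP) is the exact area under the monotone precision envelope
of the all-point precision-recall sweep (PASCAL VOC 2010+ style).  APs
are conventionally reported at IoU 0.5, and additionally at the looser
0.3 for counting tasks where precise box placement matters less than
presence.

The counting error over a set of traps is the mean absolute relative
deviation between the manual count C_i and the pipeline count Ĉ_i,

    error% = (1/N) * sum_i |C_i - Ĉ_i| / C_i * 100,

so over- and under-counts cannot cancel; a signed variant is available
behind a flag.  Counting accuracy is 100% minus this error.  The score
threshold that minimizes counting error is calibrated on a held-out
subset of traps and then applied unchanged to the evaluation traps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import BoundingBox, Detection, iou

__all__ = [
    "UndefinedMetricError",
    "MatchResult",
    "PRCurve",
    "CountingReport",
    "match",
    "precision_recall",
    "pr_curve",
    "average_precision",
    "average_precision_pooled",
    "counting_error",
    "calibrate_threshold",
    "default_threshold_grid",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is empty (e.g. precision with no detections)."""


@dataclass(frozen=True)
class MatchResult:
    """TP/FP/FN bookkeeping from matching detections to ground truth.

    ``matches`` lists (detection index, truth index, IoU) triples, with
    detection indices referring to the input detection order; every
    detection and every truth box appears in at most one match, so
    ``TP + FN`` equals the number of truths and ``TP + FP`` the number
    of detections.
    """

    TP: int
    FP: int
    FN: int
    matches: tuple[tuple[int, int, float], ...]
    iou_threshold: float


@dataclass(frozen=True)
class PRCurve:
    """All-point precision-recall sweep with its area-under-envelope AP.

    ``recall`` and ``precision`` are in percent, ordered by descending
    score threshold (recall non-decreasing); ``ap`` is in [0, 1].
    """

    recall: tuple[float, ...]
    precision: tuple[float, ...]
    ap: float


def match(
    dets: Sequence[Detection],
    truth: Sequence[BoundingBox],
    iou_threshold: float,
) -> MatchResult:
    """Greedily match detections to ground truth at an IoU threshold.

    Detections are processed in score-descending order (ties by input
    order); each is assigned to the still-unmatched truth box of highest
    IoU provided that IoU reaches the threshold (a true positive),
    otherwise it is a false positive.  Truth boxes left unmatched are
    false negatives.  IoU ties between truths are broken toward the
    lower truth index.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold {iou_threshold} outside (0, 1]")
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    taken = [False] * len(truth)
    matches: list[tuple[int, int, float]] = []
    for i in order:
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(truth):
            if taken[j]:
                continue
            v = iou(dets[i].box, t)
            if v > best_iou:  # strict: IoU ties keep the lower index
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            matches.append((i, best_j, best_iou))
    tp = len(matches)
    return MatchResult(
        TP=tp,
        FP=len(dets) - tp,
        FN=len(truth) - tp,
        matches=tuple(sorted(matches)),
        iou_threshold=iou_threshold,
    )


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """Precision and recall of a match result, in percent.

    Raises :class:`UndefinedMetricError` when a denominator is empty
    (no detections for precision, no truths for recall) rather than
    silently reporting 0.
    """
    if m.TP + m.FP == 0:
        raise UndefinedMetricError("precision undefined: no detections (TP + FP = 0)")
    if m.TP + m.FN == 0:
        raise UndefinedMetricError("recall undefined: no ground truth (TP + FN = 0)")
    return (100.0 * m.TP / (m.TP + m.FP), 100.0 * m.TP / (m.TP + m.FN))


def _score_tp_flags(
    image_pairs: Sequence[tuple[Sequence[Detection], Sequence[BoundingBox]]],
    iou_threshold: float,
) -> tuple[list[tuple[float, bool]], int]:
    """Per-detection (score, is-TP) flags pooled across images, plus #truths."""
    flags: list[tuple[float, bool]] = []
    n_truth = 0
    for dets, truth in image_pairs:
        n_truth += len(truth)
        m = match(dets, truth, iou_threshold)
        tp_idx = {i for i, _, _ in m.matches}
        for i, d in enumerate(dets):
            flags.append((d.score, i in tp_idx))
    flags.sort(key=lambda p: -p[0])
    return flags, n_truth


def pr_curve(
    dets: Sequence[Detection],
    truth: Sequence[BoundingBox],
    iou_threshold: float,
) -> PRCurve:
    """All-point PR sweep for one detection/truth set; see module docstring."""
    flags, n_truth = _score_tp_flags([(dets, truth)], iou_threshold)
    return _curve_from_flags(flags, n_truth)


def _curve_from_flags(flags: list[tuple[float, bool]], n_truth: int) -> PRCurve:
    if n_truth == 0:
        raise UndefinedMetricError("AP undefined: no ground-truth boxes")
    if not flags:
        return PRCurve(recall=(), precision=(), ap=0.0)
    tps = np.cumsum([f for _, f in flags])
    ranks = np.arange(1, len(flags) + 1)
    recall = tps / n_truth
    precision = tps / ranks
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev = np.concatenate(([0.0], recall[:-1]))
    ap = float(np.sum((recall - prev) * envelope))
    return PRCurve(
        recall=tuple(100.0 * recall),
        precision=tuple(100.0 * precision),
        ap=ap,
    )


def average_precision(
    dets: Sequence[Detection],
    truth: Sequence[BoundingBox],
    iou_threshold: float,
) -> float:
    """AP in [0, 1] for one detection/truth set at an IoU threshold."""
    return pr_curve(dets, truth, iou_threshold).ap


def average_precision_pooled(
    image_pairs: Sequence[tuple[Sequence[Detection], Sequence[BoundingBox]]],
    iou_threshold: float,
) -> float:
    """AP pooled over several images: one global score sweep, per-image matching."""
    flags, n_truth = _score_tp_flags(image_pairs, iou_threshold)
    return _curve_from_flags(flags, n_truth).ap


@dataclass(frozen=True)
class CountingReport:
    """Per-trap manual vs. predicted counts with the aggregate counting error."""

    pairs: tuple[tuple[int, int], ...]  # (C_i manual, Ĉ_i predicted)
    signed: bool = False

    @property
    def N(self) -> int:
        return len(self.pairs)

    @property
    def error(self) -> float:
        return counting_error(self.pairs, signed=self.signed)

    @property
    def accuracy(self) -> float:
        return 100.0 - self.error


def counting_error(
    pairs: Sequence[tuple[float, float]], *, signed: bool = False
) -> float:
    """Mean per-trap relative count deviation, in percent.

    ``(1/N) * sum |C_i - Ĉ_i| / C_i * 100`` by default; with
    ``signed=True`` the absolute value is dropped, letting over- and
    under-counts cancel.
    """
    if len(pairs) == 0:
        raise ValueError("counting error needs at least one trap")
    devs = []
    for c_manual, c_pred in pairs:
        if c_manual <= 0:
            raise ValueError("manual count must be positive; exclude empty traps upstream")
        d = (c_manual - c_pred) / c_manual
        devs.append(d if signed else abs(d))
    return 100.0 * float(np.mean(devs))


def default_threshold_grid() -> np.ndarray:
    """Candidate score thresholds 0.05, 0.10, ..., 0.95."""
    return np.round(np.arange(0.05, 0.951, 0.05), 2)


def calibrate_threshold(
    calibration: Sequence[tuple[Sequence[Detection], int]],
    thresholds: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Select the score threshold minimizing counting error on calibration traps.

    Parameters
    ----------
    calibration
        Per-trap pairs of (stitched global detections, manual count C_i).
        Detection is run once per trap; the threshold sweep only
        re-counts scores.
    thresholds
        Candidate grid in [0, 1]; defaults to 0.05..0.95 in steps of
        0.05.  Ties in counting error are broken toward the higher
        threshold.

    Returns
    -------
    (threshold, calibration_error_percent)
    """
    if len(calibration) == 0:
        raise ValueError("calibration set is empty")
    grid = default_threshold_grid() if thresholds is None else np.asarray(thresholds, float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if grid.min() < 0.0 or grid.max() > 1.0:
        raise ValueError("threshold grid must lie in [0, 1]")
    best_t, best_err = None, None
    for t in sorted(grid):
        pairs = [
            (c_i, sum(1 for d in dets if d.score >= t)) for dets, c_i in calibration
        ]
        err = counting_error(pairs)
        if best_err is None or err <= best_err:  # "<=" prefers the higher threshold
            best_t, best_err = float(t), err
    return best_t, best_err
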