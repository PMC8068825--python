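"""Independent brute-force reference implementations used as test oracles.

These deliberately favour clarity over speed and share no code with the
package's vectorised/cumulative implementations, so agreement between
the two routes is meaningful.
"""

from __future__ import annotations

import numpy as np

from trapcount.geometry import BoundingBox, Detection, iou
from trapcount.evaluation import match


def brute_force_nms(dets, iou_threshold):
    """Literal simulation of greedy NMS: repeatedly pick the best remaining
    detection (score descending, input order on ties) and delete everything
    overlapping it beyond the threshold."""
    remaining = list(enumerate(dets))
    kept = []
    while remaining:
        best_pos = 0
        for pos in range(1, len(remaining)):
            if remaining[pos][1].score > remaining[best_pos][1].score:
                best_pos = pos
        best_idx, best = remaining.pop(best_pos)
        kept.append(best)
        remaining = [
            (i, d) for i, d in remaining if iou(best.box, d.box) <= iou_threshold
        ]
    return kept


def brute_force_ap(dets, truth, iou_threshold):
    """AP by explicit enumeration of every PR operating point.

    For each distinct score threshold the detections above it are
    matched from scratch; the area under the monotone precision
    envelope is then summed over the enumerated recall increments
    (no trapezoids, exact for a step curve).
    """
    if len(truth) == 0:
        raise ValueError("no truth boxes")
    if len(dets) == 0:
        return 0.0
    points = []  # (recall fraction, precision fraction)
    for s in sorted({d.score for d in dets}, reverse=True):
        subset = [d for d in dets if d.score >= s]
        m = match(subset, truth, iou_threshold)
        points.append((m.TP / len(truth), m.TP / len(subset)))
    points.sort()
    ap = 0.0
    prev_r = 0.0
    for r, _ in points:
        if r > prev_r:
            env = max(p for rr, p in points if rr >= r)
            ap += (r - prev_r) * env
            prev_r = r
    return ap


def random_boxes(rng, n, frame=(0.0, 0.0, 100.0, 100.0), max_side=30.0):
    """n random valid boxes inside a frame."""
    x0f, y0f, x1f, y1f = frame
    boxes = []
    for _ in range(n):
        w = rng.uniform(1.0, max_side)
        h = rng.uniform(1.0, max_side)
        x = rng.uniform(x0f, x1f - w)
        y = rng.uniform(y0f, y1f - h)
        boxes.append(BoundingBox(x, y, x + w, y + h))
    return boxes


def random_detections(rng, n, **kwargs):
    """n random detections with distinct scores (no ties)."""
    scores = rng.choice(np.linspace(0.01, 0.99, 997), size=n, replace=False)
    return [
        Detection(b, float(s)) for b, s in zip(random_boxes(rng, n, **kwargs), scores)
    ]
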