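"""Axis-aligned box arithmetic, IoU, and greedy non-maximum suppression.

Boxes use 0-based, half-open, real-valued pixel coordinates: a box spans
``[xmin, xmax) x [ymin, ymax)`` and its width is ``xmax - xmin`` with no
"+1" correction (the COCO convention).  These primitives underpin tiling,
stitching and evaluation alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = ["BoundingBox", "Detection", "iou", "nms"]

DEFAULT_LABEL = "insect"


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in pixel coordinates.

    Parameters
    ----------
    xmin, ymin, xmax, ymax
        Corner coordinates; ``xmax > xmin`` and ``ymax > ymin`` are
        required so every box has strictly positive area.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"degenerate box: ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))

    def translate(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.xmin + dx, self.ymin + dy, self.xmax + dx, self.ymax + dy)

    def intersection_area(self, other: "BoundingBox") -> float:
        iw = min(self.xmax, other.xmax) - max(self.xmin, other.xmin)
        ih = min(self.ymax, other.ymax) - max(self.ymin, other.ymin)
        if iw <= 0.0 or ih <= 0.0:
            return 0.0
        return iw * ih

    def contains(self, other: "BoundingBox") -> bool:
        """True if `other` lies entirely inside this box."""
        return (
            self.xmin <= other.xmin
            and self.ymin <= other.ymin
            and other.xmax <= self.xmax
            and other.ymax <= self.ymax
        )

    def clip(self, xmin: float, ymin: float, xmax: float, ymax: float) -> "BoundingBox | None":
        """Intersect with a clipping rectangle; None if nothing remains."""
        nx0, ny0 = max(self.xmin, xmin), max(self.ymin, ymin)
        nx1, ny1 = min(self.xmax, xmax), min(self.ymax, ymax)
        if nx1 <= nx0 or ny1 <= ny0:
            return None
        return BoundingBox(nx0, ny0, nx1, ny1)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)


@dataclass(frozen=True)
class Detection:
    """A bounding box with a confidence score — the detector output unit."""

    box: BoundingBox
    score: float
    label: str = field(default=DEFAULT_LABEL)

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes.

    Symmetric, in [0, 1]; 0 for disjoint boxes and 1 iff identical.
    """
    inter = a.intersection_area(b)
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


def nms(dets: Iterable[Detection], iou_threshold: float = 0.5) -> list[Detection]:
    """Greedy score-descending non-maximum suppression.

    Repeatedly keeps the highest-scoring remaining detection and discards
    every remaining detection whose IoU with it is strictly greater than
    ``iou_threshold`` (a pair exactly at the threshold survives).  Score
    ties are broken by input order, earlier first.  The result is sorted
    by score descending and is always a subset of the input.
    """
    if not (0.0 <= iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold {iou_threshold} outside [0, 1]")
    pool: list[Detection] = list(dets)
    # stable sort keeps input order among equal scores
    order = sorted(range(len(pool)), key=lambda i: -pool[i].score)
    kept: list[Detection] = []
    suppressed = [False] * len(pool)
    for rank, i in enumerate(order):
        if suppressed[i]:
            continue
        kept.append(pool[i])
        for j in order[rank + 1:]:
            if not suppressed[j] and iou(pool[i].box, pool[j].box) > iou_threshold:
                suppressed[j] = True
    return kept
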