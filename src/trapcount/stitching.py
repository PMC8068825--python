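"""Merging per-window detections into one trap-level detection set.

Overlapping windows see the same insect more than once, in two distinct
ways.  An insect wholly inside two windows produces two near-identical
global boxes, which global NMS collapses.  An insect *cut* by a window
border produces a partial box whose IoU with the whole-insect box from
the neighbouring window is low, so NMS alone would double-count it; such
boxes are instead removed outright whenever a box coordinate lies at an
interior window border.  Borders that coincide with the image boundary
are exempt — an insect at the trap's perimeter is clipped in every
window that sees it and would otherwise be uncountable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detectors import Detector
from .geometry import Detection, nms
from .tiling import Window, WindowGrid, compute_grid, extract_tile, to_global

__all__ = ["TrapDetectionResult", "filter_edge_boxes", "stitch", "count_trap"]

DEFAULT_EDGE_TOLERANCE = 1.0
DEFAULT_NMS_IOU = 0.5


@dataclass
class TrapDetectionResult:
    """Detections and count for one trap image.

    ``detections`` holds the stitched detections at or above
    ``score_threshold``; ``all_detections`` keeps the full stitched set
    so the threshold can be swept without re-running detection.
    """

    trap_id: str
    detections: list[Detection]
    count: int
    grid: WindowGrid
    score_threshold: float
    all_detections: list[Detection] = field(default_factory=list, repr=False)

    def count_at(self, threshold: float) -> int:
        """Count of stitched detections at an alternative score threshold."""
        return sum(1 for d in self.all_detections if d.score >= threshold)


def filter_edge_boxes(
    dets: Sequence[Detection],
    w: Window,
    grid: WindowGrid,
    tolerance: float = DEFAULT_EDGE_TOLERANCE,
) -> list[Detection]:
    """Drop window-local detections lying at an interior window border.

    A detection is removed when any box coordinate is within
    ``tolerance`` pixels of a window border, unless that border
    coincides with the image boundary.  Survivors are returned
    unchanged.
    """
    left_is_edge = w.x_offset == 0
    top_is_edge = w.y_offset == 0
    right_is_edge = w.xmax == grid.image_width
    bottom_is_edge = w.ymax == grid.image_height
    kept: list[Detection] = []
    for d in dets:
        b = d.box
        cut = (
            (b.xmin <= tolerance and not left_is_edge)
            or (b.ymin <= tolerance and not top_is_edge)
            or (b.xmax >= w.width - tolerance and not right_is_edge)
            or (b.ymax >= w.height - tolerance and not bottom_is_edge)
        )
        if not cut:
            kept.append(d)
    return kept


def stitch(
    per_window: Sequence[tuple[Window, Sequence[Detection]]],
    grid: WindowGrid,
    nms_iou: float = DEFAULT_NMS_IOU,
    tolerance: float = DEFAULT_EDGE_TOLERANCE,
    *,
    filter_edges: bool = True,
) -> list[Detection]:
    """Merge window-local detection lists into a global detection set.

    Per window: edge-box filtering, then translation to global
    coordinates; the pooled list is deduplicated by global NMS and
    returned sorted by score descending.  ``filter_edges=False`` skips
    the edge filter (leaving cut-object duplicates to NMS alone, which
    cannot remove them — useful for demonstrating why the filter exists).
    """
    pooled: list[Detection] = []
    for w, dets in per_window:
        if w not in grid:
            raise ValueError(f"window {w} does not belong to the grid")
        local = filter_edge_boxes(dets, w, grid, tolerance) if filter_edges else list(dets)
        pooled.extend(
            Detection(to_global(d.box, w), d.score, d.label) for d in local
        )
    return nms(pooled, nms_iou)


def count_trap(
    image: np.ndarray,
    detector: Detector,
    window_size: int,
    overlap: int = 100,
    score_threshold: float = 0.5,
    *,
    nms_iou: float = DEFAULT_NMS_IOU,
    edge_tolerance: float = DEFAULT_EDGE_TOLERANCE,
    filter_edges: bool = True,
    trap_id: str = "trap",
) -> TrapDetectionResult:
    """Run the full counting pipeline on one trap image.

    Builds the sliding-window grid, runs the detector on every window,
    stitches the per-window detections (edge filter + global NMS), then
    counts the stitched detections with score at or above
    ``score_threshold``.
    """
    h, w = image.shape[:2]
    grid = compute_grid(w, h, window_size, overlap)
    per_window = [
        (win, detector.detect(extract_tile(image, win), win)) for win in grid
    ]
    stitched = stitch(
        per_window, grid, nms_iou, edge_tolerance, filter_edges=filter_edges
    )
    survivors = [d for d in stitched if d.score >= score_threshold]
    return TrapDetectionResult(
        trap_id=trap_id,
        detections=survivors,
        count=len(survivors),
        grid=grid,
        score_threshold=score_threshold,
        all_detections=stitched,
    )
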