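"""Detector contract and trained-weight-free reference detectors.

The counting pipeline is detector-agnostic: any object that maps an image
tile to a list of scored boxes in tile-local coordinates can drive it.  In
the field that slot is filled by a trained CNN; here two weight-free
implementations make the pipeline exercisable end-to-end on a desk:

* :class:`BlobDetector` — a deterministic intensity/blob detector that
  finds dark connected components on the bright trap background, suitable
  for synthetic scenes.
* :class:`NoisyOracleDetector` — reads the ground truth and corrupts it
  with controllable miss, false-positive and localization-jitter rates,
  so metric and calibration behaviour can be tested under known error
  regimes (missed insects in clusters, wing-like false positives).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed
from skimage.util import img_as_float

from .geometry import BoundingBox, Detection
from .tiling import Window, to_local

__all__ = [
    "Detector",
    "BlobConfig",
    "BlobDetector",
    "blob_detect",
    "NoisyOracleConfig",
    "NoisyOracleDetector",
    "oracle_detect",
]


@runtime_checkable
class Detector(Protocol):
    """The pluggable detector contract.

    ``detect`` returns detections in tile-local coordinates, each with a
    score in [0, 1] and a box inside the tile bounds; output must be
    deterministic given the tile, the detector configuration and, for
    stochastic detectors, the window identity (which seeds per-tile
    randomness).  ``window`` is optional context: location-aware
    detectors (the oracle) use it, image-only detectors ignore it.
    """

    def detect(self, tile: np.ndarray, window: Window | None = None) -> list[Detection]:
        ...


# ---------------------------------------------------------------------------
# blob detector
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlobConfig:
    """Configuration of the intensity/blob detector.

    threshold
        Grayscale cut in [0, 1]; pixels darker than it are foreground.
        ``None`` selects the threshold per tile by Otsu's method.
    min_area, max_area
        Connected-component area bounds in pixels; components outside
        them are discarded (speckle noise below, merged clutter above).
        ``max_area=None`` means unbounded.
    min_contrast
        Minimum background-to-component contrast for a component to be
        emitted; rejects Otsu splits of near-uniform tiles.
    split_touching
        Split merged components of touching insects by watershed on the
        distance transform (peak separation adapted to the median
        component radius in the tile).  Components touching the tile
        border are never split, so objects cut by the tiling still
        produce a single border-touching box for the stitching stage's
        edge filter to remove.
    """

    threshold: float | None = 0.5
    min_area: float = 20.0
    max_area: float | None = None
    min_contrast: float = 0.05
    split_touching: bool = True


def _split_touching_components(lbl: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Split merged blobs of touching objects by marker-based watershed.

    Markers are distance-transform peaks with a minimum separation of
    0.8x the median equivalent component radius, so a single convex blob
    is never split while side-by-side pairs are.  Components whose
    bounding box lies within 2 px of the tile border keep their original
    label: partial objects at the tiling seams must stay single
    border-touching boxes.
    """
    regions = regionprops(lbl)
    if not regions:
        return lbl
    med_radius = float(np.median([np.sqrt(r.area / np.pi) for r in regions]))
    min_distance = max(2, int(round(0.8 * med_radius)))
    h, w = lbl.shape
    protected = np.zeros(lbl.max() + 1, dtype=bool)
    for r in regions:
        minr, minc, maxr, maxc = r.bbox
        if minr < 2 or minc < 2 or maxr > h - 2 or maxc > w - 2:
            protected[r.label] = True
    dist = ndi.distance_transform_edt(mask)
    coords = peak_local_max(
        dist, min_distance=min_distance, labels=lbl, exclude_border=False
    )
    if len(coords) <= len(regions):
        return lbl
    markers = np.zeros(lbl.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    split = watershed(-dist, markers, mask=mask)
    keep_parent = protected[lbl]
    return np.where(keep_parent, lbl, split + lbl.max())


def blob_detect(tile: np.ndarray, config: BlobConfig = BlobConfig()) -> list[Detection]:
    """Detect dark blobs on a bright background in one tile.

    Grayscale conversion, intensity threshold (fixed or Otsu), connected
    components, area filter; each surviving component becomes a Detection
    whose box is the component's bounding rectangle and whose score is
    the component's mean contrast against the tile background, clipped
    to [0, 1].
    """
    gray = img_as_float(tile)
    if gray.ndim == 3:
        gray = rgb2gray(gray)
    if config.threshold is not None:
        cut = config.threshold
    else:
        if gray.std() < 1e-6:
            return []
        cut = threshold_otsu(gray)
    mask = gray < cut
    if not mask.any():
        return []
    background = float(np.median(gray[~mask])) if (~mask).any() else 1.0
    lbl = label(mask, connectivity=2)
    if config.split_touching:
        lbl = _split_touching_components(lbl, mask)
    dets: list[Detection] = []
    for region in regionprops(lbl, intensity_image=gray):
        if region.area < config.min_area:
            continue
        if config.max_area is not None and region.area > config.max_area:
            continue
        contrast = background - float(region.intensity_mean)
        if contrast < config.min_contrast:
            continue
        score = float(np.clip(contrast / max(background, 1e-9), 0.0, 1.0))
        minr, minc, maxr, maxc = region.bbox  # half-open, matches box convention
        dets.append(Detection(BoundingBox(minc, minr, maxc, maxr), score))
    dets.sort(key=lambda d: -d.score)
    return dets


class BlobDetector:
    """Deterministic dark-blob detector satisfying the Detector contract."""

    def __init__(self, config: BlobConfig | None = None, **kwargs) -> None:
        self.config = config if config is not None else BlobConfig(**kwargs)

    def detect(self, tile: np.ndarray, window: Window | None = None) -> list[Detection]:
        return blob_detect(tile, self.config)


# ---------------------------------------------------------------------------
# noisy oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoisyOracleConfig:
    """Error model of the ground-truth oracle detector.

    With the defaults (all noise off, true score 1.0) the oracle
    reproduces the ground truth exactly.

    miss_rate
        Probability that a truth box is dropped.
    false_positive_rate_per_tile
        Poisson mean of spurious boxes added per tile.
    localization_jitter
        Maximum absolute per-coordinate perturbation, in pixels.
    true_score_range, fp_score_range
        Uniform score laws for true and spurious boxes.
    fp_box_size
        Nominal side of spurious boxes, in pixels.
    """

    miss_rate: float = 0.0
    false_positive_rate_per_tile: float = 0.0
    localization_jitter: float = 0.0
    true_score_range: tuple[float, float] = (1.0, 1.0)
    fp_score_range: tuple[float, float] = (0.05, 0.5)
    fp_box_size: float = 60.0
    seed: int = 0


def _emit_noisy(
    boxes: Sequence[BoundingBox],
    tile_w: float,
    tile_h: float,
    config: NoisyOracleConfig,
    rng: np.random.Generator,
) -> list[Detection]:
    dets: list[Detection] = []
    for box in boxes:
        if config.miss_rate > 0 and rng.random() < config.miss_rate:
            continue
        if config.localization_jitter > 0:
            j = rng.uniform(-config.localization_jitter, config.localization_jitter, 4)
            jittered = BoundingBox(
                min(box.xmin + j[0], box.xmax + j[2] - 1e-6),
                min(box.ymin + j[1], box.ymax + j[3] - 1e-6),
                max(box.xmax + j[2], box.xmin + j[0] + 1e-6),
                max(box.ymax + j[3], box.ymin + j[1] + 1e-6),
            )
            clipped = jittered.clip(0.0, 0.0, tile_w, tile_h)
            if clipped is None:
                continue
            box = clipped
        score = float(rng.uniform(*config.true_score_range))
        dets.append(Detection(box, min(max(score, 0.0), 1.0)))
    n_fp = int(rng.poisson(config.false_positive_rate_per_tile))
    for _ in range(n_fp):
        s = config.fp_box_size
        side_x = s * rng.uniform(0.6, 1.4)
        side_y = s * rng.uniform(0.6, 1.4)
        if side_x >= tile_w or side_y >= tile_h:
            continue
        x0 = rng.uniform(0.0, tile_w - side_x)
        y0 = rng.uniform(0.0, tile_h - side_y)
        score = float(rng.uniform(*config.fp_score_range))
        dets.append(Detection(BoundingBox(x0, y0, x0 + side_x, y0 + side_y), score))
    dets.sort(key=lambda d: -d.score)
    return dets


def oracle_detect(
    tile: np.ndarray,
    truth: Sequence[BoundingBox],
    config: NoisyOracleConfig = NoisyOracleConfig(),
    rng: np.random.Generator | None = None,
) -> list[Detection]:
    """Corrupt tile-local truth boxes according to the oracle error model."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = tile.shape[:2]
    return _emit_noisy(truth, float(w), float(h), config, rng)


class NoisyOracleDetector:
    """Ground-truth oracle over global annotations, honouring the contract.

    Holds the truth boxes in global image coordinates; when asked to
    detect on a window it localizes the truths to that window first.  A
    truth box only partially inside the window is emitted clipped to the
    window — exactly what a real detector sees for an insect cut by the
    tiling, which is the input the stitching stage's edge filter exists
    to clean up.  Per-tile randomness is seeded from (seed, window
    offsets), so repeated runs are reproducible and independent of the
    window processing order.
    """

    def __init__(
        self,
        truth: Sequence[BoundingBox],
        config: NoisyOracleConfig | None = None,
        *,
        emit_partial: bool = True,
    ) -> None:
        self.truth = list(truth)
        self.config = config if config is not None else NoisyOracleConfig()
        self.emit_partial = emit_partial

    def detect(self, tile: np.ndarray, window: Window | None = None) -> list[Detection]:
        h, w = tile.shape[:2]
        if window is None:
            window = Window(0, 0, 0, 0, w, h)
        rng = np.random.default_rng(
            [self.config.seed & 0x7FFFFFFF, window.x_offset, window.y_offset]
        )
        local: list[BoundingBox] = []
        for box in self.truth:
            visible = box.clip(window.x_offset, window.y_offset, window.xmax, window.ymax)
            if visible is None:
                continue
            if visible.as_tuple() != box.as_tuple() and not self.emit_partial:
                continue
            local.append(to_local(visible, window))
        return _emit_noisy(local, float(w), float(h), self.config, rng)
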