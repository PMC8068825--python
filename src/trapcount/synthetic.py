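"""Seeded synthetic sticky-trap scenes with ground-truth annotations.

Real monitoring data for the black pine bast scale consists of yellow
pheromone-trap photographs (nominally 6000 x 4000 px) bearing hundreds of
~60 px dark insects, frequently overlapping in clusters, among pale
wing-like debris that tempts detectors into false positives.  No such
image set is distributed here; this module emulates its statistical
structure so the whole pipeline — tiling, detection, stitching, metrics,
calibration — can be exercised without any download or trained model.

Insects are dark rotated ellipses; the emitted ground-truth box of each
insect is the bounding rectangle of its actually rendered pixels, so the
generator is its own census.  A configurable fraction of insects is
placed within one body-diameter of a cluster mate (producing overlaps,
the dominant real-world error mode); the rest are placed with rejection
sampling so they never touch.  Distractors are bright elongated ellipses
and are rendered but never annotated.

Scenes can be rendered at reduced scale (same insect:image and
insect:window ratios) so a full stratified benchmark fits in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .geometry import BoundingBox

__all__ = [
    "SceneConfig",
    "TrapSample",
    "BenchmarkDataset",
    "generate_scene",
    "generate_benchmark",
    "DENSITY_BANDS",
]

# trap-count strata: fewer than 300, 300-500, more than 500 insects per trap
DENSITY_BANDS: dict[str, tuple[int, int]] = {
    "low": (150, 299),
    "mid": (300, 500),
    "high": (501, 650),
}


def density_band(n_insects: int) -> str:
    if n_insects < 300:
        return "low"
    if n_insects <= 500:
        return "mid"
    return "high"


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic trap scene.

    Defaults mirror the real acquisition: a 6000 x 4000 image with
    insects of mean box side 60 px.  ``scaled`` produces a geometrically
    consistent reduced-scale variant for fast tests.
    """

    image_width: int = 6000
    image_height: int = 4000
    n_insects: int = 250
    insect_size_mean: float = 60.0
    insect_size_sd: float = 6.0
    cluster_fraction: float = 0.05
    n_distractors: int = 20
    background_rgb: tuple[int, int, int] = (205, 185, 60)
    noise_sd: float = 6.0
    seed: int = 0

    @property
    def density_band(self) -> str:
        """Stratum of the configured count: low (<300), mid (300-500), high (>500)."""
        return density_band(self.n_insects)

    def scaled(self, factor: float) -> "SceneConfig":
        """Scale the scene geometry (image and insect sizes) by `factor`."""
        return replace(
            self,
            image_width=int(round(self.image_width * factor)),
            image_height=int(round(self.image_height * factor)),
            insect_size_mean=self.insect_size_mean * factor,
            insect_size_sd=self.insect_size_sd * factor,
        )


def _place_centers(config: SceneConfig, sizes: np.ndarray, rng: np.random.Generator):
    """Choose insect centers: non-overlapping singles plus clustered pairs."""
    w, h = config.image_width, config.image_height
    n = config.n_insects
    n_cluster = int(round(config.cluster_fraction * n))
    n_free = n - n_cluster
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    gap = 2.0
    max_attempts = 400
    for i in range(n_free):
        r = sizes[i] / 2.0
        lo_x, hi_x = r + 1, w - r - 1
        lo_y, hi_y = r + 1, h - r - 1
        if hi_x <= lo_x or hi_y <= lo_y:
            raise ValueError("insect larger than image")
        for attempt in range(max_attempts):
            cx = rng.uniform(lo_x, hi_x)
            cy = rng.uniform(lo_y, hi_y)
            ok = all(
                (cx - px) ** 2 + (cy - py) ** 2 >= (r + pr + gap) ** 2
                for (px, py), pr in zip(centers, radii)
            )
            if ok:
                break
        else:
            raise ValueError(
                f"density infeasible: could not place insect {i + 1}/{n} "
                f"without overlap in {w} x {h}"
            )
        centers.append((cx, cy))
        radii.append(r)
    for i in range(n_free, n):
        r = sizes[i] / 2.0
        if centers:
            mate = centers[int(rng.integers(len(centers)))]
        else:
            mate = (w / 2.0, h / 2.0)
        # within one body diameter of the mate -> overlaps are likely
        for _ in range(max_attempts):
            ang = rng.uniform(0.0, 2.0 * np.pi)
            dist = rng.uniform(0.3, 1.0) * sizes[i]
            cx = mate[0] + dist * np.cos(ang)
            cy = mate[1] + dist * np.sin(ang)
            if r + 1 <= cx <= w - r - 1 and r + 1 <= cy <= h - r - 1:
                break
        else:
            cx = min(max(mate[0], r + 1), w - r - 1)
            cy = min(max(mate[1], r + 1), h - r - 1)
        centers.append((cx, cy))
        radii.append(r)
    return centers


def generate_scene(config: SceneConfig) -> tuple[np.ndarray, list[BoundingBox]]:
    """Render one synthetic trap image and its ground-truth boxes.

    Returns an (H, W, 3) uint8 array and one box per insect, the tight
    bounding rectangle of the insect's rendered pixels (half-open
    convention).  Distractors are drawn but not annotated.  Output is a
    pure function of the config, including its seed.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.image_width, config.image_height
    base = np.asarray(config.background_rgb, dtype=float)
    image = np.empty((h, w, 3), dtype=float)
    image[:] = base
    if config.noise_sd > 0:
        image += rng.normal(0.0, config.noise_sd, size=(h, w, 3))

    lo = max(config.insect_size_mean * 0.5, 4.0)
    hi = config.insect_size_mean * 1.5
    sizes = np.clip(
        rng.normal(config.insect_size_mean, config.insect_size_sd, config.n_insects),
        lo,
        hi,
    )
    centers = _place_centers(config, sizes, rng)

    truth: list[BoundingBox] = []
    for (cx, cy), s in zip(centers, sizes):
        a = s / 2.0
        b = a * rng.uniform(0.8, 1.0)
        theta = rng.uniform(-np.pi, np.pi)
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
        color = np.array([45.0, 35.0, 25.0]) + rng.uniform(-15.0, 15.0)
        image[rr, cc] = color + rng.normal(0.0, 3.0, size=(rr.size, 3))
        truth.append(
            BoundingBox(float(cc.min()), float(rr.min()), float(cc.max() + 1), float(rr.max() + 1))
        )

    # wing-like distractors: pale, elongated, never annotated
    for _ in range(config.n_distractors):
        length = config.insect_size_mean * rng.uniform(0.8, 1.6) / 2.0
        width = length * rng.uniform(0.2, 0.35)
        cx = rng.uniform(length, w - length)
        cy = rng.uniform(length, h - length)
        theta = rng.uniform(-np.pi, np.pi)
        rr, cc = draw_ellipse(cy, cx, length, width, shape=(h, w), rotation=theta)
        color = np.array([232.0, 228.0, 212.0]) + rng.uniform(-10.0, 10.0)
        image[rr, cc] = color

    return np.clip(image, 0, 255).astype(np.uint8), truth


@dataclass
class TrapSample:
    """One benchmark trap: image, annotations, and its manual-count surrogate."""

    trap_id: str
    image: np.ndarray
    truth: list[BoundingBox]
    band: str

    @property
    def count(self) -> int:
        return len(self.truth)


@dataclass
class BenchmarkDataset:
    """A stratified set of synthetic traps with annotations and counts."""

    traps: list[TrapSample]
    template: SceneConfig

    def __len__(self) -> int:
        return len(self.traps)

    def counts(self) -> dict[str, int]:
        return {t.trap_id: t.count for t in self.traps}

    def save(self, out_dir: str | Path) -> None:
        """Write images (PNG), annotations (Pascal-VOC XML) and counts (CSV)."""
        from PIL import Image as PILImage

        from .io import AnnotationRecord, write_annotations, write_counts_csv

        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "annotations").mkdir(parents=True, exist_ok=True)
        records = []
        for t in self.traps:
            PILImage.fromarray(t.image).save(out / "images" / f"{t.trap_id}.png")
            records.append(
                AnnotationRecord(
                    image_id=t.trap_id,
                    width=t.image.shape[1],
                    height=t.image.shape[0],
                    boxes=[("insect", b) for b in t.truth],
                )
            )
        write_annotations(records, out / "annotations", fmt="voc")
        write_counts_csv(
            {t.trap_id: t.count for t in self.traps}, out / "counts.csv"
        )


def generate_benchmark(
    n_per_band: int = 10,
    template: SceneConfig | None = None,
    seed: int = 0,
    bands: dict[str, tuple[int, int]] | None = None,
) -> BenchmarkDataset:
    """Generate the stratified trap benchmark.

    ``n_per_band`` traps are drawn in each density band (by default the
    three monitoring strata of fewer than 300, 300-500, and more than
    500 insects per trap), each with an independent seed derived from
    ``seed``.  The per-trap manual-count surrogate C_i is the exact
    number of generated insects.
    """
    template = template if template is not None else SceneConfig()
    bands = bands if bands is not None else DENSITY_BANDS
    rng = np.random.default_rng(seed)
    traps: list[TrapSample] = []
    for band, (lo, hi) in bands.items():
        for k in range(n_per_band):
            n = int(rng.integers(lo, hi + 1))
            cfg = replace(
                template,
                n_insects=n,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            image, truth = generate_scene(cfg)
            traps.append(
                TrapSample(
                    trap_id=f"trap_{band}_{k:02d}", image=image, truth=truth, band=band
                )
            )
    return BenchmarkDataset(traps=traps, template=template)
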