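"""Overlap-aware sliding-window grids over large trap images.

A 6000 x 4000 trap photographed at full resolution is far too large for a
detector tuned to ~60 px insects, so the image is scanned with fixed-size
windows that overlap by more than one insect diameter: an insect cut at
one window's edge is then guaranteed to appear whole in a neighbouring
window.  With a 500 px window and 100 px overlap the standard trap image
yields a 15 x 10 grid (150 windows); with a 1000 px window, 7 x 5 (35).

The final window in each axis is clamped to the image edge rather than
padded, so every window has exactly the configured size and the grid
counts above fall out of ``n = ceil((L - window) / stride) + 1``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import BoundingBox

__all__ = ["Window", "WindowGrid", "compute_grid", "extract_tile", "to_global", "to_local"]


@dataclass(frozen=True)
class Window:
    """One tile of the scanning grid: a global offset plus a fixed size."""

    col_index: int
    row_index: int
    x_offset: int
    y_offset: int
    width: int
    height: int

    @property
    def xmax(self) -> int:
        return self.x_offset + self.width

    @property
    def ymax(self) -> int:
        return self.y_offset + self.height


@dataclass(frozen=True)
class WindowGrid:
    """The full row-major grid of scanning windows for one image."""

    image_width: int
    image_height: int
    window_size: int
    overlap: int
    n_cols: int
    n_rows: int
    windows: tuple[Window, ...] = field(repr=False)

    @property
    def stride(self) -> int:
        return self.window_size - self.overlap

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __contains__(self, w: Window) -> bool:
        return w in self.windows

    def to_json(self) -> str:
        """Serialize the grid parameters and window offsets for provenance logs."""
        return json.dumps(
            {
                "image_width": self.image_width,
                "image_height": self.image_height,
                "window_size": self.window_size,
                "overlap": self.overlap,
                "n_cols": self.n_cols,
                "n_rows": self.n_rows,
                "offsets": [[w.x_offset, w.y_offset] for w in self.windows],
            }
        )


def _axis_offsets(length: int, window: int, stride: int) -> list[int]:
    n = math.ceil((length - window) / stride) + 1 if length > window else 1
    offsets = [i * stride for i in range(n - 1)]
    offsets.append(length - window)  # clamp the final window to the edge
    return offsets


def compute_grid(
    image_width: int, image_height: int, window_size: int, overlap: int
) -> WindowGrid:
    """Build the sliding-window grid for an image.

    Windows are placed at multiples of ``stride = window_size - overlap``
    with the last window in each axis clamped to the image boundary, so
    the union of windows covers every pixel and adjacent windows overlap
    by at least ``overlap`` pixels.

    Raises
    ------
    ValueError
        If the window exceeds the image in either axis, or if
        ``overlap >= window_size`` (non-positive stride).
    """
    if window_size > min(image_width, image_height):
        raise ValueError(
            f"window {window_size} exceeds image {image_width} x {image_height}"
        )
    if not (0 <= overlap < window_size):
        raise ValueError(f"overlap {overlap} must satisfy 0 <= overlap < window_size")
    stride = window_size - overlap
    xs = _axis_offsets(image_width, window_size, stride)
    ys = _axis_offsets(image_height, window_size, stride)
    windows = tuple(
        Window(ci, ri, x, y, window_size, window_size)
        for ri, y in enumerate(ys)
        for ci, x in enumerate(xs)
    )
    return WindowGrid(
        image_width=image_width,
        image_height=image_height,
        window_size=window_size,
        overlap=overlap,
        n_cols=len(xs),
        n_rows=len(ys),
        windows=windows,
    )


def extract_tile(image: np.ndarray, w: Window) -> np.ndarray:
    """Crop a window from an image array (rows = y, cols = x).

    Grids built by :func:`compute_grid` always lie within the image, so no
    padding is ever required; a window out of bounds signals a grid that
    does not belong to this image.
    """
    h, wid = image.shape[:2]
    if w.x_offset < 0 or w.y_offset < 0 or w.xmax > wid or w.ymax > h:
        raise ValueError(f"window {w} out of bounds for image {wid} x {h}")
    return image[w.y_offset : w.ymax, w.x_offset : w.xmax]


def to_global(local: BoundingBox, w: Window) -> BoundingBox:
    """Translate a window-local box into global image coordinates."""
    return local.translate(w.x_offset, w.y_offset)


def to_local(box: BoundingBox, w: Window) -> BoundingBox:
    """Translate a global box into window-local coordinates (inverse of to_global)."""
    return box.translate(-w.x_offset, -w.y_offset)
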