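"""Core geometric containers shared across the pipeline.

Conventions used everywhere in this package:

* Images are 2-D ``float64`` numpy arrays in ``(row, col)`` order with
  0-based indices.
* Physical coordinates are in nanometres; the centre of pixel ``(r, c)``
  sits at ``((c + 0.5) * pixel_size_nm, (r + 0.5) * pixel_size_nm)`` in
  ``(x, y)`` order, with y increasing down the rows.
* Patch windows are half-open: a window anchored at ``(r0, c0)`` of side
  ``s`` covers rows ``r0 .. r0 + s`` (exclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ImageGrid",
    "CanvasGeometry",
    "SegmentationGeometry",
    "window_starts",
    "LR_PIXEL_NM",
    "SR_PIXEL_NM",
]

#: Camera pixel size of the conventional (diffraction-limited) images.
LR_PIXEL_NM = 160.0
#: Pixel size of the super-resolution rendering target.
SR_PIXEL_NM = 32.0


@dataclass
class ImageGrid:
    """A 2-D grayscale image with physical pixel-size metadata."""

    data: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"ImageGrid requires a 2-D array, got shape {self.data.shape}")
        if not self.pixel_size_nm > 0:
            raise ValueError(f"pixel_size_nm must be positive, got {self.pixel_size_nm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def height_px(self) -> int:
        return self.data.shape[0]

    @property
    def width_px(self) -> int:
        return self.data.shape[1]

    @property
    def extent_nm(self) -> tuple[float, float]:
        """Physical (width, height) of the canvas in nanometres."""
        return (self.width_px * self.pixel_size_nm, self.height_px * self.pixel_size_nm)

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.data.copy(), self.pixel_size_nm)


@dataclass(frozen=True)
class CanvasGeometry:
    """Pixel dimensions and physical pixel size of a rendering canvas."""

    width_px: int
    height_px: int
    pixel_size_nm: float

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("canvas dimensions must be positive")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def extent_nm(self) -> tuple[float, float]:
        return (self.width_px * self.pixel_size_nm, self.height_px * self.pixel_size_nm)

    @property
    def center_nm(self) -> tuple[float, float]:
        w, h = self.extent_nm
        return (w / 2.0, h / 2.0)

    def scaled(self, factor: int) -> "CanvasGeometry":
        """Geometry of the same physical canvas sampled ``factor`` times finer."""
        return CanvasGeometry(
            self.width_px * factor, self.height_px * factor, self.pixel_size_nm / factor
        )


# Default canvases: single/crossing examples live on a 50 px LR field
# (8 um) whose SR counterpart is 250 px at 32 nm; random examples on a
# 200 px LR field paired with 1000 px SR.
DEFAULT_LR_CANVAS = CanvasGeometry(50, 50, LR_PIXEL_NM)
DEFAULT_SR_CANVAS = CanvasGeometry(250, 250, SR_PIXEL_NM)
DEFAULT_LR_CANVAS_RANDOM = CanvasGeometry(200, 200, LR_PIXEL_NM)
DEFAULT_SR_CANVAS_RANDOM = CanvasGeometry(1000, 1000, SR_PIXEL_NM)


@dataclass(frozen=True)
class SegmentationGeometry:
    """How an up-sampled image is cut into an overlapping patch grid.

    ``patch_px`` is the LR patch side, ``step_px`` the grid stride and
    ``pairing_core_px`` the side of the central LR region that is paired
    with the SR image when building a database.  Adjacent patches overlap
    by ``patch_px - step_px`` pixels along the stepping axis.
    """

    patch_px: int = 21
    step_px: int = 5
    pairing_core_px: int = 15

    def __post_init__(self) -> None:
        if self.patch_px < 1 or self.step_px < 1:
            raise ValueError("patch_px and step_px must be >= 1")
        if self.patch_px < self.step_px:
            raise ValueError("patch_px must be >= step_px so adjacent patches overlap")
        if self.pairing_core_px > self.patch_px:
            raise ValueError("pairing_core_px cannot exceed patch_px")
        if (self.patch_px - self.pairing_core_px) % 2 != 0:
            raise ValueError("patch_px - pairing_core_px must be even (centred core)")

    @property
    def overlap_px(self) -> int:
        """Overlap of adjacent patches along the stepping axis."""
        return self.patch_px - self.step_px

    @property
    def core_overlap_px(self) -> int:
        """Overlap of adjacent pairing cores (SR patches) along the axis."""
        return self.pairing_core_px - self.step_px

    @property
    def core_margin_px(self) -> int:
        """Offset of the pairing core inside the LR patch."""
        return (self.patch_px - self.pairing_core_px) // 2


#: Database segmentation: 21 px patches every 5 px, 15 px SR cores.
DB_GEOMETRY = SegmentationGeometry(patch_px=21, step_px=5, pairing_core_px=15)
#: Input segmentation: 21 px patches every 12 px.
INPUT_GEOMETRY = SegmentationGeometry(patch_px=21, step_px=12, pairing_core_px=15)


def window_starts(length: int, window: int, step: int) -> np.ndarray:
    """Anchor positions of ``window``-wide patches tiling ``length`` pixels.

    Windows advance by ``step``; if the last regular window does not reach
    the far border, one extra window clamped to ``length - window`` is
    appended so that every pixel is covered.
    """
    if length < window:
        raise ValueError(f"image extent {length} is smaller than the patch size {window}")
    last = length - window
    starts = list(range(0, last + 1, step))
    if starts[-1] != last:
        starts.append(last)
    return np.asarray(starts, dtype=np.intp)
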