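"""Translation-ensemble averaging.

The example database only covers rotational variants of the filament
geometry (category-1/2 examples are centred), so a reconstruction can
depend on where the patch grid happens to fall on the input.  To
compensate, the input is translated at single-pixel steps on the
up-sampled (32 nm) grid, each translated copy is reconstructed, the SR
results are translated back, and the final image is their pixel-wise
mean.  Only sub-period shifts change the patch content relative to the
grid, so the default shift grid spans one input-segmentation period
(12 x 12 shifts).

The per-pixel standard deviation across the shifted reconstructions is a
reliability map: where the database contains the true structure, every
shifted patch finds the same match and the SD is low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .database import PatchDatabase, upsample
from .grid import INPUT_GEOMETRY, ImageGrid, SegmentationGeometry, window_starts
from .mrf import InferenceConfig, reconstruct_upsampled

__all__ = ["EnsembleConfig", "EnsembleResult", "ensemble_reconstruct", "reliability_mask"]


@dataclass(frozen=True)
class EnsembleConfig:
    """Shift counts per axis (on the up-sampled grid) plus inference options."""

    shifts_x: int = INPUT_GEOMETRY.step_px
    shifts_y: int = INPUT_GEOMETRY.step_px
    inference: InferenceConfig = field(default_factory=InferenceConfig)

    def __post_init__(self) -> None:
        if self.shifts_x < 1 or self.shifts_y < 1:
            raise ValueError("shift counts must be >= 1")

    @property
    def n_shifts(self) -> int:
        return self.shifts_x * self.shifts_y


@dataclass
class EnsembleResult:
    """Mean SR image, per-pixel SD map, and per-pixel shift coverage."""

    mean_sr: ImageGrid
    sd_map: ImageGrid
    coverage: ImageGrid  # number of shifted reconstructions covering each pixel
    n_shifts: int


def _covered_box(length: int, patch: int, step: int, margin: int, core: int):
    """Pixel range [lo, hi) covered by stitched SR cores along one axis."""
    starts = window_starts(length, patch, step)
    return int(starts[0]) + margin, int(starts[-1]) + margin + core


def ensemble_reconstruct(
    lr_input: ImageGrid,
    db: PatchDatabase,
    config: EnsembleConfig = EnsembleConfig(),
    geometry: SegmentationGeometry = INPUT_GEOMETRY,
) -> EnsembleResult:
    """Average reconstructions of single-pixel-shifted copies of the input.

    A shift ``(dx, dy)`` crops the first ``dy`` rows and ``dx`` columns of
    the up-sampled input (no pixels are invented), reconstructs the crop,
    and the inverse translation places the result back at ``(dy, dx)``.
    Pixels are averaged over the shifts that actually cover them.
    """
    import math

    if not math.isclose(lr_input.pixel_size_nm, db.lr_pixel_size_nm):
        raise ValueError(
            f"input pixel size {lr_input.pixel_size_nm} nm does not match the "
            f"database's native LR pixel size {db.lr_pixel_size_nm} nm"
        )
    factor = int(round(db.lr_pixel_size_nm / db.pixel_size_nm))
    up = upsample(lr_input, factor)
    h, w = up.shape
    max_dy, max_dx = config.shifts_y - 1, config.shifts_x - 1
    if h - max_dy < geometry.patch_px or w - max_dx < geometry.patch_px:
        raise ValueError(
            f"shift grid {config.shifts_x} x {config.shifts_y} leaves less than "
            f"one {geometry.patch_px}-pixel patch of the {w} x {h} input"
        )
    acc = np.zeros((h, w))
    acc2 = np.zeros((h, w))
    cnt = np.zeros((h, w))
    margin = geometry.core_margin_px
    core = geometry.pairing_core_px
    for dy in range(config.shifts_y):
        for dx in range(config.shifts_x):
            crop = ImageGrid(up.data[dy:, dx:], up.pixel_size_nm)
            sr = reconstruct_upsampled(crop, db, config.inference, geometry)
            r_lo, r_hi = _covered_box(h - dy, geometry.patch_px, geometry.step_px, margin, core)
            c_lo, c_hi = _covered_box(w - dx, geometry.patch_px, geometry.step_px, margin, core)
            block = sr.data[r_lo:r_hi, c_lo:c_hi]
            rows = slice(dy + r_lo, dy + r_hi)
            cols = slice(dx + c_lo, dx + c_hi)
            acc[rows, cols] += block
            acc2[rows, cols] += block**2
            cnt[rows, cols] += 1.0
    covered = cnt > 0
    mean = np.divide(acc, cnt, out=np.zeros_like(acc), where=covered)
    var = np.divide(acc2, cnt, out=np.zeros_like(acc2), where=covered) - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))
    return EnsembleResult(
        mean_sr=ImageGrid(mean, up.pixel_size_nm),
        sd_map=ImageGrid(sd, up.pixel_size_nm),
        coverage=ImageGrid(cnt, up.pixel_size_nm),
        n_shifts=config.n_shifts,
    )


def reliability_mask(result: EnsembleResult, sd_threshold: float) -> ImageGrid:
    """Binary map of pixels whose across-shift SD is at most the threshold."""
    if sd_threshold < 0:
        raise ValueError("sd_threshold must be >= 0")
    mask = (result.sd_map.data <= sd_threshold).astype(np.float64)
    return ImageGrid(mask, result.sd_map.pixel_size_nm)
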