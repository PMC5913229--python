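"""Quantitative evaluation of reconstructions.

Covers the structural similarity index (SSIM) against ground truth, an
operational two-filament resolution measurement, database-size sweeps,
the SNR-matching study, line-profile FWHM measurement, and the Laplacian
contrast enhancement used for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.metrics import structural_similarity

from .database import PatchDatabase, build_database
from .grid import CanvasGeometry, ImageGrid, LR_PIXEL_NM, SR_PIXEL_NM
from .mrf import InferenceConfig, reconstruct
from .simulate import (
    FilamentSpec,
    LR_WIDTH_NM,
    SR_WIDTH_NM,
    add_noise,
    make_crossing_set,
    make_random_set,
    make_single_set,
    render_filaments,
)

__all__ = [
    "ssim",
    "fwhm",
    "laplacian_enhance",
    "ResolutionProbe",
    "measure_resolution",
    "SweepResult",
    "run_dbsize_sweep",
    "SNRStudyResult",
    "run_snr_study",
    "EVAL_LR_CANVAS",
    "EVAL_SR_CANVAS",
]

# Desk-scale evaluation canvases: a 3.2 um field keeps database builds and
# reconstructions fast while leaving room for several patch periods.
EVAL_LR_CANVAS = CanvasGeometry(20, 20, LR_PIXEL_NM)
EVAL_SR_CANVAS = CanvasGeometry(100, 100, SR_PIXEL_NM)


def ssim(img_a, img_b) -> float:
    """Standard SSIM (luminance, contrast, structure; 11-pixel Gaussian
    window, sigma 1.5), averaged over the image.  1.0 for identical images.
    """
    a = img_a.data if isinstance(img_a, ImageGrid) else np.asarray(img_a, dtype=np.float64)
    b = img_b.data if isinstance(img_b, ImageGrid) else np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    data_range = float(max(a.max(), b.max()) - min(a.min(), b.min()))
    if data_range == 0.0:
        return 1.0  # both images constant and equal
    return float(
        structural_similarity(
            a,
            b,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def fwhm(profile: np.ndarray, pixel_size_nm: float) -> float:
    """Full width at half maximum of a 1-D profile, in nm.

    The half level is measured above the profile's baseline (its minimum)
    and the crossings are located by linear interpolation around the peak.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 1 or len(p) < 3:
        raise ValueError("profile must be a 1-D array with at least 3 samples")
    lo, hi = p.min(), p.max()
    if hi <= lo:
        raise ValueError("flat profile: FWHM is undefined")
    half = lo + (hi - lo) / 2.0
    peak = int(np.argmax(p))

    def _cross(i0: int, direction: int) -> float:
        i = i0
        while 0 <= i + direction < len(p) and p[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= len(p):
            raise ValueError("profile does not fall below half maximum on one side")
        # linear interpolation between samples i (>= half) and j (< half)
        frac = (p[i] - half) / (p[i] - p[j])
        return i + direction * frac

    left = _cross(peak, -1)
    right = _cross(peak, +1)
    return float((right - left) * pixel_size_nm)


_LAPLACIAN_KERNEL = np.array(
    [[1.0, 1.0, 1.0], [1.0, -8.0, 1.0], [1.0, 1.0, 1.0]]
)


def laplacian_response(img: ImageGrid) -> ImageGrid:
    """Response of the 3 x 3 Laplacian derivative operator (centre -8)."""
    out = ndimage.convolve(img.data, _LAPLACIAN_KERNEL, mode="reflect")
    return ImageGrid(out, img.pixel_size_nm)


def laplacian_enhance(img: ImageGrid, gain: float = 1.0) -> ImageGrid:
    """Sharpen by subtracting the Laplacian response (display only)."""
    lap = laplacian_response(img)
    return ImageGrid(img.data - gain * lap.data, img.pixel_size_nm)


# ----------------------------------------------------------------------
# resolution measurement
# ----------------------------------------------------------------------


@dataclass
class ResolutionProbe:
    """Outcome of the two-filament separation test."""

    separations_nm: list[float]
    resolved_flags: list[bool]
    resolution_nm: float | None  # smallest separation resolved, or None


def two_filament_specs(
    canvas: CanvasGeometry, separation_nm: float, angle_deg: float = 0.0
) -> list[FilamentSpec]:
    """Two parallel filaments straddling the canvas centre at the given
    centre-to-centre distance."""
    cx, cy = canvas.center_nm
    w, h = canvas.extent_nm
    half = math.hypot(w, h)
    theta = math.radians(angle_deg)
    dx, dy = half * math.cos(theta), half * math.sin(theta)
    # normal to the filament direction
    nx, ny = -math.sin(theta), math.cos(theta)
    specs = []
    for s in (-separation_nm / 2.0, separation_nm / 2.0):
        ox, oy = cx + s * nx, cy + s * ny
        specs.append(FilamentSpec((ox - dx, oy - dy), (ox + dx, oy + dy)))
    return specs


def _transverse_profile(sr: ImageGrid, frac_band: float = 0.2) -> np.ndarray:
    """Row profile averaged over a central band of columns (for horizontal
    filaments, this is the transverse intensity profile at the midpoint)."""
    h, w = sr.shape
    half_band = max(1, int(w * frac_band / 2))
    c = w // 2
    return sr.data[:, c - half_band : c + half_band].mean(axis=1)


def is_resolved(
    profile: np.ndarray,
    pixel_size_nm: float,
    true_positions_nm: tuple[float, float],
    dip_fraction: float = 0.75,
    tolerance_nm: float = 100.0,
) -> bool:
    """Rayleigh-style two-peak test with a position check.

    Resolved means (a) the profile has two maxima whose inter-peak dip is
    at most ``dip_fraction`` of the lower peak, and (b) each recovered
    ridge lies within ``tolerance_nm`` of a true centreline, so a
    hallucinated double does not count.
    """
    peaks, _ = signal.find_peaks(profile)
    if len(peaks) < 2:
        return False
    # the two strongest maxima
    top2 = peaks[np.argsort(profile[peaks])[-2:]]
    p1, p2 = sorted(int(i) for i in top2)
    dip = profile[p1 : p2 + 1].min()
    lower_peak = min(profile[p1], profile[p2])
    if lower_peak <= 0 or dip > dip_fraction * lower_peak:
        return False
    measured = sorted(((i + 0.5) * pixel_size_nm for i in (p1, p2)))
    expected = sorted(true_positions_nm)
    return all(abs(m - e) <= tolerance_nm for m, e in zip(measured, expected))


def measure_resolution(
    reconstructor,
    separations_nm: list[float],
    lr_canvas: CanvasGeometry = EVAL_LR_CANVAS,
    lr_width_nm: float = LR_WIDTH_NM,
    dip_fraction: float = 0.75,
    tolerance_nm: float = 100.0,
) -> ResolutionProbe:
    """Smallest centre-to-centre filament distance the method resolves.

    ``reconstructor`` maps an LR :class:`ImageGrid` to an SR one.  For
    each separation (descending), two parallel horizontal filaments are
    rendered, reconstructed, and tested with :func:`is_resolved`.
    """
    seps = list(separations_nm)
    if not seps:
        raise ValueError("separations_nm must be nonempty")
    if any(s <= 0 for s in seps):
        raise ValueError("separations must be positive")
    if sorted(seps, reverse=True) != seps:
        raise ValueError("separations must be in descending order")
    _, cy = lr_canvas.center_nm
    flags = []
    for s in seps:
        specs = two_filament_specs(lr_canvas, s)
        lr = render_filaments(specs, lr_canvas, lr_width_nm)
        sr = reconstructor(lr)
        profile = _transverse_profile(sr)
        flags.append(
            is_resolved(
                profile,
                sr.pixel_size_nm,
                (cy - s / 2.0, cy + s / 2.0),
                dip_fraction,
                tolerance_nm,
            )
        )
    resolved = [s for s, f in zip(seps, flags) if f]
    return ResolutionProbe(seps, flags, min(resolved) if resolved else None)


# ----------------------------------------------------------------------
# database-size sweep
# ----------------------------------------------------------------------


@dataclass
class SweepResult:
    """SSIM and resolution as a function of random-filament count."""

    db_sizes: list[int]  # number of random filaments added to the database
    ssim_mean: list[float]
    ssim_sd: list[float]
    resolution_mean: list[float]  # nm; unresolved probes count at the probe max
    resolution_sd: list[float]


def _desk_scale_examples(
    lr_canvas: CanvasGeometry,
    sr_canvas: CanvasGeometry,
    angle_step_deg: float,
):
    """Fixed category-1 and category-2 examples for the sweeps.

    The angle grid covers 0..(180 - step) degrees so orientations remain
    evenly spaced without the 0/180 duplicate, at any coarseness.
    """
    if 180.0 % angle_step_deg != 0:
        raise ValueError("angle_step_deg must divide 180")
    stop = 180.0 - angle_step_deg
    singles = make_single_set(
        angle_stop_deg=stop, angle_step_deg=angle_step_deg,
        lr_canvas=lr_canvas, sr_canvas=sr_canvas,
    )
    crossings = make_crossing_set(
        angle_stop_deg=stop, angle_step_deg=angle_step_deg,
        lr_canvas=lr_canvas, sr_canvas=sr_canvas,
    )
    return singles + crossings


def build_sweep_database(
    n_random_filaments: int,
    seed: int,
    lr_canvas: CanvasGeometry = EVAL_LR_CANVAS,
    sr_canvas: CanvasGeometry = EVAL_SR_CANVAS,
    angle_step_deg: float = 30.0,
    filaments_per_image: int = 5,
) -> PatchDatabase:
    """Database with fixed category-1/2 content plus random examples
    totalling ``n_random_filaments`` filaments."""
    examples = _desk_scale_examples(lr_canvas, sr_canvas, angle_step_deg)
    if n_random_filaments > 0:
        n_images = math.ceil(n_random_filaments / filaments_per_image)
        examples += make_random_set(
            n_images,
            filaments_per_image=filaments_per_image,
            lr_canvas=lr_canvas,
            sr_canvas=sr_canvas,
            seed=seed,
        )
    return build_database(examples)


def run_dbsize_sweep(
    db_sizes: list[int],
    n_repeats: int = 3,
    seed: int = 0,
    probe_separations_nm: list[float] = (800.0, 600.0, 480.0, 320.0),
    lr_canvas: CanvasGeometry = EVAL_LR_CANVAS,
    sr_canvas: CanvasGeometry = EVAL_SR_CANVAS,
    angle_step_deg: float = 30.0,
    filaments_per_image: int = 5,
    config: InferenceConfig = InferenceConfig(),
) -> SweepResult:
    """Reconstruction quality as the database gains random examples.

    For every size, ``n_repeats`` databases are built with distinct
    random-set seeds; SSIM against the true SR object is measured on
    two-filament probes at each separation, and the resolvable separation
    is measured on the same probes.  Unresolved probes are scored at the
    largest tested separation so means remain defined.
    """
    if list(db_sizes) != sorted(db_sizes):
        raise ValueError("db_sizes must be non-decreasing")
    probe_separations_nm = sorted(probe_separations_nm, reverse=True)
    ssim_mean, ssim_sd, res_mean, res_sd = [], [], [], []
    for size in db_sizes:
        ssim_runs, res_runs = [], []
        for rep in range(n_repeats):
            db = build_sweep_database(
                size,
                seed=seed + 1000 * rep,
                lr_canvas=lr_canvas,
                sr_canvas=sr_canvas,
                angle_step_deg=angle_step_deg,
                filaments_per_image=filaments_per_image,
            )
            recon = lambda lr: reconstruct(lr, db, config)  # noqa: E731
            vals = []
            for s in probe_separations_nm:
                specs = two_filament_specs(lr_canvas, s)
                truth = render_filaments(specs, sr_canvas, SR_WIDTH_NM)
                lr = render_filaments(specs, lr_canvas, LR_WIDTH_NM)
                sr = recon(lr)
                vals.append(ssim(sr, truth))
            ssim_runs.append(float(np.mean(vals)))
            probe = measure_resolution(recon, probe_separations_nm, lr_canvas)
            res_runs.append(
                probe.resolution_nm
                if probe.resolution_nm is not None
                else probe_separations_nm[0]
            )
        ssim_mean.append(float(np.mean(ssim_runs)))
        ssim_sd.append(float(np.std(ssim_runs)))
        res_mean.append(float(np.mean(res_runs)))
        res_sd.append(float(np.std(res_runs)))
    return SweepResult(list(db_sizes), ssim_mean, ssim_sd, res_mean, res_sd)


# ----------------------------------------------------------------------
# SNR-matching study
# ----------------------------------------------------------------------


@dataclass
class SNRStudyResult:
    """SSIM of noisy-input reconstructions over a (library SNR, input SNR) grid."""

    snr_library: list[float]
    snr_input: list[float]
    ssim_table: np.ndarray  # (n_library, n_input)


def run_snr_study(
    snr_library: list[float],
    snr_input: list[float],
    seed: int = 0,
    probe_separation_nm: float = 640.0,
    n_realizations: int = 3,
    lr_canvas: CanvasGeometry = EVAL_LR_CANVAS,
    sr_canvas: CanvasGeometry = EVAL_SR_CANVAS,
    angle_step_deg: float = 30.0,
    config: InferenceConfig = InferenceConfig(),
) -> SNRStudyResult:
    """Reconstruction quality when library and input noise levels differ.

    Noise enters matching through the LR side only, so it is added to the
    LR example images before database construction; SR examples stay
    clean, as does the ground truth the output is scored against.  Each
    table cell is the mean SSIM over ``n_realizations`` independent input
    noise draws, which tames single-draw fluctuations the same way
    measuring over several images does.
    """
    if any(s <= 0 for s in list(snr_library) + list(snr_input)):
        raise ValueError("SNR values must be positive")
    specs = two_filament_specs(lr_canvas, probe_separation_nm)
    truth = render_filaments(specs, sr_canvas, SR_WIDTH_NM)
    clean_lr = render_filaments(specs, lr_canvas, LR_WIDTH_NM)
    base_examples = _desk_scale_examples(lr_canvas, sr_canvas, angle_step_deg)
    table = np.empty((len(snr_library), len(snr_input)))
    for i, s_lib in enumerate(snr_library):
        noisy_examples = []
        for n, ex in enumerate(base_examples):
            noisy = add_noise(ex.lr, s_lib, seed=seed + n)
            noisy_examples.append(
                type(ex)(
                    lr=noisy,
                    sr=ex.sr,
                    category=ex.category,
                    specs=ex.specs,
                    angles_deg=ex.angles_deg,
                )
            )
        db = build_database(noisy_examples)
        for j, s_in in enumerate(snr_input):
            vals = []
            for r in range(n_realizations):
                lr = add_noise(clean_lr, s_in, seed=seed + 7919 + r)
                sr = reconstruct(lr, db, config)
                vals.append(ssim(sr, truth))
            table[i, j] = float(np.mean(vals))
    return SNRStudyResult(list(snr_library), list(snr_input), table)
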