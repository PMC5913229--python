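# Methods

This note records, in one place, what the package computes and why the
defaults are what they are. Coordinates follow `exsr.grid`: images are
`(row, col)` float64 arrays; the centre of pixel `(r, c)` sits at
`((c + 0.5)·px, (r + 0.5)·px)` nm with y increasing down the rows.

## 1. Filament simulator (`exsr.simulate`)

A filament is a line segment with a Gaussian transverse intensity
profile. For a pixel at perpendicular distance `d` from the segment
(distance to the clamped projection, so ends are rounded), intensity is
`I·exp(−d²/2σ²)` with `σ = FWHM / (2√(2 ln 2))`. Filaments add
linearly; example images are normalized to unit peak.

Defaults (all explicit parameters, none hidden):

| quantity | LR | SR |
|---|---|---|
| pixel size | 160 nm | 32 nm |
| filament FWHM | 341 nm | 60 nm |
| single/crossing canvas | 50×50 px | 250×250 px |
| random canvas | 200×200 px | 1000×1000 px |

Example categories:

- **single** — one centred filament per image over an evenly spaced
  angle grid (default 0–178° in 2° steps → 90 images; passing
  `angle_stop_deg=None` means "180° − step", so any step dividing 180
  gives a duplicate-free grid).
- **crossing** — one image per unordered pair of grid angles
  (4005 images at the 2° default).
- **random** — `n` filaments per image (default 20) with endpoints
  drawn uniformly over the canvas; seeded `numpy` Generator, fully
  reproducible.

`degrade_to_lr` produces an LR image from an SR one by adding the
quadrature-difference blur (variance `σ_LR² − σ_SR²`) and
block-averaging 5×5; it agrees with directly rendering at LR width to
within 8% of peak and exists for validation, not for database
construction (examples are rendered at both scales directly).
`add_noise` adds Gaussian noise with SD = peak / SNR and clamps at
zero.

The SR width (60 nm) is a property of the *rendering target*, distinct
from the method's theoretical localization limit (~25 nm); both are
independent, explicit parameters rather than being coupled.

## 2. Example database (`exsr.database`)

Each LR example is up-sampled 5× by bicubic interpolation
(`skimage.transform.resize`, order 3, edge mode, no anti-aliasing —
values are preserved, nothing is invented at borders) so it lives on
the same 32 nm grid as its SR partner. The up-sampled image is cut into
21×21 patches at step 5 (16 px overlap). The 15×15 core of each LR
patch (3 px margin) is paired with the SR window at the same physical
location; adjacent SR cores overlap by 10 px.

**Boundary policy.** Patch anchors advance from the top-left in steps
of 5; if the last regular window does not reach the far border, one
extra window clamped to `length − 21` is appended so every pixel is
covered and no padding is ever introduced. A 250×250 image therefore
yields 47 starts per axis → 2209 pairs per single-filament example
(checked against brute-force enumeration in the tests).

Pairs are stored in HDF5 with their segmentation geometry and a SHA-256
provenance digest. Lookup uses an exact k-d tree
(`sklearn.neighbors.KDTree`) over flattened LR patches; results are
re-fetched within the k-th radius and re-sorted by exact squared
distance, ties broken by insertion order, so the index is bit-for-bit
equivalent to a linear scan (enforced by an oracle test).

## 3. MRF inference (`exsr.mrf`)

The input LR image is up-sampled 5× and segmented into 21×21 patches at
step 12 (9 px overlap; SR candidate cores overlap 15×3). Each node
keeps its `k = 30` nearest database pairs. In log domain:

- evidence `log ψ_i(x_i) = −‖p_i − L(x_i)‖² / 2σ₁²` (the squared
  distances come straight from the tree query);
- connectivity `log θ_ij(x_i,x_j) = −‖O_ij(S(x_i)) − O_ji(S(x_j))‖² /
  2σ₂²` over the geometric overlap of the two 15×15 SR cores.

σ₁ = σ₂ = 1 on the unit-peak intensity scale.

**Optimizer.** Damped max-product belief propagation: messages are
max-normalized, damped (`0.5·old + 0.5·new`), and updated
*sequentially* in a fixed scan order (in place), which settles loopy
graphs much more reliably than a synchronous sweep. After every sweep
the beliefs are decoded and scored with the exact joint objective; the
best assignment seen is returned ("anytime" decoding), so even an
oscillating instance yields its strongest decoding. Convergence
tolerance 1e−9, at most 50 sweeps, `argmax` ties resolve to the lowest
candidate index. On chains (trees) the result equals the exhaustive
argmax exactly; on random ≤3×3 loopy grids the decoded score is within
1% of the exhaustive optimum's score range (both properties are in the
acceptance suite). An exhaustive optimizer (capped at 2×10⁶
combinations) is provided as the testing oracle.

**Stitching.** The chosen 15×15 SR cores are placed at their anchor
positions and overlaps are averaged (sum / coverage count).

## 4. Translation ensemble (`exsr.ensemble`)

For shifts `(dx, dy)` with `0 ≤ dx < N_x`, `0 ≤ dy < N_y` (defaults
12×12, the input step, on the up-sampled grid), the first `dy` rows and
`dx` columns of the up-sampled input are cropped (observed pixels only
— no padding), the crop is reconstructed, and the inverse translation
places the result back at `(dy, dx)`. Per-pixel mean, population SD and
coverage are accumulated over the shifts that cover each pixel. A
single 1×1 "ensemble" is bit-identical to a plain reconstruction. The
SD map is a reliability indicator: `reliability_mask` thresholds it.
Note the SD map is identically zero only for a *blank* input; a
non-zero constant input legitimately selects structured patches whose
tiling is not shift-invariant.

## 5. Evaluation (`exsr.evaluate`)

- **SSIM** — `skimage.metrics.structural_similarity`, Gaussian window
  σ = 1.5, population covariance, data range = joint min–max (constant
  equal images score 1 by convention). Cross-checked against an
  independent implementation to 1e−6.
- **FWHM** — baseline = profile minimum, half level above baseline,
  crossings by linear interpolation. Calibration probes run along a
  pixel-centre row; a filament centred *between* rows samples a halved
  peak and biases the width upward. Measured at defaults: 350.26 nm
  (LR, nominal 341, one-pixel tolerance 160 nm) and 58.66 nm (SR,
  nominal 60, tolerance 32 nm).
- **Laplacian enhancement** — 3×3 all-ones kernel with −8 centre
  (reflect boundary); `laplacian_enhance` subtracts the response
  (display sharpening only, never part of inference). Response to a
  constant is zero up to float64 rounding (exact for dyadic values).
- **Resolution** — two parallel horizontal filaments at a given
  centre-to-centre distance; the transverse row profile is averaged
  over the central 20% of columns; "resolved" requires two peaks whose
  inter-peak dip is ≤ 0.75 of the lower peak *and* whose positions lie
  within 100 nm of the true centrelines (hallucinated doubles do not
  count). The resolution is the smallest resolved probe separation.
- **Database-size sweep** — evaluation canvases 20×20 LR / 100×100 SR
  (3.2 µm field), fixed content = singles + crossings at a 30° grid,
  plus random examples totalling the requested filament count (5
  filaments per image at this field size), 3 databases per size with
  distinct seeds; SSIM against ground truth on probes at
  {800, 600, 480, 320} nm and the resolution measured on the same
  probes (unresolved runs score at the largest tested separation).
- **SNR study** — noise enters matching through the LR side only, so
  it is added to LR example images before database construction; SR
  examples and the scoring ground truth stay clean. Each cell of the
  (library SNR × input SNR) table is the mean SSIM over 3 independent
  input-noise draws.

## 6. Scale of the shipped studies

Full-scale databases (2° angle grid → 90 + 4005 examples, millions of
pairs) are supported by the data structures but are not what the tests
run: the shipped studies use the 3.2 µm evaluation field and coarse
angle grids so the entire suite finishes in about a minute on one CPU,
while exercising every code path at the paper-scale geometry constants
(patch sizes, steps, pixel sizes, widths are unchanged).

## 7. Known limitations

- The prior is filament-specific; inputs whose structures are absent
  from the example set reconstruct poorly — the SD map is the intended
  safeguard.
- Loopy BP is a heuristic on grids; the acceptance bound (within 1% of
  the optimum's score range on small random grids) is a quality floor,
  not a guarantee of global optimality.
- The simulator models additive Gaussian transverse profiles and
  Gaussian noise; photophysics (blinking, background autofluorescence)
  is out of scope.
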