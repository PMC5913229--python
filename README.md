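# exsr — example-based super-resolution for fluorescence microscopy

`exsr` infers a super-resolution (SR) image from a **single**
conventional, diffraction-limited fluorescence image of filamentous
structures (e.g. microtubules). Instead of acquiring thousands of
blinking frames, it exploits prior knowledge of what filaments look
like: a database of corresponding low-resolution (LR) / SR image pairs
is generated by simulation, the input image is cut into overlapping
patches, each patch retrieves its nearest LR neighbours from the
database, and a Markov random field (MRF) selects one SR candidate per
patch such that neighbouring candidates agree where they overlap. The
chosen SR patches are stitched into the output. Averaging the
reconstructions of single-pixel-shifted copies of the input (a
translation ensemble) suppresses stitching artefacts and yields a
per-pixel standard-deviation map that flags unreliable regions.

## The model

The input is up-sampled 5× by bicubic interpolation (160 nm camera
pixels → the 32 nm SR grid) and segmented into 21×21 patches with a
step of 12 px (9 px overlap). Patch `i` keeps the `k = 30` nearest
database pairs as its candidate labels `x_i`. The joint probability of
a labelling is

```
P(x) ∝ ∏_i ψ_i(x_i) · ∏_(i,j) θ_ij(x_i, x_j)

ψ_i(x_i)      = exp( −‖p_i − L(x_i)‖² / 2σ₁² )      (evidence)
θ_ij(x_i,x_j) = exp( −‖O_ij(S(x_i)) − O_ji(S(x_j))‖² / 2σ₂² )  (connectivity)
```

where `p_i` is the input patch, `L(x)`/`S(x)` the LR/SR members of a
database pair, and `O_ij` extracts the 15×3 overlap strip between the
SR cores of neighbouring patches (σ₁ = σ₂ = 1 on the unit-peak
intensity scale). The MAP labelling is found by damped max-product
loopy belief propagation (sequential message updates; the best-scoring
decoding seen across sweeps is returned), which is exact on chains and
verified against exhaustive enumeration on small grids.

The database is built from three categories of simulated examples —
single straight filaments over an angle grid, crossing pairs at all
unordered angle combinations, and images of randomly placed filaments —
rendered with Gaussian transverse profiles of 341 nm FWHM (LR) and
60 nm FWHM (SR), segmented at step 5 (16 px overlap) with 15×15 SR
cores, and indexed with a k-d tree.

## Worked example

Build a small database (21 fixed single/crossing examples at a 30°
angle grid plus 50 random filaments on a 3.2 µm field, 8959 patch
pairs), then reconstruct a probe of two parallel filaments 480 nm
apart — less than half the ~1.2 µm LR spot the two filaments blur into:

```python
from exsr.database import upsample
from exsr.ensemble import EnsembleConfig, ensemble_reconstruct
from exsr.evaluate import (EVAL_LR_CANVAS, EVAL_SR_CANVAS,
                           build_sweep_database, ssim, two_filament_specs)
from exsr.mrf import reconstruct
from exsr.simulate import LR_WIDTH_NM, SR_WIDTH_NM, render_filaments

db = build_sweep_database(50, seed=0)          # 8959 LR/SR patch pairs
specs = two_filament_specs(EVAL_LR_CANVAS, 480.0)
lr    = render_filaments(specs, EVAL_LR_CANVAS, LR_WIDTH_NM)
truth = render_filaments(specs, EVAL_SR_CANVAS, SR_WIDTH_NM)

print(ssim(upsample(lr, 5), truth))            # 0.5466  bicubic baseline
print(ssim(reconstruct(lr, db), truth))        # 0.8476  single MRF pass
res = ensemble_reconstruct(lr, db, EnsembleConfig(shifts_x=3, shifts_y=3))
print(ssim(res.mean_sr, truth))                # 0.9607  3x3 translation ensemble
```

Against the same database, the two-filament separation test
(`exsr.evaluate.measure_resolution`) resolves all probes down to
320 nm, while bicubic up-sampling alone stops at 480 nm. Growing the
database improves quality monotonically; with 3 random-set seeds per
size:

```
$ exsr evaluate sweep --sizes 0,50,200 --seed 0 --out sweep.csv
db_size,ssim_mean,ssim_sd,resolution_mean_nm,resolution_sd_nm
0,0.826506,0.000000,320.0,0.0
50,0.880207,0.014631,320.0,0.0
200,0.911416,0.005799,320.0,0.0
```

and matching the noise level of the example library to the input helps
(each cell is the mean SSIM over 3 input-noise draws):

```
$ exsr evaluate snr --library 2,10 --input 2,10 --seed 0 --out snr.csv
snr_library,snr_input,ssim
2.0,2.0,0.725111
2.0,10.0,0.720914
10.0,2.0,0.717681
10.0,10.0,0.734235
```

## Command line

```bash
exsr simulate --category single --out examples/      # render example pairs
exsr build-db examples/ --out db.h5                  # patch database (HDF5)
exsr query db.h5 input.tif -k 5                      # inspect nearest pairs
exsr reconstruct db.h5 input.tif --out sr.tif --ensemble --shifts 12 12
exsr evaluate ssim a.tif b.tif
exsr run config.yaml                                 # full pipeline from YAML
```

Exit codes: 0 success, 2 configuration error, 3 data error. TIFF images
carry their pixel size in a JSON sidecar (`image.tif.json`).

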