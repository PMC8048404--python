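# scanforge

Image-processing and metrology toolkit for low-cost photogrammetry scanners
that image pinned specimens (insects and other small objects) on a two-axis
gimbal inside a light-grey illumination dome. Given the raw focal stacks
captured at each viewing angle, scanforge produces the masked,
metadata-tagged images that photogrammetry packages (e.g. Meshroom) consume,
plus the analytic camera-pose priors that make their SfM solve robust, and
the statistics used to quantify reconstruction accuracy and measurement
precision.

## What it does

- **Focus filtering** — scores each focal plane with the variance of a
  3×3 Laplacian response, Var[∇²I], and discards planes with no in-focus
  content.
- **Stack alignment** — registers every plane to the most distal one with an
  isotropic scale *s* plus translation (t_x, t_y), compensating the
  magnification change as the camera advances and the rail's XY jitter.
- **EDOF blending** — fuses the aligned stack into one Extended Depth Of
  Field image by winner-takes-all (hard-mask) selection of the plane with
  maximal local Laplacian-variance contrast per pixel; every output pixel is
  copied verbatim from exactly one plane.
- **Automatic masking** — a five-step routine (denoise + CLAHE → edge
  detection → largest-shape extraction → adaptive-threshold infill removal →
  connected-component cleaning) that separates the specimen from the dome
  background and exports binary masks and cut-outs.
- **Camera-pose priors** — for gimbal angles (x, y) and working distance r,
  the equivalent camera centre c = R_y(−y)·R_x(−x)·(0,0,r) and its look-at
  rotation, serialised as an AliceVision-dialect `.sfm` scene; EXIF metadata
  (focal length, 35 mm equivalent, sensor width, serial) is embedded in each
  image.
- **Metrology** — gauge-block step heights (mean vertical distance between
  two vertex regions), closed-mesh surface area and volume (divergence
  theorem), longest body axis.
- **Precision statistics** — coefficients of variation c_v = σ/µ and the
  Feltz–Miller asymptotic chi-square test for equality of CVs across k
  groups, D = Σ mᵢ(cᵢ−c)² / [c²(0.5+c²)] with mᵢ = nᵢ−1 and df = k−1.
- **Synthetic fixtures** — seeded generators for focal stacks with known
  all-in-focus truth, specimen images with ground-truth masks, gauge-block
  meshes and CV-controlled samples, so the whole pipeline is testable
  without scanner hardware.

## Worked example

```python
import scanforge as sf

# synthesise a 3-plane focal stack with known ground truth
spec = sf.FixtureSpec(seed=3, shape=(256, 256), n_planes=3, blur_scale=2.5)
stack, gt_sharp, gt_index, _ = sf.make_focal_stack(spec)

# the synthetic stack is aligned by construction; real stacks go through
# sf.align_stack(...) first
focused = sf.select_focused(stack, threshold=0.0)
edof, index_map = sf.blend_hard_mask(focused)

import numpy as np
mse = np.mean((edof.pixels.astype(float) - gt_sharp.astype(float))**2)
print(f"EDOF PSNR vs truth: {10*np.log10(255**2/mse):.1f} dB")

# measurement precision: femur length measured by 7 observers on the
# physical specimen (2D) vs on the 3D model
g2d = sf.GroupSummary(n=7, mean=6.25, sd=0.10, label="femur 2D")
g3d = sf.GroupSummary(n=7, mean=6.57, sd=0.07, label="femur 3D")
print(f"cv 2D = {sf.cv_rounded(g2d):.3f}, cv 3D = {sf.cv_rounded(g3d):.3f}")
res = sf.feltz_miller_test([g2d, g3d])
print(f"Feltz-Miller D = {res.statistic:.3f}, df = {res.df}, p = {res.p_value:.3f}")
```

prints

```
EDOF PSNR vs truth: 46.5 dB
cv 2D = 0.016, cv 3D = 0.011
Feltz-Miller D = 0.965, df = 1, p = 0.326
```

The PSNR says the blended image is nearly indistinguishable from the known
all-in-focus truth; the CVs say seven observers agree to ~1–2% on both
protocols, and the test finds no significant precision difference between
them for this measurement.

The command-line interface mirrors the library
(`scanforge synth|stack|mask|poses|measure|cvtest|run`, see `--help`).

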