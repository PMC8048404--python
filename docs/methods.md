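# Methods

This note documents the models behind each scanforge stage, the parameters
that matter, the synthetic data the package is validated on, and the design
choices made where several reasonable options existed.

## Focus scoring and filtering

Sharpness is measured as the population variance of the response of the 3×3
four-neighbour Laplacian kernel [[0,1,0],[1,−4,1],[0,1,0]]. Defocus acts as
a low-pass filter, so the variance decays monotonically with blur; a
constant image scores exactly zero. Convolution uses reflect padding, which
keeps the response the same size as the input and adds no artificial edge
energy at the borders. RGB inputs are reduced with the channel-average grey
projector so scores are consistent with the projector used for blending.

`select_focused` keeps planes scoring **≥** the threshold (ties retained)
and preserves stack order. The default threshold is 0.0 (keep everything):
the useful value depends on sensor noise, rail step size, aperture and
magnification, and must be tuned per camera — it belongs in configuration
presets, not in code.

## Stack alignment

Motion between focal planes is modelled as an isotropic scale about the
image centre plus a translation: `T(p) = s(p − c) + c + t`. The camera rail
only translates the camera along the optical axis, so rotation and shear are
excluded by design; magnification growth toward proximal planes produces
`s > 1`, rail imperfections produce small `t`.

The scale is estimated by a bounded golden-section search (bounds
0.93–1.08, tolerance 1e-4) minimising the phase-correlation error after the
candidate magnification is removed; the translation then comes from
phase correlation with 20× subpixel upsampling. A log-polar
magnitude-spectrum correlation was evaluated first and discarded: at the
near-unity magnification steps of a focal stack (≤ 1.04 between adjacent
planes) the radial log-polar shift is below one pixel and the estimate was
not reliable at the required 0.005 scale tolerance, whereas the direct
search recovers constructed scales to ~2e-4 and shifts to ~0.1 px. The
identity transform is kept whenever it correlates at least as well as the
search optimum, so stacks of identical images map to exact identities.

Because in-focus content overlaps only between neighbouring planes, each
plane is registered against its z-neighbour and the pairwise transforms are
composed through to the reference (the most distal plane, z = 0). The
centred scale+translation family is closed under composition
(`s = s₁s₂`, `t = s₂t₁ + t₂`), so chaining stays in-model. Resampling is
bilinear with edge replication for out-of-frame pixels; integer dtypes are
rounded and clipped back to their range.

Featureless (constant) images cannot be registered; they yield an identity
transform flagged with confidence score 0 rather than an error, so a
pipeline never aborts on a degenerate plane.

Registering planes that differ only in local blur (e.g. an already-aligned
synthetic stack) can return spurious sub-tolerance transforms, because
defocus itself changes the spectrum; the resulting resampling slightly
softens the blend. This is inherent to intensity-based registration of
focal stacks and is why recovery tolerances (0.005 scale / 0.5 px), not
exact identity, are the contract.

## EDOF blending

Per-pixel sharpness is the local variance of the Laplacian response within a
7 px window (computed via uniform filters of the response and its square).
For each pixel the plane with maximal local contrast wins and its value is
copied verbatim — a hard mask. Luminance and saturation never influence
selection. Ties break to the lowest z index (most distal plane), making the
result deterministic.

The raw argmax map is smoothed with a 5×5 majority filter to suppress
salt-and-pepper plane switching in low-texture regions; because pixels are
copied *after* smoothing, the hard-mask fidelity invariant (every output
pixel is bit-identical to its index-map source) holds unconditionally. The
window size is a tunable whose contract is the blend quality on fixtures
(PSNR ≥ 30 dB against the known all-in-focus truth; in practice ~46 dB on
the 3-plane fixture).

Two grey projectors are available for the contrast analysis: channel
average (default) and CIE 1976 L\* computed from linearised sRGB and
rescaled to the input range. L\* expands small contrast differences in
highlights and shadows and can reduce halos at plane seams, at extra cost.
Colour is always copied untouched from the winning plane.

## Automatic masking

Five deterministic steps:

1. **enhance** — grey projection, Gaussian blur (5×5 kernel; sigma from the
   OpenCV kernel→sigma rule), median blur (5×5), then CLAHE. CLAHE runs with
   tile size 64 px and clip limit 2.0 expressed in the OpenCV convention
   (mapped internally to scikit-image's normalised clip limit as clip/100).
   Constant images pass through unchanged, as histogram equalisation is
   undefined at zero dynamic range.
2. **detect_outline** — normalised Scharr gradient magnitude of the enhanced
   image (values in [0,1]). The alternative `forest` detector keeps the
   interface for an externally trained structured-forest edge model and
   raises an explicit configuration error when the model (or its inference
   backend) is unavailable — never a silent fallback. All shipped fixtures
   and defaults use the gradient path.
3. **largest_shape_mask** — binarise at `edge_threshold` (default 0.10),
   close with a radius-3 disk (bridges 1-px gaps in the thresholded
   outline), fill holes, keep the largest 8-connected component. An empty
   result is a warning, not an error.
4. **remove_infill** — inside the current foreground only, flip pixels
   brighter than their local mean (block 101 px) plus 5 grey levels back to
   background (`adaptive_offset = −5` on the 8-bit scale, following the
   threshold = mean − offset convention). This is luminance keying against
   the light dome background: it removes background enclosed between legs
   and body, and also trims the bright outer edge band left by step 3. It
   relies on the dome lighting being locally uniform, and it assumes the
   specimen is darker than the background; enclosed regions larger than the
   block size would survive. Background never flips to foreground here.
5. **clean_mask** — remove foreground components and fill background holes
   with area < `min_component_fraction` × (H·W) (default 1e-4, i.e. a
   resolution-dependent threshold; components exactly at the threshold are
   kept). The largest foreground component always survives. Foreground is
   8-connected, background 4-connected — the standard dual pair that avoids
   topological paradoxes. One pass of this step is idempotent on its own
   output.

Cut-outs apply the mask either as an alpha channel (RGBA, alpha = 255·mask)
or by zeroing background; foreground pixel values are never altered.

## Camera-pose priors

World frame: right-handed, +Y up (the gimbal's vertical axis), +Z from dome
centre toward the camera home position; the camera looks along its local −Z.
The specimen's gimbal rotation (x tilt, then y yaw — the X stage rides on
the Y stage) is inverted onto a virtual camera:
`c = R_y(−y)·R_x(−x)·(0,0,r)` with look-at rotation toward the origin,
up-reference world +Y (world +X within 1e-6 of the ±Y poles, unreachable
given the ~100° physical tilt range). All centres lie on the radius-r
sphere and every pose looks exactly at the origin; these invariants (1e-9
orthonormality/radius, 1e-7 rad look-at) are the correctness contract, since
the sign conventions of any particular downstream tool cannot be diffed
against. The `.sfm` output (AliceVision JSON dialect: views, one shared
intrinsics record, poses with 9 row-major rotation numbers and a 3-vector
centre) is written with sorted keys and fixed float formatting, so identical
scenes serialise byte-identically. Poses are rig-model priors for the SfM
solver, not metrically solved extrinsics.

EXIF tagging embeds Make, Model, BodySerialNumber, FocalLength and
FocalLengthIn35mmFormat in their standard tags. The physical sensor width
has no standard EXIF tag; it is stored losslessly as
FocalPlaneXResolution (an exact rational in pixels per centimetre) plus
FocalPlaneResolutionUnit, and reconstructed on read. The 35 mm-equivalent
focal length is user-supplied configuration, not derived from the sensor
width: vendor-quoted pairs need not match a pure width-ratio crop factor.
Re-encoding is lossless (PNG/TIFF); a pixel checksum helper verifies that
tagging never touches image data.

## Metrology

`step_height` is the difference of mean up-axis coordinates between two
box-selected vertex regions; box selection is used instead of plane fitting
so the manual vertex-group workflow is scriptable and testable. The reported
sd combines the two regions' up-coordinate standard deviations in
quadrature — the spread of a single top/reference vertex pair, not the
standard error of the mean. Surface area is the triangle-area sum; volume
is the magnitude of the signed-tetrahedron sum (divergence theorem) and is
refused with an explicit error for meshes that are not watertight with
consistent winding (the error still carries the area). The longest axis is
the maximum pairwise vertex distance, computed exactly below 500 vertices
and on convex-hull vertices above (the hull contains the farthest pair).

## CV statistics

`cv` and the Feltz–Miller asymptotic test operate on group summaries
(n, mean, sd) because measurement-precision tables print only summaries;
a wrapper computes summaries from raw samples. With mᵢ = nᵢ−1,
cᵢ = sdᵢ/meanᵢ and pooled c = Σmᵢcᵢ/Σmᵢ, the statistic
Σmᵢ(cᵢ−c)²/[c²(0.5+c²)] is chi-square with k−1 df under equality. The plain
asymptotic form is implemented and named as such in the output; no
small-sample correction or likelihood-ratio variant is provided. CVs are
reported at 3 decimals by convention. The test's Monte-Carlo size at
α = 0.05 (two normal groups, n = 50, 5,000 replicates) is ~0.05, checked in
the acceptance suite. A log-log OLS helper (slope with t-based confidence
interval) supports area–volume scaling analyses.

## Synthetic fixtures: what they do and do not show

- **Focal stacks** — a multi-scale random texture split into vertical bands,
  band j in focus on plane j, Gaussian-blurred with sigma linear in the
  depth offset elsewhere, optionally magnified/jittered with recorded
  ground-truth transforms, plus optional Gaussian pixel noise. The linear
  Gaussian defocus model is sufficient to exercise winner-takes-all
  selection and registration; it is not a physical thin-lens PSF, and the
  texture has no occlusion or specularity. Default geometry: 256×256 px,
  3–5 planes.
- **Specimen images** — a dark articulated body (two segments, head, six
  legs ~9 px wide) with one enclosed background hole, on a light-grey
  background (level 200) with mild radial vignetting and a 140-grey-level
  foreground/background separation; a zero separation is rejected as
  unusable. Passing masking tests on these shows the routine handles the
  intended geometry (thin appendages, enclosed background, vignetting,
  moderate noise) — not that it handles specular, iridescent or translucent
  specimens, which remain hard for the gradient detector.
- **Gauge blocks** — two 5×5 mm planar vertex grids at certified-style
  heights (1.50/1.10/1.05 vs 1.00 mm → 500/100/50 µm steps), with optional
  i.i.d. vertical vertex noise emulating reconstruction roughness. Real
  reconstructions add correlated, non-Gaussian surface error; recovering the
  step on these meshes validates the measurement protocol, not the scanner.
- **CV groups** — normal samples at specified means and CVs for size/power
  simulation.

All generators are pure functions of their spec (seed included); identical
specs give bit-identical output.

## Problem sizes and tolerances used in validation

Masking fixtures run at 512×512 px, blending and alignment at 256×256 px
with 2–5 planes, the pose grid at 6×20 = 120 views, the noisy gauge
protocol at 10⁴ vertices per plane over 100 seeds, and the test-size
simulation at 5,000 replicates of two n = 50 groups — sizes chosen so the
full validation completes in seconds while keeping Monte-Carlo error well
below the asserted margins. Geometric invariants are asserted at 1e-9
(orthonormality, sphere radius, serialisation round-trip), registration at
its 0.005/0.5 px recovery tolerances, and statistics at their simulation
margins (±0.01 on the 0.05 test size).

## Known limitations

- Intensity-based registration cannot distinguish defocus change from small
  magnification change perfectly; residuals stay within tolerance but are
  nonzero even for perfectly aligned inputs.
- The masking routine assumes a specimen darker than a locally uniform
  light background; bright or translucent specimens, strong shadows, or
  enclosed regions larger than the adaptive block defeat the keying step.
- The structured-forest edge detector is interface-only; no trained model
  ships with the package.
- Pose priors model an ideal gimbal (axes through the dome centre, exact
  angles); mechanical offsets are left to the downstream bundle adjustment.
- `.sfm` output follows the AliceVision JSON dialect as documented publicly;
  version drift in downstream software may require adjusting field names.
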