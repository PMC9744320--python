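# Methods

## Pipeline overview

`dtiglyph` implements a six-step glyph-rendering algorithm for diffusion
tensor fields, aimed at thin curved fiber structures (the optic nerve
and tract), plus the σ\* atrophy score built on its display threshold.

1. Every voxel is represented by a line segment along the principal
   eigenvector V₁ (sign-free; glyphs are drawn centered on the voxel, so
   V₁ and −V₁ are equivalent).
2. Segment length is α (L₁ − RD)²: quadratic emphasis of voxels where
   diffusion is strongly unidirectional.
3. Segment opacity is clip(β·MD·FA, 0, 1): strong, anisotropic diffusion
   is opaque.
4. Color is (clip(γ·L₁N, 0, 1), 1 − L₁N, 0) with L₁N = L₁/L₁max. Axial
   diffusivity is roughly constant along a healthy nerve, so the nerve
   renders in one hue regardless of its local direction — unlike the
   standard direction-encoded RGB, which fragments curved tracts into
   color segments.
5. A contiguous stack of slices is projected orthographically onto one
   anatomical plane (transverse drops the slice axis; sagittal drops x;
   coronal drops y). Superposition of ~7 layers makes a thin tract that
   wanders between slices appear as one continuous fiber.
6. A voxel is displayed only if L₁N > RDN + σ (strict). This removes the
   isotropic clutter that superposition would otherwise accumulate.

## Units and parameters

Diffusivities are carried in mm²/s throughout (healthy white-matter
MD ≈ 9×10⁻⁴). This is the only unit convention under which the default
β = 1000 s/mm² produces opacities inside [0, 1] for tissue-typical
values (1000 · 9×10⁻⁴ · 0.53 ≈ 0.48), so α and β absorb the units of
their factors. Report output prints MD ×10⁶ (so "900" means
9×10⁻⁴ mm²/s), the convention familiar from clinical tables.

| parameter | default | units | role |
|---|---|---|---|
| α | 250 | display units per (mm²/s)² | length gain |
| β | 1000 | s/mm² | opacity gain |
| γ | 1.2 | – | red-channel gain |
| σ | 0.2 | – | display threshold |
| layers | 7 | slices | projection depth |

α, β and γ are cosmetic: they provably change no display flag, and σ\*
is independent of them (verified by test). Only σ changes which voxels
appear.

Both L₁N and RDN are divided by the *same* L₁max. The alternative —
per-map maxima — would decouple the display condition from the physical
difference L₁ − RD and make σ\* incomparable across nerves; it is kept
as an explicit option (`normalize_maps(..., per_map=True)`) for
sensitivity checks only. L₁max is taken over the whole volume by
default; a mask option exists for data where fat or CSF artifacts
dominate the global maximum. The σ\* estimator requires the global
scope, and the machine-readable report records which scope was used.

## Tensor estimation

The fit solves ln Sᵢ = ln S₀ − bᵢ gᵢᵀ D gᵢ by ordinary least squares
over all volumes, after averaging the b≈0 volumes (b ≤ 50 s/mm² by
default) into a single baseline row. OLS is chosen as the default
because it inverts noiseless data exactly — the property the
round-trip tests rely on — and because the glyph algorithm is agnostic
to the fit flavor; a signal-weighted variant (`weighted=True`) is
available for low-SNR data. Voxels containing non-positive signals are
fitted on their strictly positive subset (logged), or zeroed when fewer
than 7 usable measurements remain. A gradient design whose condition
number exceeds 10⁸ (e.g. coplanar directions, or a single shell with no
baseline, where the intercept column is exactly collinear with the
diagonal columns) is rejected with the condition number in the message.

Eigendecomposition uses batched symmetric `eigh`; eigenvalues are
returned descending. Negative eigenvalues — non-physical, produced by
noise and signal dropout — are clamped to exactly 0 (idempotent,
order-preserving); the percentage of affected voxels per map, computed
*before* clamping, is the image-quality report. FA uses the standard
squared-eigenvalue denominator and is NaN (not 0) where all eigenvalues
vanish, so empty voxels cannot silently dilute ROI statistics;
downstream display logic excludes them explicitly.

## The σ\* score

σ\* = max(0, max over ROI of (L₁N − RDN)) is exactly the infimum of
thresholds at which the ROI contributes no displayed voxel, because the
displayed set at threshold σ is {L₁N − RDN > σ} and both quantities are
the maximum of the same finite set. Two readings of the estimator are
possible — the largest ROI difference (last voxel to vanish) or the
smallest (first voxel to vanish). The largest-difference form is the
score: it matches the removed-from-the-image semantics and yields 0 for
tissue with no axial-radial contrast. The minimum variant is available
via `mode="min"` for comparison. The floor at 0 makes fully isotropic
ROIs report 0 rather than a negative difference.

`atrophy_report` compares σ\* against a normative distribution over 21
non-atrophic optic nerves (mean 0.33, sd 0.03, min 0.27, max 0.39) via
a z-score, flagging scores below the normative minimum. The flag is
descriptive, not diagnostic.

## The phantom generator

Phantoms are curved tubes of axially symmetric tensors in isotropic
background, on a 1.3×1.3×2.0 mm grid (the clinical optic-nerve
protocol's voxel size), default 40×40×12. Tissue is specified by target
(FA, MD); the unique cylindrically symmetric triple is

L₁ = MD (1 + 2FA/√(3−2FA²)),  L₂ = L₃ = MD (1 − FA/√(3−2FA²)).

Presets:

- **healthy**: FA 0.53, MD 0.9×10⁻³ mm²/s — typical intact-nerve ROI
  values.
- **atrophic**: isotropic (FA 0), MD 2.81×10⁻³ mm²/s — tissue whose
  axonal structure has degenerated toward free water. The defining
  clinical observation for atrophic nerves is σ\* = 0: no voxel shows
  axial diffusivity exceeding radial. Any prolate per-voxel tensor
  would contradict that, so the generator models the *tissue* as
  isotropic. The moderate apparent FA (~0.4, with large spread)
  measured over such ROIs in vivo is the well-known upward bias of FA
  under noise at low SNR — a property of the measurement that the
  generator reproduces only through its noise model, not a property of
  the tissue. (Note that the elevated MD already makes the *absolute*
  difference L₁ − RD of a literal FA-0.4 tensor larger than the healthy
  profile's, which would invert the score; the isotropic reading is the
  only one consistent with the σ\* observation.)
- **background**: CSF-like isotropic MD 3.0×10⁻³ mm²/s. Because this
  exceeds every tissue L₁ in the healthy phantom, it sets the global
  L₁max, giving the closed-form anchor
  σ\*₍healthy₎ = (L₁f − RDf)/L₁max = 0.30548…, inside the normative
  range — the end-to-end correctness check used by the tests and the
  acceptance script.

Noise is applied on either of two paths: zero-mean Gaussian
perturbation of the eigenvalues (fast path; sd 2×10⁻⁴ mm²/s is the
"moderate" level used in the discrimination experiments, ~20% of
healthy MD), after which eigenvalues are re-sorted and clamped; or
Rician noise on the forward-modelled signal
S = S₀ exp(−b gᵀDg) (full path), built as the magnitude of a
complex Gaussian perturbation. Gradient schemes are deterministic
electrostatically-spread direction sets (Fibonacci-hemisphere
initialization relaxed under antipodal Coulomb repulsion); the default
acquisition is 64 directions at b = 1000 s/mm² plus 6 baselines. All
outputs are bit-reproducible from (spec, seed).

What the phantom does *not* emulate: susceptibility and eddy-current
distortion, fat/CSF partial volume, and the signal dropout at the bony
optic canal. One visible consequence: negative eigenvalues, which in
clinical data reach percent levels in L₂/L₃ and arise mostly from
dropout and correction artifacts, are essentially absent from a
uniform-brightness Rician phantom (the magnitude noise floor biases low
signals upward, pulling diffusivity estimates toward zero from above
rather than below). The QC accounting is therefore exercised against
constructed fields with known negative counts; passing phantom tests
shows the pipeline's arithmetic and threshold semantics are right, not
that real optic-nerve scans of a given quality will score any
particular QC fraction.

## Rendering choices

Voxel centers and directions are mapped to world mm through the affine
(directions by its rotation part only), so anisotropic voxels render
with true proportions. The radiological left-right flip is applied at
display time only. The on-screen length scale is not part of the model:
a device-scale factor converts length units to plot mm, by default
chosen so the 99th-percentile segment spans one in-plane voxel extent.
Draw order is lexicographic in voxel index and the SVG writer is
configured for byte-identical reruns, so overlapping translucent
segments composite reproducibly. Multi-layer glyph stacks can only be
paired with a single morphological background slice (the one nearest
the stack center); the depth mismatch is inherent to the projection.
The density diagnostic plots every voxel of the selected layers with no
subsampling.

## Problem sizes

Default test and acceptance runs use 40×40×12 grids (19 200 voxels,
~200-voxel fiber ROIs), 70-volume acquisitions, and 100 seeded noise
repetitions for the discrimination rate — sizes chosen so the full
suite exercises every path, including the complete
acquisition→fit→score loop, in well under a minute on one CPU while
keeping ROI statistics stable at the percent level.

## Known limitations

- Single-tensor model only: no multi-shell, kurtosis or crossing-fiber
  handling (a limitation shared with the visualization concept itself,
  which presumes one dominant direction per voxel).
- σ\* is a maximum statistic: under noise it is biased upward with ROI
  size, so scores should be compared across ROIs of similar size, and
  its absolute scale depends on L₁max (hence on what the field of view
  contains). The normative range shipped here was estimated on
  whole-head-normalized data.
- Masks and ROIs are user-supplied; no automatic nerve segmentation is
  attempted.
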