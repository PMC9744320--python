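# dtiglyph

Glyph-based visualization of the human optic nerve from diffusion tensor
imaging (DTI), and a quantitative score of optic-nerve atrophy derived
from the visualization threshold.

## The problem

The optic nerve is a thin (~3 mm), strongly curved white-matter tract
surrounded by fat, cerebrospinal fluid and bone. Diffusion MRI of this
region is low-resolution and artifact-prone, and streamline tractography
frequently fails to follow the nerve's anatomy. `dtiglyph` takes a
different route: it renders the diffusion tensor field directly, one
line-segment glyph per voxel, with visual codings chosen so that
strongly unidirectional diffusion — the signature of an intact nerve —
dominates the image without any segmentation or tracking.

## The model

Per voxel, the diffusion tensor D (mm²/s) has eigenvalues
L₁ ≥ L₂ ≥ L₃ and eigenvectors V₁, V₂, V₃. From these:

- FA = √( ((L₁−L₂)² + (L₂−L₃)² + (L₁−L₃)²) / (2 (L₁²+L₂²+L₃²)) )
- MD = (L₁+L₂+L₃)/3,  RD = (L₂+L₃)/2

Each voxel is drawn as a segment along V₁ with

- length  α (L₁ − RD)²,
- opacity clip(β · MD · FA, 0, 1),
- color   (clip(γ·L₁N, 0, 1), 1 − L₁N, 0) where L₁N = L₁ / L₁max,
- and it is displayed only if **L₁N > RDN + σ**,

with L₁N and RDN both normalized by the volume-wide maximum axial
diffusivity L₁max. A few contiguous slices are superposed by
orthographic projection onto a chosen anatomical plane. Defaults
α = 250, β = 1000, γ = 1.2, σ = 0.2, 7 layers.

The display threshold doubles as a measurement. For a nerve ROI,

σ\* = max(0, max over ROI of (L₁N − RDN))

is the threshold at which the nerve disappears from the image. Healthy
optic nerves cluster tightly around σ\* ≈ 0.33 (observed range
0.27–0.39 over 21 non-atrophic nerves), while an atrophied nerve whose
axons have degenerated toward free water scores σ\* ≈ 0 — it is
invisible at any threshold. σ\* is invariant to α, β, γ and to global
rescaling of the diffusivities.

## Worked example

Two synthetic fibers in one volume — a healthy profile (FA 0.53,
MD 0.9×10⁻³ mm²/s) and a free-water-like atrophic profile
(MD 2.81×10⁻³) — with seeded eigenvalue noise
(`examples/02_sigma_atrophy_score.py`):

```text
--- healthy nerve ROI (200 voxels) ---
sigma* = 0.4208
z-score vs normative (0.33 +/- 0.03): +3.03
ROI FA: 0.543 (0.119)
ROI MD [x1e-6 mm^2/s]: 892 (110)
sigma* within normative range
--- atrophic nerve ROI (204 voxels) ---
sigma* = 0.1807
z-score vs normative (0.33 +/- 0.03): -4.98
ROI FA: 0.066 (0.033)
ROI MD [x1e-6 mm^2/s]: 2800 (109)
FLAG: sigma* below normative minimum 0.27 (consistent with reduced
axial-radial contrast; descriptive only)
```

The healthy ROI keeps a large normalized axial−radial margin and
survives thresholds well past the default σ = 0.2; the atrophic ROI's
margin comes from noise alone and falls below the normative minimum.
The other examples show the full acquisition-to-image pipeline
(`01_phantom_to_glyphs.py`), negative-eigenvalue quality control
(`03_quality_control.py`) and the (RDN, L₁N) density diagnostic
(`04_density_diagnostic.py`).

## Command line

The same pipeline is available as an umbrella executable for on-disk
NIfTI + FSL-dialect `.bval`/`.bvec` data:

```bash
dtiglyph phantom ph --preset healthy --seed 1     # synthetic dataset
dtiglyph fit ph_dwi.nii.gz ph.bval ph.bvec maps   # tensors, scalars, QC
dtiglyph render maps glyphs.png --density d.png   # 7-layer projection
dtiglyph sigma maps ph_fiber_mask.nii.gz          # atrophy score
dtiglyph qc maps                                  # negative-eigenvalue QC
```

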