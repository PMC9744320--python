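"""Scoring nerve atrophy with the sigma threshold.

One volume holds two fibers: a healthy profile (FA 0.53, MD 0.9e-3) and a
free-water-like atrophic profile (isotropic, MD 2.81e-3), with seeded
eigenvalue noise.  sigma* is the display threshold at which a nerve ROI
vanishes from the image; a healthy nerve scores ~0.3 while atrophic
tissue scores ~0.
"""

import dtiglyph as dg

ef, roi_healthy, roi_atrophic = dg.make_discrimination_phantom(noise_sd=2e-4, seed=0)
sc = dg.compute_scalars(ef)
nm = dg.normalize_maps(ef, sc)  # global L1max: scores comparable across ROIs

for name, roi in [("healthy", roi_healthy), ("atrophic", roi_atrophic)]:
    result = dg.sigma_threshold(nm, roi, scalars=sc)
    report = dg.atrophy_report(result)
    print(f"--- {name} nerve ROI ({result.roi_size} voxels) ---")
    print(report.as_text())

print()
print("The z-score compares sigma* with the reference distribution over 21")
print("non-atrophic optic nerves (mean 0.33, sd 0.03, min 0.27); scores below")
print("0.27 are flagged as consistent with reduced axial-radial contrast.")
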