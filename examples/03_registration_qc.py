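"""Score tissue-warping artifacts and apply the 6 um exclusion rule.

A stained section can warp locally (folds, tears) relative to the
autofluorescence scan.  Each patch pair gets a translational alignment
score — the magnitude of the best-fitting translation in micrometres at
the 10x reference — and any region scoring strictly above 6 um is
excluded from training-patch sampling.
"""

import numpy as np

import afstain as a

phantom = a.make_phantom(a.PhantomConfig(
    width_px=96, height_px=96, pixel_size_um=1.0,  # 10x reference scale
    n_tumor=8, n_t_cell=6, n_cytotoxic=3, n_other=4,
    nucleus_radius_px=3.5, seed=3,
))
patch = a.render_he(phantom, a.RenderConfig(pixel_size_um=1.0, noise_sd=0.0))

print("shift (um)   score (um @10x)   decision")
for um in (0.0, 2.0, 4.0, 6.0, 6.5, 8.0):
    warped = a.apply_warp(patch, a.WarpSpec(translation_xy_px=(um, 0.0)), order=3)
    score = a.local_translation_score(patch, warped, metric="NGF",
                                      pixel_size_um=1.0)
    decision = a.qc_decision(score, threshold_um=6.0)
    verdict = "EXCLUDE" if decision.misaligned else "retain"
    print(f"{um:10.1f} {score.score_um_at_10x:15.1f}   {verdict}")
# The recovered score tracks the injected shift to within a few
# hundredths of a pixel; the decision flips strictly above 6 um, so a
# region displaced by exactly 6 um is still retained.
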