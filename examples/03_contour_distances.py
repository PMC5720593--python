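"""Build the curved embryo contour and assign margin distances.

Centroids from all slices are projected onto one plane; the convex hull
gives the embryo outline and its margin corners; a minimal-cost path
along the ridge of the distance transform of the nucleated tissue band
traces the contour; each nucleus is projected onto the smoothed contour
and its margin distance is the arc length to the closer end.
"""
import numpy as np
from scipy.stats import spearmanr

import smadgrad as sg
from smadgrad.config import RunConfig
from smadgrad.pipeline import process_stack

stack, truth, meta = sg.simulate_embryo(seed=1)
cfg = RunConfig(analysis={"normalization": "nuclear_ratio"})
annotated, central, cres, fit = process_stack(
    stack, cfg, center_slice=meta["mid_slice"],
    nuclear_brightness=meta["nuclear_brightness"])

L = cres.contour.total_length_um
print(f"contour length L = {L:.0f} µm "
      f"(true mid-shell arc is ~{np.pi * 280:.0f} µm)")
print(f"margin endpoints at {np.round(cres.endpoints.left_um, 1)} and "
      f"{np.round(cres.endpoints.right_um, 1)} µm (stack frame)")
paired = sg.distance_fidelity(annotated, truth, stack.n_slices,
                              stack.z_spacing_um, stack.pixel_size_um,
                              4.0, 25)
err = np.abs(paired.assigned_um - paired.d_true_um)
rho = spearmanr(paired.assigned_um, paired.d_true_um).statistic
print(f"matched nuclei: {len(paired)}; median |assigned - true| = "
      f"{np.median(err):.1f} µm ({100 * np.median(err) / L:.1f}% of L); "
      f"Spearman rho = {rho:.3f}")
# A median error of a few % of L and rho ~ 1 mean the 1D margin-distance
# coordinate faithfully orders nuclei along the tissue.
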