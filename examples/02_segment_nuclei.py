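"""Segment nuclei per z-slice and check detections against simulator truth.

Each z-slice of the nuclear-stain channel is background-corrected by
subtracting the Gaussian-blurred adjacent slices, adaptively thresholded,
size-filtered, and measured: one record per nucleus cross-section with
its centroid and the mean raw intensity of both channels.
"""
import smadgrad as sg

stack, truth, meta = sg.simulate_embryo(seed=1)
records = sg.segment_stack(stack)

score = sg.detection_score(records, truth, stack.n_slices, stack.z_spacing_um,
                           stack.pixel_size_um, nucleus_radius_um=4.0,
                           min_area_px=25)
print(f"records (nucleus cross-sections): {len(records)} across "
      f"{stack.n_slices} slices")
print(f"detection vs truth (Hungarian match, 2 µm radius): "
      f"F1={score.f1:.3f}  precision={score.precision:.3f}  "
      f"recall={score.recall:.3f}")
r = records[0]
print(f"example record: slice {r.z_index}, centroid "
      f"({r.centroid_x_um:.1f}, {r.centroid_y_um:.1f}) µm, area {r.area_px} px, "
      f"nuclear mean {r.mean_nuclear_intensity:.1f}, "
      f"pSmad2 mean {r.mean_psmad2_intensity:.1f} a.u.")
# F1 near 1 means essentially every nucleus cross-section large enough to
# pass the size filter is found once, with no spurious objects.
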