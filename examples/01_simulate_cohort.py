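"""Generate a synthetic multi-center developmental CT dataset.

Builds a paper-like cohort (two diagnostic groups, four acquisition centers,
ages 6-30), generates per-ROI cortical thickness with planted group contrasts
in the first 20% of ROIs, and attaches ADOS subscores to the ASD group.
"""

import ctshapes as cs

spec = cs.make_spec("paper-like", n_rois=40, centers=4)
cohort = cs.generate_cohort(n_asd=300, n_td=300, centers=[150] * 4, seed=1)
ct = cs.generate_ct(cohort, spec, seed=2)
cohort = cs.generate_ados(cohort, spec, seed=3)

print(f"cohort: {len(cohort)} subjects "
      f"({(cohort.group == 'ASD').sum()} ASD / {(cohort.group == 'TD').sum()} TD), "
      f"{cohort.center.nunique()} centers, ages "
      f"{cohort.age.min():.1f}-{cohort.age.max():.1f} yr")
print(f"CT table: {ct.shape[0]} subjects x {ct.shape[1]} ROIs, "
      f"values {ct.values.min():.2f}-{ct.values.max():.2f} mm")
asd = cohort[cohort.group == "ASD"]
print(f"ADOS (ASD only): comm mean {asd.ados_comm.mean():.2f}, "
      f"social {asd.ados_social.mean():.2f}, stereo {asd.ados_stereo.mean():.2f}")
print("Planted contrast ROIs:", [spec.roi_names[i] for i in spec.contrast_rois])
# The planted ROIs carry a less-negative ASD slope and a negative ASD
# curvature; everything downstream tries to recover exactly this structure.
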