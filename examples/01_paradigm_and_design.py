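"""Build the block-design task schedule and its HRF-convolved design matrix.

The task alternates 6 food and 6 neutral blocks (6 pictures x 4 s each)
separated by 8-12 s rest intervals; the design matrix convolves a 25-s block
model with the canonical double-gamma HRF sampled at TR = 2.5 s.
"""

import numpy as np

from cuedyn import build_design_matrix, build_schedule, canonical_hrf

schedule = build_schedule(seed=0)
print(f"{schedule.n_blocks} blocks, {schedule.n_stimuli} stimuli, "
      f"run {schedule.run_duration_s:.1f} s = {schedule.n_scans} scans at TR {schedule.tr_s} s")
for b in schedule.blocks[:4]:
    print(f"  {b.condition:<8} onset {b.onset_s:6.1f} s  duration {b.duration_s:.0f} s")
print("  ...")

kernel = canonical_hrf(0.1)
print(f"HRF peaks at t = {kernel.times[np.argmax(kernel.values)]:.1f} s (peak-normalised)")

design = build_design_matrix(schedule, kernel, motion=np.zeros((schedule.n_scans, 6)))
print(f"design matrix: {design.n_scans} scans x {len(design.columns)} columns")
print("columns:", ", ".join(design.columns))
# The condition regressors carry the expected sustained block responses; their
# scan-wise values are what each window GLM regresses the ROI signal on.
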