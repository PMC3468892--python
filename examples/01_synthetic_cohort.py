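"""Generate a synthetic stop-signal cohort and inspect its ground truth.

Builds a small 4-subject cohort (each subject: 2 runs of 60 volumes at
TR 2 s on a 20x20x12 grid), then prints what the generator planted: the
brain-mask size, the number of truth-positive voxels for the successful
stop vs go contrast, and the empirical noise level of a non-active voxel.
"""

import numpy as np

from fmriverse import desk_spec, generate_cohort

spec = desk_spec(
    n_subjects=4, n_runs=2, n_volumes_per_run=60,
    trial_counts={"go": 12, "stop_success": 4, "stop_fail": 4}, seed=42,
)
cohort = generate_cohort(spec)

tp = cohort.truth_positive()
print(f"subjects: {cohort.n_subjects}, runs/subject: {spec.n_runs}, "
      f"volumes/run: {spec.n_volumes_per_run}")
print(f"in-mask voxels: {int(cohort.mask.sum())}")
print(f"truth-positive voxels (stop_success > go): {int(tp.sum())}")

subj = cohort.subjects[0]
quiet = cohort.mask & ~sum((cohort.group_truth[c] > 0) for c in cohort.group_truth).astype(bool)
series = subj.runs[0][quiet][0]
print(f"example null-voxel time-series: mean {series.mean():.1f}, SD {series.std():.2f} "
      f"(spec: baseline {spec.baseline}, noise SD {spec.noise_sd})")
# The SD of a null voxel exceeds the pure-noise SD slightly because slow
# cosine drift is part of the simulated signal.
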