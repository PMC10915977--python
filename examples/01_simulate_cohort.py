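"""Simulate a small synthetic resting-EEG cohort and inspect its ground truth.

The generator produces a semi-Markov microstate sequence per subject
(geometric dwell times, mean 80 ms), renders it through five orthogonal
scalp templates with a slow amplitude envelope, per-segment polarity flips
and white sensor noise, and tags each subject with its group.
"""

import numpy as np

import microstates as ms

spec = ms.SyntheticCohortSpec(
    n_per_group={"control": 3, "poor_prognosis": 3},
    duration_s=20.0,
    seed=42,
    class_weights={"poor_prognosis": (1.0, 1.0, 1.0, 1.0, 1.5)},
)
cohort = ms.simulate_cohort(spec)

print(f"simulated {len(cohort.recordings)} subjects, "
      f"{spec.n_frames} frames each at {spec.fs:g} Hz")
print(f"templates: {', '.join(cohort.truth.templates.labels)}")
print()
print("subject            group            true class-E coverage")
for rec in cohort.recordings:
    truth = cohort.truth.subjects[rec.subject_id]
    cov_e = float(np.mean(truth.labels == 4))
    print(f"{rec.subject_id:<18} {rec.group:<16} {cov_e:.3f}")
print()
print("In expectation class E occupies 20% of frames in controls and ~25% in")
print("the boosted group (onset weight 1.5x); at 20 s per subject the")
print("per-subject values scatter around those levels.  This coverage shift")
print("is the group effect the statistics stages are expected to detect.")
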