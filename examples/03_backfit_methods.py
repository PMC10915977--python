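"""Label one subject's EEG with each of the three backfitting schemes.

* conventional: the subject's frames against their own group's templates;
* individual:   cluster the subject first, then translate the subject's own
                classes into reference class names by template matching;
* optimized:    assign raw frames directly to the reference templates, so
                every reference class is available to every subject.

On synthetic data with known truth we can also score frame-label accuracy.
"""

import numpy as np

import microstates as ms

spec = ms.SyntheticCohortSpec(n_per_group={"hc": 1}, duration_s=30.0, seed=12)
cohort = ms.simulate_cohort(spec)
rec = cohort.recordings[0]
reference = cohort.truth.templates  # stands in for the healthy-control set
truth = cohort.truth.subjects[rec.subject_id].labels

conventional = ms.backfit_conventional([rec], reference)[0]
individual = ms.backfit_individual(rec, reference, k_individual=5)
optimized = ms.backfit_optimized(rec, reference)

print("method        accuracy  mean dur (ms)  occurrence (1/s)  total GEV")
for seq in (conventional, individual, optimized):
    accuracy = float(np.mean(seq.labels == truth))
    temporal = ms.duration_occurrence(seq)
    gev = ms.gev_per_class(rec, seq, reference)
    print(
        f"{seq.method:<13} {accuracy:>7.3f}  {temporal.grand_mean_duration_ms:>12.1f}"
        f"  {temporal.grand_mean_occurrence_per_s:>15.2f}  {gev.total_gev:>9.3f}"
    )

print()
print("With the reference equal to the generating templates all three methods")
print("agree with the truth almost everywhere; the mean dwell time is the")
print("simulated 80 ms up to smoothing of sub-8 ms segments, and the total")
print("GEV below 1 reflects the injected sensor noise.")
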