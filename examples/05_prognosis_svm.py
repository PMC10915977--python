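"""Prognosis classification from microstate features.

Runs the full harness — backfit to reference templates, per-subject feature
extraction, standardized stratified-CV SVM — for each of the three feature
sets (class-E GEV alone, per-class durations + occurrences, both), reporting
pooled out-of-fold AUC, sensitivity and specificity.
"""

import microstates as ms
from microstates.evaluate import SvmConfig

spec = ms.SyntheticCohortSpec(
    n_per_group={"good_prognosis": 10, "poor_prognosis": 10},
    duration_s=30.0,
    seed=33,
    class_weights={"poor_prognosis": (1.0, 1.0, 1.0, 1.0, 1.5)},
)
cohort = ms.simulate_cohort(spec)
reference = cohort.truth.templates

print("feature set           AUC   sensitivity  specificity  accuracy")
for features in ("gevE", "duration_occurrence", "combined"):
    result = ms.prognosis_pipeline(
        cohort.recordings, reference, features,
        positive_group="poor_prognosis", config=SvmConfig(folds=5, seed=0),
    )
    print(
        f"{features:<20} {result.auc:>5.3f}  {result.sensitivity:>11.3f}"
        f"  {result.specificity:>11.3f}  {result.accuracy:>8.3f}"
    )

print()
print("The boosted onset weight raises both the class-E GEV and the class-E")
print("occurrence rate, so every feature set carries signal here; on real")
print("cohorts the sets can rank very differently, which is exactly what")
print("this harness is for.")
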