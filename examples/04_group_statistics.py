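"""Detect a between-group difference in class-E explained variance.

Backfits every subject against one shared (healthy-control) template set —
the point of the optimized scheme — computes per-class GEV, and compares the
groups with the appropriate test (normality-gated, Bonferroni-adjusted).
"""

import numpy as np

import microstates as ms

spec = ms.SyntheticCohortSpec(
    n_per_group={"control": 8, "poor_prognosis": 8},
    duration_s=30.0,
    seed=21,
    class_weights={"poor_prognosis": (1.0, 1.0, 1.0, 1.0, 1.5)},
)
cohort = ms.simulate_cohort(spec)
reference = cohort.truth.templates

gev_e, groups = [], []
for rec in cohort.recordings:
    seq = ms.backfit_optimized(rec, reference)
    stats = ms.gev_per_class(rec, seq, reference)
    gev_e.append(stats.per_class["E"].gev)
    groups.append(rec.group)

gev_e = np.asarray(gev_e)
groups = np.asarray(groups)
for g in ("control", "poor_prognosis"):
    vals = gev_e[groups == g]
    print(f"{g:<16} gev_E = {vals.mean():.4f} +- {vals.std(ddof=1):.4f}")

result = ms.compare_groups(gev_e, groups, variable="gev_E")
print(f"\n{result.test}: statistic={result.statistic:.3f}, p={result.p_value:.2e}")
for a, b, p_raw, p_adj in result.pairwise:
    print(f"  {a} vs {b}: adjusted p = {p_adj:.2e}")
print("\nThe boosted group spends more time in class E, so its class-E GEV is")
print("higher; a small adjusted p confirms the simulated effect is detected.")
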