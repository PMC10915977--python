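# eeg-microstates-toolkit

A tested Python library + CLI for EEG **microstate** analysis: extracting
template scalp maps from resting EEG, backfitting recordings to templates —
including the *optimized topographic analysis*, which assigns every frame of
every subject directly to one shared healthy-control template set — and
computing the per-class statistics (GEV, duration, occurrence, coverage) that
are compared across clinical groups and fed into prognosis classifiers.

## Who this is for

Resting EEG decomposes into sequences of quasi-stable scalp topographies
("microstates", canonical classes A–E) lasting roughly 60–120 ms.  Their
temporal statistics are sensitive markers in disorders of consciousness and
other conditions, but conventional analysis backfits each group to its *own*
template maps, which makes topographic quantities incomparable across groups.
Backfitting everyone to the *healthy-control* templates fixes that: the
explained variance of each canonical class becomes a subject-level feature
that can be tested between groups and used for prognosis prediction.  This
package implements that workflow end to end, and ships a synthetic-cohort
generator with known ground truth so that every stage is verifiable without
clinical recordings.

## The model

- **GFP** — global field power, the spatial standard deviation of the scalp
  field at frame *t*: `GFP(t) = sqrt((1/N) Σ_i (v_i(t) − v̄(t))²)`.
  Template maps are estimated only from GFP peaks.
- **AAHC** — atomize-and-agglomerate hierarchical clustering: every peak map
  starts as its own cluster; each iteration dissolves the cluster
  contributing least GFP²-weighted explained variance and reassigns its
  members by maximum `|Pearson r|`; stop at *k* (default 5).
- **Backfitting** — each frame gets the template with the largest absolute
  spatial correlation (polarity-invariant, the resting-state convention);
  segments shorter than 8 ms are absorbed by their neighbours.
- **GEV** — per class *k*:
  `GEV_k = Σ_{t: L(t)=k} GFP(t)²·r(t)² / Σ_t GFP(t)²`,
  with split microstates (two maps matching one canonical class, e.g.
  E1/E2 → E) merged by summing numerators.
- **Duration / occurrence / coverage** — mean run length of a class, its run
  onsets per second, its fraction of frames.
- **Evaluation** — rank-based (Mann–Whitney) AUC with midrank ties, and a
  stratified-CV SVM over microstate features with train-fold-only
  standardization.

## Worked example

```python
import microstates as ms

spec = ms.SyntheticCohortSpec(
    n_per_group={"control": 8, "poor_prognosis": 8},
    duration_s=30.0, seed=21,
    class_weights={"poor_prognosis": (1.0, 1.0, 1.0, 1.0, 1.5)},
)
cohort = ms.simulate_cohort(spec)
reference = cohort.truth.templates          # healthy-control templates

gev_e, groups = [], []
for rec in cohort.recordings:
    seq = ms.backfit_optimized(rec, reference)
    gev_e.append(ms.gev_per_class(rec, seq, reference).per_class["E"].gev)
    groups.append(rec.group)
print(ms.compare_groups(gev_e, groups, variable="gev_E"))
```

Running `python examples/04_group_statistics.py` (the same computation)
prints:

```
control          gev_E = 0.1253 +- 0.0239
poor_prognosis   gev_E = 0.1671 +- 0.0204

t_test: statistic=-3.761, p=2.11e-03
  control vs poor_prognosis: adjusted p = 2.11e-03
```

The boosted group spends ~25% of its time in class E instead of 20%, so the
class-E explained variance rises from 0.125 to 0.167 and the group
difference is detected at an adjusted p ≈ 0.002.  The other examples cover
simulation (`01`), template extraction and the k-reliability diagnostic
(`02`), the three backfitting schemes (`03`) and the SVM prognosis harness
(`05`).

The CLI wraps the same functions:

```bash
microstates run --config config.ini --out results/   # all stages
microstates simulate|cluster|backfit|stats|compare|evaluate --help
```

## Layout

```
src/microstates/      io, topography, clustering, backfit, stats,
                      simulate, evaluate, reference, pipeline, cli
examples/             one narrative script per capability
tests/                unit + property + end-to-end validation suite
docs/methods.md       modelling assumptions, conventions, limitations
```
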