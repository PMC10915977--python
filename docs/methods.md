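# Methods

This note records the modelling choices, conventions and limitations behind
the toolkit, in the order the pipeline uses them.

## Signal model and conventions

A recording is a channels × frames matrix in microvolts with a stated
sampling rate.  All topographic quantities are defined on average-referenced
data; `average_reference` is applied internally wherever it matters, and is
idempotent.  Frames are 0-based; the time of frame *t* is *t/fs* seconds;
segments are half-open frame intervals `[start, end)`.  Channel identity is
always by name (case-insensitive, whitespace-stripped), never by position —
template sets and patient files may order their montages differently, and a
silent positional mismatch would corrupt every spatial correlation
downstream.

Global field power uses the population formula (divide by the number of
channels).  The literature is split between the population and sample
conventions; the choice only rescales GFP by a constant and cancels in GEV,
but fixing it makes tests bit-exact.

GFP peaks are strict local maxima (greater than both neighbours).  Plateau
samples and endpoints are never peaks — a deterministic, testable rule.  An
optional minimum peak distance thins close peaks, keeping the larger; the
default (1) keeps all strict maxima since there is no principled spacing
rule at rest.

Spatial similarity is the Pearson correlation across channels.  Polarity
invariance (absolute correlation) is the default everywhere: resting-state
topographies flip sign with the underlying oscillation, so a map and its
negation are the same microstate.  A flag exposes the polarity-sensitive
mode.

## Template extraction (AAHC)

Atomize-and-agglomerate hierarchical clustering starts from every GFP-peak
map as a singleton cluster and removes one cluster per iteration: the
cluster with the smallest contribution to explained variance — the sum over
members of squared polarity-invariant correlation to the centroid, weighted
by each member's squared GFP — is dissolved, and its members are reassigned
to the surviving cluster they correlate with most in absolute value.
Centroids are polarity-aligned normalized means: member signs are flipped to
correlate positively with the current centroid, the mean is renormalized,
and the flip/mean step iterates to a fixed point (tolerance 1e−8, cap 100
iterations; in practice it converges in a handful).  The procedure has no
randomness; all ties break toward the lower index.

GFP² weighting applies when the inputs are raw peak maps (subject-level
clustering).  Pooled template maps carry no meaningful GFP, so the
group-level re-clustering in `aggregate_group_templates` is unweighted.
Group templates use the two-level route — cluster each subject, pool the
subject templates, re-cluster — rather than pooling all peaks, matching the
individual-then-group wording of the workflow this implements; both routes
are exposed.

Cluster order is arbitrary.  Output maps are sorted by descending explained
variance and given neutral labels (`M1..Mk`); canonical names A–E are
assigned only by matching against a reference set.  `select_k` reports
split-half map reliability (mean |r| between greedily matched centroids of
random half-splits) and explained variance over a k range; the pipeline
default stays k = 5 regardless, the value used throughout.

## Backfitting

`assign_frames` labels every frame with the argmax-|r| template; ties go to
the lower index; a frame with zero spatial variance has correlation 0 to
everything and falls to the tie rule.  By default every frame is labelled —
an optional correlation floor produces unassigned frames, which remain in
GEV denominators and total time.

Temporal smoothing removes segments shorter than a threshold, default 8 ms
(2 frames at 250 Hz, `round(0.008·fs)` otherwise).  The default policy
splits each short run at its midpoint between its two neighbours (a run at a
sequence boundary is absorbed whole by its single neighbour) and repeats
until no short labelled run remains; a `drop` policy marks short runs
unassigned instead.  The source descriptions of short-segment handling are
ambiguous between relabelling and discarding, which is why both policies
exist; split-to-neighbours is the default as the behaviour consistent with
segment-rejection practice in the Cartool lineage.  Smoothing is applied
uniformly to all three methods for comparability (configurable off).
Correlations stored per frame are the assignment-time values and are kept
unchanged by smoothing, as a historical record.

The three schemes:

* **conventional** — frames against the subject's own group templates;
* **individual** — GFP peaks → subject-level AAHC → frames against the
  subject's own templates → each own template matched to its best reference
  class (many-to-one allowed) → labels translated into reference classes,
  merging where needed.  Frame assignment keeps the subject's own templates
  (the matching only renames); re-fitting against the reference after
  renaming would be the optimized method;
* **optimized** — frames directly against the reference templates, so all
  reference classes are available to every subject and per-class statistics
  are comparable across groups.

## Statistics

GEV of class *k* is `Σ_{t:L(t)=k} GFP(t)²·r(t)² / Σ_t GFP(t)²` with r(t)
recomputed against the template of the assigned class, the squared-
correlation weighting being the standard definition.  The denominator spans
all frames, labelled or not, so GEV stays "fraction of total signal
variance explained" and the per-class values sum exactly to the total.
Split microstates are merged by summing numerators before reporting, which
makes merging exact (merge-then-compute equals compute-then-sum).

Duration, occurrence and coverage follow the EEGLAB-style run conventions:
duration is the mean contiguous run length of a class (reported in ms),
occurrence its number of run onsets per second of total recording time,
coverage its fraction of frames.  Runs touching the sequence boundary are
included by default; a flag excludes them, and with exclusion on the
identity `occurrence × duration(s) = coverage` holds exactly per class —
convention sensitivity around boundary runs is a known source of
discrepancies between toolboxes (e.g. duration × occurrence failing to sum
to 1), which is why the flag is explicit.  Occurrence divides by total
recording time rather than labelled time so that the identity survives
unassigned frames.  Grand means are unweighted over classes present.

`compare_groups` gates on Kolmogorov–Smirnov normality at α = 0.05 (z-scored
per group): ANOVA (>2 groups) or t-test (2 groups) when all groups pass,
Kruskal–Wallis otherwise; chi-squared handles categorical variables.
Pairwise p-values are Bonferroni-adjusted by the number of pairs.  Groups of
identical values return statistic 0, p 1 rather than the 0/0 form.

## Synthetic cohorts

The generator emulates the accepted picture of resting EEG as alternating
quasi-stable topographies.  Ground-truth labels follow a semi-Markov chain:
the next class is drawn proportionally to per-group onset weights excluding
the current class, and run lengths are geometric with mean dwell 80 ms
(minimum one frame) — inside the 60–120 ms range typical of microstates,
chosen geometric for analytic tractability of expected durations.  The
default conditions are a 19-channel 10–20 montage at 250 Hz, 60 s per
subject, k = 5 classes, a slowly modulated amplitude envelope with mean
15 µV against 3 µV white sensor noise (SNR 5), and per-segment polarity
flips with probability 0.5 so that polarity-invariant code paths are always
exercised.  Group effects are expressed through the onset weights (the
standard effect in the tests boosts class E by 1.5× in a "poor prognosis"
group, shifting its expected coverage from 0.20 to ≈ 0.25).

Generator templates are random rotations of low-order spatial polynomials
over the electrode layout, centered and orthonormalized, so pairwise
spatial correlation is exactly 0.  Everything is deterministic per (spec,
seed), with subject seeds spawned from the cohort seed.

What the generator does *not* emulate: 1/f spectral structure, spatially
correlated noise, artifacts (blinks, EMG), volume-conduction forward
physics, or non-geometric dwell distributions (a gamma option is the obvious
extension).  Passing tests therefore demonstrate the correctness of the
algorithms under the stated model, not robustness to real-world recording
pathology; preprocessing (filtering, artifact rejection) is assumed to
happen upstream of this toolkit.

The shipped canonical A–E reference set is a synthetic stylized
construction (diagonal gradients for A/B, an anterior–posterior gradient
for C, fronto-central and frontal Gaussian bumps for D/E) on the 19-channel
montage.  It exists to give template matching and merged-class bookkeeping a
stable, documented target; it is not an empirical grand-average.

## Evaluation harness

AUC uses the rank (Mann–Whitney) formulation with midrank ties, equal by
construction to the all-pairs concordance probability; ROC curve points come
from every distinct threshold, with the Youden point reported alongside.
The SVM harness defaults to an RBF kernel, C = 1, scikit-learn's "scale"
gamma and stratified 5-fold CV with a fixed seed — honest defaults, all
configurable, since no reference hyperparameters are available.
Standardization statistics are computed on training folds only (asserted by
test), sensitivity/specificity/accuracy come from pooled out-of-fold hard
predictions at the classifier's own decision threshold, and AUC from pooled
out-of-fold decision scores.  Clinical discrimination figures reported for
real cohorts depend on those cohorts and are not reproduction targets; the
harness reproduces the computation on synthetic data.

## File formats and numerics

The matrix text format is fixed (tab delimiter, `.` decimal, one frame per
row, channel-name header) and written with full-precision `repr`, so round
trips are bit-exact.  Template sets, label sequences, statistics tables and
manifests are TSV with JSON sidecars and also round-trip losslessly; no
data file contains timestamps, so reruns are byte-identical.  EDF files are
written with a built-in minimal writer (16-bit samples, physical range
±1000 µV ⇒ quantisation step ≈ 0.031 µV) and read back through mne, which
doubles as an independent check of the writer; BrainVision is read-only.
Template sets keep already-normalized maps bitwise unchanged on load
(re-normalizing only when needed) so that serialization is exactly
idempotent.

## Problem sizes used in validation

The validation battery runs on sizes chosen to exercise every code path at
meaningful statistical power: oracle agreement on 50–100 random recordings
of 19 × 1000 frames; parameter recovery on 10 subjects × 60 s; group-effect
detection on 15 + 15 subjects × 60 s with the 1.5× class-E boost; the null
cohort on 15 + 15 × 30 s; AAHC recovery on 200 noisy ±template draws.  The
full suite and the acceptance script each complete in a few minutes on one
CPU.

## Known limitations

* Modified k-means and other segmentation families are out of scope; only
  AAHC is implemented.
* No transition-probability/syntax or entropy measures.
* No source localization.
* The individual method's GEV is computed against the subject's own
  templates then merged into reference classes; alternative conventions
  (re-fitting after relabelling) would give slightly different numbers.
* EDF writing targets the ±1000 µV range; recordings exceeding it must be
  rescaled by the caller.
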