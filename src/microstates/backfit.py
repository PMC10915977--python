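"""Backfitting: turning a recording plus a template set into a per-frame
microstate label sequence.

Three schemes are provided:

* **conventional** — each group's recordings are labelled with that group's
  own aggregate templates;
* **individual** — each subject is clustered on their own GFP peaks, the
  subject's templates are matched to a reference set by maximum absolute
  spatial correlation, and the subject's label sequence is re-expressed in
  reference class names (several individual templates may merge into one
  reference class, and reference classes may be absent);
* **optimized** — every subject's raw frames are assigned directly to the
  reference (healthy-control) templates, so all reference classes are
  available to every subject and per-class statistics are comparable across
  groups.

Assignment is polarity-invariant by default: frame ``t`` gets the template
with the largest ``|Pearson r|`` across channels.  Temporal smoothing removes
implausibly short segments; the default threshold is 2 frames at 250 Hz
(8 ms), rescaled as ``round(0.008 * fs)`` for other rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .clustering import TemplateSet, TemplateMapping, aahc_cluster, match_templates
from .errors import ConfigurationError
from .io import Recording, align_channels
from .topography import (
    TopographicMap,
    average_reference,
    detect_gfp_peaks,
    global_field_power,
)

__all__ = [
    "LabelSequence",
    "UNASSIGNED",
    "default_min_frames",
    "assign_frames",
    "smooth_labels",
    "backfit_conventional",
    "backfit_individual",
    "backfit_optimized",
]

UNASSIGNED = -1


@dataclass
class LabelSequence:
    """Per-frame microstate labels with the winning assignment correlation.

    ``labels[t]`` indexes ``class_names`` (−1 marks an unassigned frame);
    ``corr[t]`` is the absolute spatial correlation to the winning template at
    assignment time (smoothing relabels frames but keeps correlations as
    historical record).
    """

    labels: np.ndarray
    corr: np.ndarray
    fs: float
    method: str  # conventional | individual | optimized
    class_names: tuple[str, ...]
    template_provenance: dict | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.labels.shape != self.corr.shape or self.labels.ndim != 1:
            raise ValueError("labels and corr must be 1-D and equal length")
        k = len(self.class_names)
        if np.any((self.labels < UNASSIGNED) | (self.labels >= k)):
            raise ValueError("labels must lie in {-1, 0..k-1}")

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def runs(self) -> list[tuple[int, int, int]]:
        """Maximal constant-label runs as (start, end, label), end exclusive."""
        return _runs_of(self.labels)


def default_min_frames(fs: float) -> int:
    """Short-segment threshold: 8 ms expressed in frames (2 at 250 Hz)."""
    return max(1, round(0.008 * fs))


def assign_frames(
    rec: Recording,
    templates: TemplateSet,
    polarity_invariant: bool = True,
    min_corr: float | None = None,
    method: str = "optimized",
) -> LabelSequence:
    """Label every frame with its argmax-|r| template.

    Ties go to the lower template index.  With ``min_corr`` set, frames whose
    best correlation falls below it become unassigned; by default every frame
    is labelled.  Frames with zero spatial variance (flat maps, which carry no
    topography) get correlation 0 and fall to the tie rule or below any
    ``min_corr``.
    """
    rec = average_reference(align_channels(rec, templates.montage))
    frames = rec.data.T  # frames × channels, already zero-mean per frame
    norms = np.linalg.norm(frames, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    corr = (frames @ templates.matrix) / safe[:, None]
    corr[norms == 0] = 0.0
    if polarity_invariant:
        corr = np.abs(corr)
    labels = np.argmax(corr, axis=1)
    win = corr[np.arange(len(labels)), labels]
    if not polarity_invariant:
        win = np.abs(win)
    if min_corr is not None:
        labels = np.where(win >= min_corr, labels, UNASSIGNED)
    return LabelSequence(
        labels=labels,
        corr=win,
        fs=rec.fs,
        method=method,
        class_names=templates.labels,
        template_provenance=dict(templates.provenance),
    )


def _runs_of(labels: np.ndarray) -> list[tuple[int, int, int]]:
    n = len(labels)
    if n == 0:
        return []
    breaks = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [n]))
    return [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)]


def _fix_one_short_run(
    labels: np.ndarray, min_frames: int, policy: str
) -> np.ndarray | None:
    """Fix the leftmost labelled run shorter than min_frames; None if clean."""
    runs = _runs_of(labels)
    if len(runs) <= 1:
        return None
    for ri, (s, e, lab) in enumerate(runs):
        if lab == UNASSIGNED or e - s >= min_frames:
            continue
        new = labels.copy()
        if policy == "drop":
            new[s:e] = UNASSIGNED
            return new
        left = runs[ri - 1][2] if ri > 0 else None
        right = runs[ri + 1][2] if ri < len(runs) - 1 else None
        if left is None and right is None:  # unreachable: len(runs) > 1
            return None
        if left is None:
            new[s:e] = right
        elif right is None:
            new[s:e] = left
        else:
            mid = s + (e - s) // 2
            new[s:mid] = left
            new[mid:e] = right
        return new
    return None


def smooth_labels(
    seq: LabelSequence, min_frames: int, policy: str = "split_to_neighbors"
) -> LabelSequence:
    """Remove labelled runs shorter than ``min_frames``.

    ``split_to_neighbors`` (default, Cartool-style small-segment rejection):
    each short run is cut at its midpoint, the left half absorbed by the left
    neighbour and the right half by the right neighbour; a short run touching
    a sequence boundary is absorbed entirely by its single neighbour.
    ``drop``: short-run frames become unassigned.  Either way the pass repeats
    until no labelled run is shorter than ``min_frames``.  Correlations are
    kept unchanged — they record the original assignment.
    """
    if min_frames < 1:
        raise ConfigurationError("min_frames must be >= 1")
    if policy not in ("split_to_neighbors", "drop"):
        raise ConfigurationError(f"unknown smoothing policy {policy!r}")
    labels = seq.labels.copy()
    while True:
        fixed = _fix_one_short_run(labels, min_frames, policy)
        if fixed is None:
            break
        labels = fixed
    return replace(seq, labels=labels, corr=seq.corr.copy())


def backfit_conventional(
    group_recs: list[Recording],
    group_templates: TemplateSet,
    min_frames: int | None = None,
    smoothing: str | None = "split_to_neighbors",
    polarity_invariant: bool = True,
) -> list[LabelSequence]:
    """Label each group recording with the group's own aggregate templates."""
    out = []
    for rec in group_recs:
        seq = assign_frames(
            rec, group_templates, polarity_invariant, method="conventional"
        )
        if smoothing is not None:
            mf = default_min_frames(rec.fs) if min_frames is None else min_frames
            seq = smooth_labels(seq, mf, smoothing)
        out.append(seq)
    return out


def backfit_individual(
    rec: Recording,
    reference: TemplateSet,
    k_individual: int = 5,
    min_frames: int | None = None,
    smoothing: str | None = "split_to_neighbors",
    polarity_invariant: bool = True,
    return_details: bool = False,
):
    """Individual-clustering backfit re-expressed in reference class names.

    Pipeline: GFP peaks → AAHC to ``k_individual`` own templates → frame
    assignment with the own templates → template matching to ``reference`` →
    relabelling into reference classes (merging when two own templates share a
    reference class) → smoothing.  Reference classes that attract no own
    template are simply absent from the output sequence.

    With ``return_details`` the own template set, the pre-relabel sequence and
    the template mapping are returned alongside, which downstream GEV needs to
    correlate frames against the template that actually won them.
    """
    rec_avg = average_reference(rec)
    gfp = detect_gfp_peaks(global_field_power(rec_avg))
    if len(gfp.peak_indices) < k_individual:
        raise ConfigurationError(
            f"recording yields {len(gfp.peak_indices)} GFP peaks; "
            f"{k_individual} required for individual clustering"
        )
    peak_maps = [
        TopographicMap(rec_avg.channel_names, rec_avg.data[:, t])
        for t in gfp.peak_indices
    ]
    own = aahc_cluster(peak_maps, k_individual, weighting="gev")
    own_seq = assign_frames(rec_avg, own, polarity_invariant, method="individual")
    mapping = match_templates(own, reference)
    ref_index = {label: i for i, label in enumerate(reference.labels)}
    translate = np.array(
        [ref_index[mapping.reference_label_for(label)] for label in own.labels]
    )
    labels = np.where(
        own_seq.labels == UNASSIGNED, UNASSIGNED, translate[own_seq.labels]
    )
    seq = LabelSequence(
        labels=labels,
        corr=own_seq.corr.copy(),
        fs=rec.fs,
        method="individual",
        class_names=reference.labels,
        template_provenance={
            "reference": dict(reference.provenance),
            "individual": dict(own.provenance),
            "mapping": [list(p) for p in mapping.pairs],
        },
    )
    if smoothing is not None:
        mf = default_min_frames(rec.fs) if min_frames is None else min_frames
        seq = smooth_labels(seq, mf, smoothing)
    if return_details:
        return seq, own, own_seq, mapping
    return seq


def backfit_optimized(
    rec: Recording,
    reference: TemplateSet,
    min_frames: int | None = None,
    smoothing: str | None = "split_to_neighbors",
    polarity_invariant: bool = True,
) -> LabelSequence:
    """Assign raw frames directly to the reference (healthy-control) templates.

    Every reference class is available to every subject, which is what makes
    the per-class explained variance comparable across groups.
    """
    seq = assign_frames(rec, reference, polarity_invariant, method="optimized")
    if smoothing is not None:
        mf = default_min_frames(rec.fs) if min_frames is None else min_frames
        seq = smooth_labels(seq, mf, smoothing)
    return seq
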