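"""Per-class microstate statistics and group comparisons.

Global explained variance (GEV) of class ``k`` is the fraction of total
GFP²-weighted signal variance carried by the frames assigned to that class:

    GEV_k = sum_{t: L(t)=k} GFP(t)² · r(t)²  /  sum_t GFP(t)²

with ``r(t)`` the spatial correlation between frame ``t`` and the template of
its assigned class.  The denominator runs over *all* frames, so unassigned
frames dilute GEV but never inflate it, and the per-class values sum exactly
to the total.  Split microstates — several template maps matched to one
reference class — are merged by summing their numerators before reporting.

Temporal statistics follow the EEGLAB convention: duration is the mean length
of a class's contiguous runs, occurrence its number of run onsets per second,
coverage its fraction of frames.  Runs touching the sequence boundary are
included by default; with ``exclude_boundary_runs`` all three statistics are
computed from interior runs only, under which occurrence × duration(s) =
coverage holds exactly per class.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .backfit import UNASSIGNED, LabelSequence
from .clustering import TemplateMapping, TemplateSet
from .errors import ConfigurationError, DataError
from .io import Recording, align_channels
from .topography import average_reference

__all__ = [
    "ClassStats",
    "MicrostateStats",
    "GroupComparisonResult",
    "gev_per_class",
    "duration_occurrence",
    "summarize",
    "compare_groups",
]


@dataclass
class ClassStats:
    gev: float = math.nan
    mean_duration_ms: float = math.nan
    occurrence_per_s: float = math.nan
    coverage: float = math.nan
    n_segments: int = 0


@dataclass
class MicrostateStats:
    """Per-class GEV / duration / occurrence / coverage for one subject."""

    subject_id: str
    method: str
    class_names: tuple[str, ...]
    per_class: dict[str, ClassStats]
    total_gev: float = math.nan
    grand_mean_duration_ms: float = math.nan
    grand_mean_occurrence_per_s: float = math.nan

    def merged_with(self, other: "MicrostateStats") -> "MicrostateStats":
        """Combine GEV fields from one computation with temporal fields from another."""
        if self.class_names != other.class_names:
            raise DataError("cannot merge stats with different class names")
        per_class = {}
        for name in self.class_names:
            a, b = self.per_class[name], other.per_class[name]
            per_class[name] = ClassStats(
                gev=a.gev if not math.isnan(a.gev) else b.gev,
                mean_duration_ms=b.mean_duration_ms
                if not math.isnan(b.mean_duration_ms)
                else a.mean_duration_ms,
                occurrence_per_s=b.occurrence_per_s
                if not math.isnan(b.occurrence_per_s)
                else a.occurrence_per_s,
                coverage=b.coverage if not math.isnan(b.coverage) else a.coverage,
                n_segments=b.n_segments or a.n_segments,
            )
        return MicrostateStats(
            subject_id=self.subject_id,
            method=self.method,
            class_names=self.class_names,
            per_class=per_class,
            total_gev=self.total_gev
            if not math.isnan(self.total_gev)
            else other.total_gev,
            grand_mean_duration_ms=other.grand_mean_duration_ms,
            grand_mean_occurrence_per_s=other.grand_mean_occurrence_per_s,
        )


def gev_per_class(
    rec: Recording,
    seq: LabelSequence,
    templates: TemplateSet,
    merge_map: TemplateMapping | None = None,
    subject_id: str | None = None,
) -> MicrostateStats:
    """Per-class global explained variance (GEV fields only).

    ``seq.labels`` must index ``templates.maps``.  With ``merge_map`` the
    per-template numerators are summed into the mapped reference classes and
    the result is reported in reference class names (unmatched reference
    classes get GEV 0).
    """
    if seq.n_frames != rec.n_frames:
        raise DataError(
            f"frame count mismatch: recording has {rec.n_frames}, "
            f"label sequence has {seq.n_frames}"
        )
    if len(seq.class_names) != templates.k:
        raise DataError("label sequence classes do not match template set")
    rec = average_reference(align_channels(rec, templates.montage))
    frames = rec.data.T  # zero-mean per frame
    n_ch = rec.n_channels
    gfp_sq = np.sum(frames**2, axis=1) / n_ch
    denom = float(np.sum(gfp_sq))
    if denom == 0.0:
        raise DataError("recording has zero total GFP; GEV undefined")
    # gfp² · r² = (frame · T_label)² / n_ch for unit-norm centered templates
    numer = np.zeros(templates.k)
    labeled = seq.labels != UNASSIGNED
    if np.any(labeled):
        proj = frames[labeled] @ templates.matrix  # frames × k
        chosen = proj[np.arange(int(labeled.sum())), seq.labels[labeled]]
        contrib = chosen**2 / n_ch
        np.add.at(numer, seq.labels[labeled], contrib)
    gev = numer / denom

    if merge_map is None:
        class_names = templates.labels
        gev_by_class = {name: float(g) for name, g in zip(class_names, gev)}
    else:
        class_names = merge_map.reference_labels or tuple(
            dict.fromkeys([p[1] for p in merge_map.pairs])
            | dict.fromkeys(merge_map.unmatched_reference_labels)
        )
        gev_by_class = {name: 0.0 for name in class_names}
        for cand_label, ref_label, _ in merge_map.pairs:
            idx = templates.labels.index(cand_label)
            gev_by_class[ref_label] += float(gev[idx])
    per_class = {name: ClassStats(gev=g) for name, g in gev_by_class.items()}
    return MicrostateStats(
        subject_id=subject_id or rec.subject_id,
        method=seq.method,
        class_names=tuple(class_names),
        per_class=per_class,
        total_gev=float(np.sum(gev)),
    )


def duration_occurrence(
    seq: LabelSequence,
    exclude_boundary_runs: bool = False,
    subject_id: str = "",
) -> MicrostateStats:
    """Mean duration (ms), occurrence (1/s) and coverage per class.

    Classes with no (counted) runs report 0 for all three.  Grand means are
    unweighted over the classes present.
    """
    if seq.n_frames == 0:
        raise DataError("empty label sequence")
    n_frames = seq.n_frames
    total_s = n_frames / seq.fs
    runs = seq.runs()
    per_class: dict[str, ClassStats] = {}
    durations_present, occurrences_present = [], []
    for ci, name in enumerate(seq.class_names):
        cls_runs = [
            (s, e)
            for s, e, lab in runs
            if lab == ci
            and not (exclude_boundary_runs and (s == 0 or e == n_frames))
        ]
        if cls_runs:
            lengths = np.array([e - s for s, e in cls_runs], dtype=float)
            mean_dur_ms = float(lengths.mean() / seq.fs * 1000.0)
            occ = len(cls_runs) / total_s
            coverage = float(lengths.sum() / n_frames)
            durations_present.append(mean_dur_ms)
            occurrences_present.append(occ)
        else:
            mean_dur_ms, occ, coverage = 0.0, 0.0, 0.0
        per_class[name] = ClassStats(
            mean_duration_ms=mean_dur_ms,
            occurrence_per_s=occ,
            coverage=coverage,
            n_segments=len(cls_runs),
        )
    return MicrostateStats(
        subject_id=subject_id,
        method=seq.method,
        class_names=seq.class_names,
        per_class=per_class,
        grand_mean_duration_ms=float(np.mean(durations_present))
        if durations_present
        else 0.0,
        grand_mean_occurrence_per_s=float(np.mean(occurrences_present))
        if occurrences_present
        else 0.0,
    )


def summarize(
    rec: Recording,
    seq: LabelSequence,
    templates: TemplateSet,
    merge_map: TemplateMapping | None = None,
    exclude_boundary_runs: bool = False,
) -> MicrostateStats:
    """GEV plus temporal statistics in one table.

    When ``merge_map`` is given, ``seq`` must index ``templates``
    (pre-relabel); the temporal statistics are then computed on the merged
    reference classes.
    """
    gev_stats = gev_per_class(rec, seq, templates, merge_map)
    if merge_map is None:
        temporal = duration_occurrence(
            seq, exclude_boundary_runs, subject_id=rec.subject_id
        )
    else:
        ref_names = gev_stats.class_names
        index = {name: i for i, name in enumerate(ref_names)}
        translate = np.array(
            [
                index[merge_map.reference_label_for(label)]
                for label in templates.labels
            ]
        )
        merged_labels = np.where(
            seq.labels == UNASSIGNED, UNASSIGNED, translate[seq.labels]
        )
        merged_seq = LabelSequence(
            labels=merged_labels,
            corr=seq.corr,
            fs=seq.fs,
            method=seq.method,
            class_names=ref_names,
        )
        temporal = duration_occurrence(
            merged_seq, exclude_boundary_runs, subject_id=rec.subject_id
        )
    return gev_stats.merged_with(temporal)


@dataclass
class GroupComparisonResult:
    """Outcome of one between-group test with Bonferroni-adjusted pairwise p."""

    variable: str
    group_names: tuple[str, ...]
    test: str  # one_way_anova | kruskal_wallis | t_test | chi_squared
    statistic: float
    p_value: float
    pairwise: list[tuple[str, str, float, float]] = field(default_factory=list)
    # (group_a, group_b, raw p, Bonferroni-adjusted p)


def _ks_normal(x: np.ndarray) -> bool:
    """Kolmogorov–Smirnov normality check at alpha = 0.05 on z-scored values."""
    sd = x.std(ddof=1)
    if sd == 0:
        return False
    z = (x - x.mean()) / sd
    return sps.kstest(z, "norm").pvalue >= 0.05


def compare_groups(
    values,
    groups,
    test: str = "auto",
    pairwise: bool = True,
    variable: str = "value",
) -> GroupComparisonResult:
    """Between-group test with Bonferroni-adjusted pairwise comparisons.

    ``auto`` picks ANOVA (>2 groups) or the t-test (2 groups) when every group
    passes the Kolmogorov–Smirnov normality check at α = 0.05, otherwise
    Kruskal–Wallis.  ``chi_squared`` treats ``values`` as categorical.
    """
    values = np.asarray(values)
    groups = np.asarray(groups)
    names = tuple(dict.fromkeys(groups.tolist()))
    if len(names) < 2:
        raise ConfigurationError("compare_groups needs at least 2 groups")
    by_group = {g: values[groups == g] for g in names}

    if test == "chi_squared":
        cats = tuple(dict.fromkeys(values.tolist()))
        table = np.array(
            [[np.sum(by_group[g] == c) for c in cats] for g in names], dtype=float
        )
        stat, p, _, _ = sps.chi2_contingency(table)
        result = GroupComparisonResult(variable, names, test, float(stat), float(p))
        if pairwise and len(names) > 2:
            n_pairs = len(names) * (len(names) - 1) // 2
            for a, b in itertools.combinations(names, 2):
                sub = np.array(
                    [
                        [np.sum(by_group[g] == c) for c in cats]
                        for g in (a, b)
                    ],
                    dtype=float,
                )
                sub = sub[:, sub.sum(axis=0) > 0]
                _, p_raw, _, _ = sps.chi2_contingency(sub)
                result.pairwise.append((a, b, float(p_raw), min(1.0, p_raw * n_pairs)))
        return result

    values = values.astype(float)
    for g in names:
        if len(by_group[g]) < 2:
            raise ConfigurationError(f"group {g!r} has fewer than 2 observations")
    if test == "auto":
        normal = all(_ks_normal(by_group[g]) for g in names)
        if normal:
            test = "t_test" if len(names) == 2 else "one_way_anova"
        else:
            test = "kruskal_wallis"

    samples = [by_group[g] for g in names]
    if np.ptp(values) == 0:
        stat, p = 0.0, 1.0  # identical values: no between-group effect
    elif test == "one_way_anova":
        stat, p = sps.f_oneway(*samples)
    elif test == "kruskal_wallis":
        stat, p = sps.kruskal(*samples)
    elif test == "t_test":
        if len(names) != 2:
            raise ConfigurationError("t_test requires exactly 2 groups")
        stat, p = sps.ttest_ind(*samples)
    else:
        raise ConfigurationError(f"unknown test {test!r}")

    result = GroupComparisonResult(
        variable, names, test, float(stat), float(p)
    )
    if pairwise:
        pairs = list(itertools.combinations(names, 2))
        for a, b in pairs:
            xa, xb = by_group[a], by_group[b]
            if np.ptp(np.concatenate([xa, xb])) == 0:
                p_raw = 1.0
            elif test == "kruskal_wallis":
                p_raw = float(sps.mannwhitneyu(xa, xb).pvalue)
            else:
                p_raw = float(sps.ttest_ind(xa, xb).pvalue)
            result.pairwise.append((a, b, p_raw, min(1.0, p_raw * len(pairs))))
    return result
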