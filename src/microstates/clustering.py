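"""Template extraction by atomize-and-agglomerate hierarchical clustering.

AAHC starts from every GFP-peak map as its own cluster and removes one cluster
per iteration: the cluster contributing the least explained variance is
dissolved and each of its members is reassigned to the surviving cluster whose
centroid it correlates with most strongly in absolute value.  A cluster's
contribution is the sum over members of the squared polarity-invariant
correlation to its centroid, weighted by each member's squared GFP when the
members are raw peak maps (``weighting="gev"``); pooled template maps carry no
meaningful GFP and are clustered unweighted.

Centroids are polarity-aligned normalized means: each member's sign is flipped
to correlate positively with the current centroid, the flipped members are
averaged, normalized, and the flip/mean step is iterated to convergence.  The
procedure is fully deterministic — ties are broken toward the lower index —
so no seed is involved.

Cluster order is arbitrary; canonical microstate names (A–E) are assigned only
by matching against a reference set (:func:`match_templates`), never by
cluster order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .topography import TopographicMap, normalize_map

__all__ = [
    "TemplateSet",
    "TemplateMapping",
    "SelectKResult",
    "aahc_cluster",
    "select_k",
    "aggregate_group_templates",
    "match_templates",
]

_ALIGN_TOL = 1e-8
_ALIGN_MAX_ITER = 100


@dataclass
class TemplateSet:
    """k labelled, normalized template maps on a shared montage."""

    maps: list[TopographicMap]
    montage: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.montage = tuple(self.montage)
        if not self.maps:
            raise ValueError("a template set needs at least one map")
        labels = [m.label for m in self.maps]
        if len(set(labels)) != len(labels):
            raise ValueError("template labels must be unique")
        maps = []
        for m in self.maps:
            m = m.reordered(self.montage)
            scale = float(np.max(np.abs(m.values))) or 1.0
            mean = abs(float(m.values.mean()))
            norm = float(np.linalg.norm(m.values))
            if mean < 1e-12 * scale and abs(norm - 1.0) < 1e-12:
                maps.append(m)  # already normalized: keep bitwise (round trips)
            else:
                maps.append(normalize_map(m))
        self.maps = maps

    @property
    def k(self) -> int:
        return len(self.maps)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(m.label for m in self.maps)

    @property
    def matrix(self) -> np.ndarray:
        """Channels × k matrix of template values."""
        return np.column_stack([m.values for m in self.maps])


@dataclass
class TemplateMapping:
    """Assignment of candidate maps to their best reference class.

    Many-to-one is allowed (two candidates may both match reference class E);
    reference classes receiving no candidate are listed as unmatched.
    """

    pairs: list[tuple[str, str, float]]  # (candidate label, reference label, |r|)
    unmatched_reference_labels: tuple[str, ...]
    reference_labels: tuple[str, ...] = ()  # full reference class order

    def reference_label_for(self, candidate_label: str) -> str:
        for cand, ref, _ in self.pairs:
            if cand == candidate_label:
                return ref
        raise KeyError(candidate_label)


def _as_unit_matrix(maps: list[TopographicMap], montage: tuple[str, ...]) -> np.ndarray:
    """Maps × channels matrix of centered, unit-norm map vectors."""
    out = np.empty((len(maps), len(montage)))
    for i, m in enumerate(maps):
        out[i] = normalize_map(m.reordered(montage)).values
    return out


def _aligned_centroid(unit_members: np.ndarray, init: np.ndarray | None = None) -> np.ndarray:
    """Polarity-aligned normalized mean of unit map vectors (iterated to a fixed point)."""
    if len(unit_members) == 1:
        return unit_members[0].copy()
    c = unit_members[0] if init is None else init
    for _ in range(_ALIGN_MAX_ITER):
        signs = np.where(unit_members @ c >= 0, 1.0, -1.0)
        mean = (signs[:, None] * unit_members).mean(axis=0)
        mean -= mean.mean()
        norm = np.linalg.norm(mean)
        if norm == 0.0:
            # perfectly cancelling members; fall back to the first member
            return unit_members[0].copy()
        new = mean / norm
        if np.linalg.norm(new - c) < _ALIGN_TOL:
            return new
        c = new
    return c


def aahc_cluster(
    peak_maps: list[TopographicMap],
    k_target: int,
    weighting: str = "gev",
) -> TemplateSet:
    """Reduce GFP-peak maps to ``k_target`` templates by AAHC.

    Returned maps are cluster centroids labelled ``M1..Mk`` in order of
    decreasing explained variance.
    """
    if not peak_maps:
        raise ConfigurationError("aahc_cluster: empty input")
    if not 1 <= k_target <= len(peak_maps):
        raise ConfigurationError(
            f"aahc_cluster: k_target={k_target} outside [1, {len(peak_maps)}]"
        )
    if weighting not in ("gev", "unweighted"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    montage = tuple(peak_maps[0].channel_names)
    unit = _as_unit_matrix(peak_maps, montage)
    if weighting == "gev":
        # squared GFP of each raw map (population variance across channels)
        weights = np.array(
            [np.mean((m.reordered(montage).values - m.values.mean()) ** 2) for m in peak_maps]
        )
        if np.all(weights == 0):
            weights = np.ones(len(peak_maps))
    else:
        weights = np.ones(len(peak_maps))

    members: list[list[int]] = [[i] for i in range(len(peak_maps))]
    centroids: list[np.ndarray] = [unit[i].copy() for i in range(len(peak_maps))]

    def contribution(ci: int) -> float:
        idx = members[ci]
        r = unit[idx] @ centroids[ci]
        return float(np.sum(weights[idx] * r**2))

    contrib = [contribution(i) for i in range(len(members))]

    while len(members) > k_target:
        worst = int(np.argmin(contrib))  # lower index wins ties
        orphan_idx = members.pop(worst)
        centroids.pop(worst)
        contrib.pop(worst)
        cent = np.asarray(centroids)
        # reassign each orphan to the surviving cluster it correlates with most
        corr = np.abs(unit[orphan_idx] @ cent.T)
        dest = np.argmax(corr, axis=1)  # argmax → lower index on ties
        touched = set()
        for member, d in zip(orphan_idx, dest):
            members[d].append(member)
            touched.add(int(d))
        for d in touched:
            centroids[d] = _aligned_centroid(unit[members[d]], init=centroids[d])
            contrib[d] = contribution(d)

    order = np.argsort([-c for c in contrib], kind="stable")
    maps = [
        TopographicMap(montage, centroids[i], label=f"M{rank + 1}")
        for rank, i in enumerate(order)
    ]
    total_weight = float(np.sum(weights))
    ev = [contrib[i] / total_weight for i in order]
    return TemplateSet(
        maps=maps,
        montage=montage,
        provenance={
            "kind": "individual",
            "weighting": weighting,
            "n_maps": len(peak_maps),
            "k": k_target,
            "explained_variance": ev,
        },
    )


@dataclass
class SelectKResult:
    """Diagnostics from split-half reliability scanning over k."""

    k_range: tuple[int, ...]
    reliability: tuple[float, ...]  # mean |r| between matched half centroids
    explained_variance: tuple[float, ...]
    best_k: int


def _greedy_match_mean_corr(a: TemplateSet, b: TemplateSet) -> float:
    """Greedy one-to-one matching of two template sets; returns mean |r|."""
    corr = np.abs(a.matrix.T @ _as_unit_matrix(b.maps, a.montage).T)
    corr = corr.copy()
    picked = []
    for _ in range(min(corr.shape)):
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        picked.append(corr[i, j])
        corr[i, :] = -1
        corr[:, j] = -1
    return float(np.mean(picked))


def select_k(
    peak_maps: list[TopographicMap],
    k_range: tuple[int, int],
    n_splits: int = 10,
    seed: int = 0,
) -> SelectKResult:
    """Scan k over ``k_range`` reporting split-half map reliability.

    Reliability at each k is the mean absolute correlation between greedily
    matched centroids clustered from random half-splits of the peak maps.
    The toolkit's pipeline default is k=5 independent of this diagnostic.
    """
    lo, hi = k_range
    n = len(peak_maps)
    if lo < 1 or hi < lo:
        raise ConfigurationError(f"bad k_range {k_range}")
    if hi > max(1, n // 2):
        raise ConfigurationError(
            f"k_range upper bound {hi} exceeds half the number of maps ({n})"
        )
    rng = np.random.default_rng(seed)
    ks = tuple(range(lo, hi + 1))
    reliability = []
    evs = []
    for k in ks:
        rel_vals = []
        for _ in range(n_splits):
            perm = rng.permutation(n)
            half = n // 2
            first = [peak_maps[i] for i in perm[:half]]
            second = [peak_maps[i] for i in perm[half : 2 * half]]
            set_a = aahc_cluster(first, k)
            set_b = aahc_cluster(second, k)
            rel_vals.append(_greedy_match_mean_corr(set_a, set_b))
        reliability.append(float(np.mean(rel_vals)))
        full = aahc_cluster(peak_maps, k)
        evs.append(float(np.sum(full.provenance["explained_variance"])))
    best_k = ks[int(np.argmax(reliability))]
    return SelectKResult(
        k_range=ks,
        reliability=tuple(reliability),
        explained_variance=tuple(evs),
        best_k=best_k,
    )


def aggregate_group_templates(
    individual_sets: list[TemplateSet], k_target: int
) -> TemplateSet:
    """Two-level aggregation: pool individual templates, re-cluster unweighted."""
    if not individual_sets:
        raise ConfigurationError("aggregate_group_templates: no input sets")
    montage = individual_sets[0].montage
    pooled: list[TopographicMap] = []
    for i, ts in enumerate(individual_sets):
        for m in ts.maps:
            pooled.append(
                TopographicMap(montage, m.reordered(montage).values, label=None)
            )
    result = aahc_cluster(pooled, k_target, weighting="unweighted")
    result.provenance = {
        **result.provenance,
        "kind": "group_aggregate",
        "n_subjects": len(individual_sets),
    }
    return result


def match_templates(candidates: TemplateSet, reference: TemplateSet) -> TemplateMapping:
    """Map each candidate map to its best reference class by maximum |r|.

    Every candidate is assigned independently, so several candidates may share
    one reference class (split microstates) and some reference classes may
    receive nothing — the structure seen when a patient group lacks a
    canonical map.  Ties go to the lower reference index.
    """
    cand_unit = _as_unit_matrix(candidates.maps, reference.montage)
    corr = np.abs(cand_unit @ reference.matrix)
    pairs = []
    hit: set[str] = set()
    for i, cand_map in enumerate(candidates.maps):
        j = int(np.argmax(corr[i]))
        ref_label = reference.maps[j].label
        pairs.append((cand_map.label, ref_label, float(corr[i, j])))
        hit.add(ref_label)
    unmatched = tuple(m.label for m in reference.maps if m.label not in hit)
    return TemplateMapping(
        pairs=pairs,
        unmatched_reference_labels=unmatched,
        reference_labels=reference.labels,
    )
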