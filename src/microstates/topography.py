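"""Scalp-map algebra: average reference, global field power, GFP peaks and
polarity-aware spatial correlation.

All quantities here are defined on average-referenced potentials.  The global
field power at frame ``t`` is the spatial standard deviation across the ``N``
channels,

    GFP(t) = sqrt( (1/N) * sum_i (v_i(t) - vbar(t))^2 ),

using the population normalisation (divide by ``N``).  Spatial similarity
between two maps is the Pearson correlation across channels; resting-state
microstate analysis conventionally ignores polarity, so the polarity-invariant
mode (absolute correlation) is the default throughout the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ChannelMismatchError, UndefinedCorrelationError
from .io import Recording, canonical_name

__all__ = [
    "TopographicMap",
    "GfpSeries",
    "average_reference",
    "global_field_power",
    "detect_gfp_peaks",
    "spatial_correlation",
    "normalize_map",
]


@dataclass(frozen=True)
class TopographicMap:
    """One scalp potential map: a value per channel, optionally labelled."""

    channel_names: tuple[str, ...]
    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if values.ndim != 1 or len(values) != len(self.channel_names):
            raise ValueError("values must be 1-D with one entry per channel")
        if not np.all(np.isfinite(values)):
            raise ValueError("topographic map contains non-finite values")

    def reordered(self, montage: Sequence[str]) -> "TopographicMap":
        """Return the map restricted/reordered to ``montage`` (matched by name)."""
        index = {canonical_name(c): i for i, c in enumerate(self.channel_names)}
        missing = [c for c in montage if canonical_name(c) not in index]
        if missing:
            raise ChannelMismatchError(
                f"channels missing from map: {', '.join(missing)}"
            )
        idx = [index[canonical_name(c)] for c in montage]
        return TopographicMap(tuple(montage), self.values[idx], self.label)


@dataclass
class GfpSeries:
    """Global field power per frame, with detected peak frame indices."""

    values: np.ndarray
    fs: float
    peak_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if np.any(self.values < 0):
            raise ValueError("GFP values must be non-negative")


def average_reference(rec: Recording) -> Recording:
    """Re-reference every frame to the instantaneous channel mean.

    Idempotent; the returned recording carries ``reference="average"``.
    """
    if rec.reference == "average":
        return rec
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data, reference="average")


def global_field_power(rec: Recording) -> GfpSeries:
    """Spatial standard deviation of the scalp field at each frame."""
    rec = average_reference(rec)
    gfp = np.sqrt(np.mean(rec.data**2, axis=0))
    return GfpSeries(values=gfp, fs=rec.fs)


def detect_gfp_peaks(g: GfpSeries, min_distance_frames: int = 1) -> GfpSeries:
    """Mark strict local maxima of the GFP curve.

    A peak is strictly greater than both neighbours (plateaus never count,
    endpoints never count).  When two accepted peaks would lie closer than
    ``min_distance_frames``, the larger one is kept; ties keep the earlier.
    """
    if min_distance_frames < 1:
        raise ValueError("min_distance_frames must be >= 1")
    v = g.values
    if len(v) < 3:
        return GfpSeries(v, g.fs, np.empty(0, dtype=int))
    inner = np.arange(1, len(v) - 1)
    strict = (v[inner] > v[inner - 1]) & (v[inner] > v[inner + 1])
    peaks = inner[strict]
    if min_distance_frames > 1 and len(peaks) > 1:
        # Greedy thinning: accept peaks in decreasing height order, reject any
        # candidate within min_distance of an already accepted peak.
        order = np.argsort(-v[peaks], kind="stable")
        accepted: list[int] = []
        for i in order:
            p = peaks[i]
            if all(abs(p - q) >= min_distance_frames for q in accepted):
                accepted.append(p)
        peaks = np.sort(np.asarray(accepted, dtype=int))
    return GfpSeries(v, g.fs, peaks)


def normalize_map(m: TopographicMap) -> TopographicMap:
    """Center the map across channels and scale it to unit L2 norm."""
    centered = m.values - m.values.mean()
    norm = float(np.linalg.norm(centered))
    if norm == 0.0:
        raise UndefinedCorrelationError("cannot normalize a constant map")
    return TopographicMap(m.channel_names, centered / norm, m.label)


def spatial_correlation(
    a: TopographicMap, b: TopographicMap, polarity_invariant: bool = True
) -> float:
    """Pearson correlation between two maps across channels.

    Channels are matched by name (case-insensitive), so the two maps may list
    the same montage in different orders.  With ``polarity_invariant`` (the
    default) the absolute correlation is returned, treating a map and its
    polarity reversal as the same topography.
    """
    b = b.reordered(a.channel_names)
    ac = a.values - a.values.mean()
    bc = b.values - b.values.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        raise UndefinedCorrelationError(
            "spatial correlation undefined for a constant map"
        )
    r = float(np.dot(ac, bc) / (na * nb))
    r = max(-1.0, min(1.0, r))
    return abs(r) if polarity_invariant else r
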