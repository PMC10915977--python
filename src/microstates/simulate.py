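"""Synthetic resting-EEG cohorts with known microstate ground truth.

The generator emulates the accepted picture of resting EEG as a sequence of
quasi-stable scalp topographies: a semi-Markov label process (alternating
classes, geometric dwell times with a default mean of 80 ms, inside the
60–120 ms range typical of microstates) drives a set of smooth, mutually
orthogonal template maps, scaled by a slowly varying positive amplitude
envelope, with optional polarity reversal per segment (resting-state
oscillatory polarity flips are why backfitting uses absolute correlation) and
additive white sensor noise.  Group differences are expressed through
per-class onset weights — e.g. boosting class E in a "poor prognosis" group.

Everything is deterministic per (spec, seed): subject-level seeds are spawned
from the cohort seed, so adding subjects never perturbs existing ones.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clustering import TemplateSet
from .errors import ConfigurationError
from .io import CohortManifest, Recording, write_manifest, write_recording
from .topography import TopographicMap, average_reference

__all__ = [
    "TEN_TWENTY_19",
    "SyntheticCohortSpec",
    "SyntheticTruth",
    "CohortResult",
    "make_templates",
    "simulate_label_sequence",
    "simulate_recording",
    "simulate_cohort",
]

# 10-20 system, 19 electrodes, with approximate 2-D layout positions
# (x: left → right, y: posterior → anterior), used to build smooth maps.
TEN_TWENTY_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

_POSITIONS: dict[str, tuple[float, float]] = {
    "fp1": (-0.31, 0.95), "fp2": (0.31, 0.95),
    "f7": (-0.81, 0.59), "f3": (-0.40, 0.54), "fz": (0.0, 0.50),
    "f4": (0.40, 0.54), "f8": (0.81, 0.59),
    "t3": (-1.0, 0.0), "c3": (-0.50, 0.0), "cz": (0.0, 0.0),
    "c4": (0.50, 0.0), "t4": (1.0, 0.0),
    "t5": (-0.81, -0.59), "p3": (-0.40, -0.54), "pz": (0.0, -0.50),
    "p4": (0.40, -0.54), "t6": (0.81, -0.59),
    "o1": (-0.31, -0.95), "o2": (0.31, -0.95),
}


def electrode_positions(montage: tuple[str, ...]) -> np.ndarray:
    """2-D layout for a montage: 10-20 names where known, else a unit circle."""
    pos = np.empty((len(montage), 2))
    unknown = [i for i, c in enumerate(montage) if c.strip().lower() not in _POSITIONS]
    for i, c in enumerate(montage):
        key = c.strip().lower()
        if key in _POSITIONS:
            pos[i] = _POSITIONS[key]
    if unknown:
        angles = np.linspace(0, 2 * np.pi, len(unknown), endpoint=False)
        for j, i in enumerate(unknown):
            pos[i] = (np.cos(angles[j]), np.sin(angles[j]))
    return pos


@dataclass
class SyntheticCohortSpec:
    """Study conditions for a simulated cohort.

    Defaults: 19-channel 10-20 montage at 250 Hz, 60 s per subject, k = 5
    classes dwelling ~80 ms, amplitude envelope averaging 15 µV against 3 µV
    sensor noise (SNR 5), polarity flipped per segment with probability 0.5.
    Per-group ``class_weights`` are relative onset probabilities; omitted
    groups use uniform weights.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"control": 10, "poor_prognosis": 10}
    )
    montage: tuple[str, ...] = TEN_TWENTY_19
    fs: float = 250.0
    duration_s: float = 60.0
    k: int = 5
    dwell_mean_ms: float = 80.0
    class_weights: dict[str, tuple[float, ...]] = field(default_factory=dict)
    amplitude_mean_uv: float = 15.0
    noise_sd_uv: float = 3.0
    polarity_flip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_group.values()):
            raise ConfigurationError("n_per_group counts must be >= 1")
        if self.dwell_mean_ms <= 0:
            raise ConfigurationError("dwell_mean_ms must be positive")
        if self.fs * self.duration_s < 10:
            raise ConfigurationError("cohort spec yields fewer than 10 frames")
        for group, w in self.class_weights.items():
            w = tuple(float(x) for x in w)
            if len(w) != self.k or any(x < 0 for x in w) or sum(w) <= 0:
                raise ConfigurationError(
                    f"class_weights for {group!r} must be {self.k} non-negative "
                    "numbers with positive sum"
                )
            self.class_weights[group] = w

    def weights_for(self, group: str) -> np.ndarray:
        w = self.class_weights.get(group)
        return np.asarray(w if w is not None else [1.0] * self.k, dtype=float)

    @property
    def n_frames(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass
class SubjectTruth:
    """Ground truth for one simulated subject."""

    subject_id: str
    group: str
    labels: np.ndarray  # true class per frame
    segment_signs: np.ndarray  # polarity sign per frame
    envelope: np.ndarray  # amplitude per frame (µV)


@dataclass
class SyntheticTruth:
    """Cohort-level ground truth: per-subject truths, templates, spec echo."""

    spec: SyntheticCohortSpec
    templates: TemplateSet
    subjects: dict[str, SubjectTruth]


@dataclass
class CohortResult:
    recordings: list[Recording]
    truth: SyntheticTruth
    manifest: CohortManifest | None = None


def make_templates(
    montage: tuple[str, ...] = TEN_TWENTY_19, k: int = 5, seed: int = 0
) -> TemplateSet:
    """k smooth, mutually orthogonal (hence |r| = 0 pairwise) template maps.

    Maps are random rotations of low-order spatial polynomials over the
    electrode layout, centered and orthonormalized, labelled A, B, C, ...
    Deterministic per seed.
    """
    n_ch = len(montage)
    if not 1 <= k <= n_ch - 1:
        raise ConfigurationError(
            f"k={k} must be between 1 and channels-1 ({n_ch - 1})"
        )
    pos = electrode_positions(tuple(montage))
    x, y = pos[:, 0], pos[:, 1]
    basis = np.column_stack(
        [x, y, x**2 - y**2, 2 * x * y, x**2 + y**2, x * (x**2 - 3 * y**2),
         y * (3 * x**2 - y**2), np.exp(-((x**2 + (y - 0.8) ** 2)) / 0.4)]
    )
    basis = basis - basis.mean(axis=0, keepdims=True)
    rng = np.random.default_rng(seed)
    for _ in range(10):
        mix = rng.standard_normal((basis.shape[1], k))
        cand = basis @ mix
        cand -= cand.mean(axis=0, keepdims=True)
        q, r = np.linalg.qr(cand)
        if np.min(np.abs(np.diag(r))) > 1e-8:
            q = q[:, :k]
            q -= q.mean(axis=0, keepdims=True)  # renormalized below by TemplateSet
            labels = list(string.ascii_uppercase)[:k]
            maps = [
                TopographicMap(tuple(montage), q[:, j], label=labels[j])
                for j in range(k)
            ]
            return TemplateSet(
                maps=maps,
                montage=tuple(montage),
                provenance={"kind": "reference", "generator": "synthetic", "seed": seed},
            )
    raise ConfigurationError(
        "could not build linearly independent templates for this montage"
    )


def simulate_label_sequence(
    spec: SyntheticCohortSpec, group: str, n_frames: int, seed: int
) -> np.ndarray:
    """Semi-Markov ground-truth labels: alternating classes, geometric dwells.

    The next class is drawn proportionally to the group's class weights with
    the current class excluded; run lengths are geometric with mean
    ``dwell_mean_ms·fs/1000`` (minimum one frame).
    """
    rng = np.random.default_rng(seed)
    weights = spec.weights_for(group)
    mean_frames = max(1.0, spec.dwell_mean_ms * spec.fs / 1000.0)
    p = 1.0 / mean_frames
    labels = np.empty(n_frames, dtype=int)
    current = -1
    t = 0
    while t < n_frames:
        w = weights.copy()
        if current >= 0:
            w[current] = 0.0
        if w.sum() == 0:  # single positive-weight class: allow self-transition
            w = weights.copy()
        nxt = rng.choice(spec.k, p=w / w.sum())
        run = rng.geometric(p)
        labels[t : t + run] = nxt
        current = int(nxt)
        t += run
    return labels


def simulate_recording(
    templates: TemplateSet,
    true_labels: np.ndarray,
    amplitude_mean_uv: float = 15.0,
    noise_sd_uv: float = 3.0,
    polarity_flip_prob: float = 0.5,
    fs: float = 250.0,
    seed: int = 0,
    subject_id: str = "sim",
    group: str | None = None,
) -> tuple[Recording, SubjectTruth]:
    """Render a label sequence into a noisy multichannel recording.

    Frame ``t`` is ``s_seg · a(t) · T_L(t) + ε(t)``: the active template,
    scaled by a smooth positive amplitude envelope with mean
    ``amplitude_mean_uv``, sign-flipped per segment with probability
    ``polarity_flip_prob``, plus white channel noise of sd ``noise_sd_uv``;
    the result is average-referenced.
    """
    rng = np.random.default_rng(seed)
    n_frames = len(true_labels)
    t_sec = np.arange(n_frames) / fs
    phase = rng.uniform(0, 2 * np.pi)
    freq = rng.uniform(0.4, 1.0)  # Hz; slow amplitude modulation
    envelope = amplitude_mean_uv * (1.0 + 0.3 * np.sin(2 * np.pi * freq * t_sec + phase))

    # one polarity sign per contiguous true segment
    boundaries = np.flatnonzero(np.diff(true_labels)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n_frames]))
    signs = np.ones(n_frames)
    for s, e in zip(starts, ends):
        if rng.uniform() < polarity_flip_prob:
            signs[s:e] = -1.0

    matrix = templates.matrix  # channels × k, unit-norm columns
    signal = matrix[:, true_labels] * (signs * envelope)[None, :]
    noise = rng.normal(0.0, noise_sd_uv, size=signal.shape) if noise_sd_uv > 0 else 0.0
    rec = Recording(
        subject_id=subject_id,
        channel_names=templates.montage,
        fs=fs,
        data=signal + noise,
        group=group,
    )
    rec = average_reference(rec)
    truth = SubjectTruth(
        subject_id=subject_id,
        group=group or "",
        labels=np.asarray(true_labels, dtype=int).copy(),
        segment_signs=signs,
        envelope=envelope,
    )
    return rec, truth


def simulate_cohort(
    spec: SyntheticCohortSpec, out_dir: str | Path | None = None
) -> CohortResult:
    """Simulate every subject of a cohort; optionally write it to disk.

    With ``out_dir`` set, per-subject matrix recordings, truth label tables
    and a cohort manifest are written there and the returned result carries
    the manifest.
    """
    ss = np.random.SeedSequence(spec.seed)
    templates = make_templates(spec.montage, spec.k, seed=int(ss.generate_state(1)[0] % 2**31))
    subject_seeds = ss.spawn(sum(spec.n_per_group.values()))
    recordings: list[Recording] = []
    truths: dict[str, SubjectTruth] = {}
    i = 0
    for group, count in spec.n_per_group.items():
        for j in range(count):
            subject_id = f"{group}_{j + 1:02d}"
            child = subject_seeds[i].generate_state(2) % 2**31
            labels = simulate_label_sequence(spec, group, spec.n_frames, int(child[0]))
            rec, truth = simulate_recording(
                templates,
                labels,
                amplitude_mean_uv=spec.amplitude_mean_uv,
                noise_sd_uv=spec.noise_sd_uv,
                polarity_flip_prob=spec.polarity_flip_prob,
                fs=spec.fs,
                seed=int(child[1]),
                subject_id=subject_id,
                group=group,
            )
            recordings.append(rec)
            truths[subject_id] = truth
            i += 1
    truth = SyntheticTruth(spec=spec, templates=templates, subjects=truths)

    manifest = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for rec in recordings:
            rec_path = out_dir / f"{rec.subject_id}.tsv"
            write_recording(rec, rec_path, format="matrix")
            truth_path = out_dir / f"{rec.subject_id}.truth.tsv"
            lines = ["frame\ttrue_label"]
            lines += [f"{t}\t{lab}" for t, lab in enumerate(truths[rec.subject_id].labels)]
            truth_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
            entries.append((rec.subject_id, rec.group, rec_path, "matrix"))
        manifest = CohortManifest(entries=entries, fs=spec.fs)
        write_manifest(manifest, out_dir / "manifest.tsv")
        from .io import write_template_set

        write_template_set(templates, out_dir / "true_templates.tsv")
    return CohortResult(recordings=recordings, truth=truth, manifest=manifest)
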