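"""Readers and writers for every on-disk artifact the pipeline touches.

Supported recording formats: EDF, BrainVision (vhdr/vmrk/eeg triple) and a
plain tab-separated matrix (one frame per row, one channel per column, channel
names in the first row).  EDF and BrainVision are parsed with ``mne``; the
matrix dialect is fixed (tab delimiter, ``.`` decimal) so that round trips are
bit-exact.  Template sets, label sequences and statistics tables are
tab-separated tables with a JSON sidecar carrying names and provenance.

Channel identity is always by name — case-insensitive, whitespace-stripped —
never by position: template sets and patient files may order their montages
differently, and positional matching would silently corrupt every spatial
correlation downstream.

EDF writing is implemented directly (16-bit samples, physical range ±1000 µV,
hence a quantisation step of 2000/65535 ≈ 0.031 µV); reads go through ``mne``,
so the writer is exercised against an independent parser.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .errors import (
    ChannelMismatchError,
    ConfigurationError,
    FormatError,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .backfit import LabelSequence
    from .clustering import TemplateSet
    from .stats import MicrostateStats

__all__ = [
    "Recording",
    "CohortManifest",
    "canonical_name",
    "read_recording",
    "write_recording",
    "align_channels",
    "read_template_set",
    "write_template_set",
    "read_label_sequence",
    "write_label_sequence",
    "read_stats_table",
    "write_stats_table",
    "read_manifest",
    "write_manifest",
]

EDF_PHYSICAL_RANGE_UV = 1000.0  # ± bound; fixes the 16-bit quantisation step


def canonical_name(name: str) -> str:
    """Canonical channel identity: whitespace-stripped, lower-case."""
    return name.strip().lower()


@dataclass
class Recording:
    """One subject's multichannel EEG in microvolts (channels × frames)."""

    subject_id: str
    channel_names: tuple[str, ...]
    fs: float
    data: np.ndarray
    reference: str = "raw"  # "raw" | "average"
    group: str | None = None

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels × frames matrix")
        n_ch, n_fr = self.data.shape
        if n_ch != len(self.channel_names):
            raise ValueError("data row count must match channel_names")
        if n_ch < 3:
            raise ValueError("a recording needs at least 3 channels")
        if n_fr < 2:
            raise ValueError("a recording needs at least 2 frames")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        canon = [canonical_name(c) for c in self.channel_names]
        if len(set(canon)) != len(canon):
            raise ValueError("channel names must be unique")
        if self.reference not in ("raw", "average"):
            raise ValueError("reference must be 'raw' or 'average'")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class CohortManifest:
    """Index of a cohort on disk: one (subject, group, file) entry per subject."""

    entries: list[tuple[str, str, Path, str]]  # subject_id, group, path, format
    fs: float

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids in a manifest must be unique")


def align_channels(rec: Recording, montage: Sequence[str]) -> Recording:
    """Reorder/subset a recording's channels to ``montage``, matched by name."""
    index = {canonical_name(c): i for i, c in enumerate(rec.channel_names)}
    missing = [c for c in montage if canonical_name(c) not in index]
    if missing:
        raise ChannelMismatchError(
            f"montage channels absent from recording '{rec.subject_id}': "
            + ", ".join(missing)
        )
    idx = [index[canonical_name(c)] for c in montage]
    return replace(rec, channel_names=tuple(montage), data=rec.data[idx])


# ---------------------------------------------------------------------------
# recordings


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs_override: float | None = None,
    subject_id: str | None = None,
    group: str | None = None,
) -> Recording:
    """Load an EEG recording from EDF, BrainVision or matrix text.

    ``format`` is inferred from the suffix (.edf / .vhdr / anything else =
    matrix) when not given.  Matrix files carry no sampling rate, so
    ``fs_override`` is mandatory for them; for the binary formats it overrides
    the stored rate when provided.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {"": "matrix", ".edf": "edf", ".vhdr": "brainvision"}.get(
            suffix, "matrix"
        )
    if subject_id is None:
        subject_id = path.stem
    if format == "matrix":
        if fs_override is None:
            raise ConfigurationError(
                "matrix recordings carry no sampling rate; pass fs_override"
            )
        names, data = _read_matrix(path)
        return Recording(subject_id, names, fs_override, data, group=group)
    if format in ("edf", "brainvision"):
        import mne  # heavy import, deferred

        try:
            if format == "edf":
                raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
            else:
                raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        except Exception as exc:  # mne raises assorted types for bad files
            raise FormatError(f"unreadable {format} file {path}: {exc}") from exc
        data_uv = raw.get_data() * 1e6  # mne stores volts
        fs = float(fs_override if fs_override is not None else raw.info["sfreq"])
        return Recording(subject_id, tuple(raw.ch_names), fs, data_uv, group=group)
    raise ConfigurationError(f"unknown recording format: {format!r}")


def _read_matrix(path: Path) -> tuple[tuple[str, ...], np.ndarray]:
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    names = tuple(lines[0].split("\t"))
    rows: list[list[float]] = []
    for row_no, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != len(names):
            raise FormatError(
                f"{path}: line {row_no} has {len(cells)} cells, expected {len(names)}"
            )
        row = []
        for col_no, cell in enumerate(cells, start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} at line {row_no}, "
                    f"column {col_no}"
                ) from None
        rows.append(row)
    data = np.asarray(rows, dtype=float).T  # stored frames × channels
    return names, data


def write_recording(rec: Recording, path: str | Path, format: str = "matrix") -> Path:
    """Write a recording as matrix text (lossless) or EDF (16-bit quantised)."""
    path = Path(path)
    if format == "matrix":
        lines = ["\t".join(rec.channel_names)]
        for frame in rec.data.T:
            lines.append("\t".join(repr(float(v)) for v in frame))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path
    if format == "edf":
        _write_edf(rec, path)
        return path
    raise ConfigurationError(f"unknown recording format: {format!r}")


def _edf_field(value: str, width: int) -> bytes:
    text = value[:width].ljust(width)
    return text.encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: one data record holding the whole recording."""
    n_ch, n_fr = rec.data.shape
    phys = EDF_PHYSICAL_RANGE_UV
    if np.any(np.abs(rec.data) > phys):
        raise ValueError(
            f"EDF physical range is ±{phys:g} µV; clip or rescale the recording"
        )
    duration = n_fr / rec.fs
    dur_text = f"{duration:.7g}"[:8]
    if not math.isclose(float(dur_text), duration, rel_tol=1e-9):
        raise ValueError("record duration not representable in an EDF header")
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(rec.subject_id, 80),
            _edf_field("Startdate 01-JAN-2000", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (n_ch + 1)), 8),
            _edf_field("", 44),
            _edf_field("1", 8),
            _edf_field(dur_text, 8),
            _edf_field(str(n_ch), 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_edf_field(c, 16) for c in rec.channel_names),
            b"".join(_edf_field("", 80) for _ in range(n_ch)),
            b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
            b"".join(_edf_field(f"{-phys:g}", 8) for _ in range(n_ch)),
            b"".join(_edf_field(f"{phys:g}", 8) for _ in range(n_ch)),
            b"".join(_edf_field("-32768", 8) for _ in range(n_ch)),
            b"".join(_edf_field("32767", 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 80) for _ in range(n_ch)),
            b"".join(_edf_field(str(n_fr), 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 32) for _ in range(n_ch)),
        ]
    )
    scale = 65535 / (2 * phys)  # digital units per µV
    digital = np.rint((rec.data + phys) * scale - 32768).astype(np.int64)
    digital = np.clip(digital, -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        fh.write(digital.tobytes())  # channel-major within the single record


# ---------------------------------------------------------------------------
# template sets


def write_template_set(templates: "TemplateSet", path: str | Path) -> Path:
    """Write a template set as channels × k TSV plus a JSON sidecar."""
    path = Path(path)
    labels = [m.label or f"M{i + 1}" for i, m in enumerate(templates.maps)]
    lines = ["\t".join(labels)]
    matrix = templates.matrix  # channels × k
    for row in matrix:
        lines.append("\t".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    sidecar = {
        "class_names": labels,
        "montage": list(templates.montage),
        "provenance": templates.provenance,
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2) + "\n", encoding="utf-8"
    )
    return path


def read_template_set(path: str | Path) -> "TemplateSet":
    from .clustering import TemplateSet
    from .topography import TopographicMap

    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
    montage = tuple(sidecar["montage"])
    lines = path.read_text(encoding="utf-8").splitlines()
    labels = lines[0].split("\t")
    rows = [[float(c) for c in line.split("\t")] for line in lines[1:] if line]
    matrix = np.asarray(rows, dtype=float)
    if matrix.shape != (len(montage), len(labels)):
        raise FormatError(
            f"{path}: matrix shape {matrix.shape} does not match sidecar "
            f"({len(montage)} channels × {len(labels)} classes)"
        )
    if labels != sidecar["class_names"]:
        raise FormatError(f"{path}: header labels disagree with sidecar class_names")
    maps = [
        TopographicMap(montage, matrix[:, j], label=labels[j])
        for j in range(len(labels))
    ]
    return TemplateSet(maps=maps, montage=montage, provenance=sidecar["provenance"])


# ---------------------------------------------------------------------------
# label sequences


def write_label_sequence(seq: "LabelSequence", path: str | Path) -> Path:
    """One (label, correlation) record per frame, with a JSON sidecar."""
    path = Path(path)
    lines = ["label\tcorr"]
    for lab, r in zip(seq.labels, seq.corr):
        lines.append(f"{int(lab)}\t{float(r)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    sidecar = {
        "class_names": list(seq.class_names),
        "fs": seq.fs,
        "method": seq.method,
        "template_provenance": seq.template_provenance,
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2) + "\n", encoding="utf-8"
    )
    return path


def read_label_sequence(path: str | Path) -> "LabelSequence":
    from .backfit import LabelSequence

    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != ["label", "corr"]:
        raise FormatError(f"{path}: expected 'label<TAB>corr' header")
    labels, corr = [], []
    for line in lines[1:]:
        if not line:
            continue
        lab, r = line.split("\t")
        labels.append(int(lab))
        corr.append(float(r))
    return LabelSequence(
        labels=np.asarray(labels, dtype=int),
        corr=np.asarray(corr, dtype=float),
        fs=float(sidecar["fs"]),
        method=sidecar["method"],
        class_names=tuple(sidecar["class_names"]),
        template_provenance=sidecar["template_provenance"],
    )


# ---------------------------------------------------------------------------
# statistics tables

_STATS_COLUMNS = [
    "subject_id",
    "method",
    "class",
    "gev",
    "mean_duration_ms",
    "occurrence_per_s",
    "coverage",
    "n_segments",
    "total_gev",
    "grand_mean_duration_ms",
    "grand_mean_occurrence_per_s",
]


def write_stats_table(stats: Iterable["MicrostateStats"], path: str | Path) -> Path:
    """One row per subject × class; per-subject totals repeated on each row."""
    import pandas as pd

    rows = []
    for st in stats:
        for name in st.class_names:
            cs = st.per_class[name]
            rows.append(
                {
                    "subject_id": st.subject_id,
                    "method": st.method,
                    "class": name,
                    "gev": cs.gev,
                    "mean_duration_ms": cs.mean_duration_ms,
                    "occurrence_per_s": cs.occurrence_per_s,
                    "coverage": cs.coverage,
                    "n_segments": cs.n_segments,
                    "total_gev": st.total_gev,
                    "grand_mean_duration_ms": st.grand_mean_duration_ms,
                    "grand_mean_occurrence_per_s": st.grand_mean_occurrence_per_s,
                }
            )
    frame = pd.DataFrame(rows, columns=_STATS_COLUMNS)
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_stats_table(path: str | Path) -> list["MicrostateStats"]:
    import pandas as pd

    from .stats import ClassStats, MicrostateStats

    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_STATS_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: list[MicrostateStats] = []
    for (subject, method), grp in frame.groupby(["subject_id", "method"], sort=False):
        per_class = {}
        for _, row in grp.iterrows():
            per_class[str(row["class"])] = ClassStats(
                gev=float(row["gev"]),
                mean_duration_ms=float(row["mean_duration_ms"]),
                occurrence_per_s=float(row["occurrence_per_s"]),
                coverage=float(row["coverage"]),
                n_segments=int(row["n_segments"]),
            )
        out.append(
            MicrostateStats(
                subject_id=str(subject),
                method=str(method),
                class_names=tuple(per_class),
                per_class=per_class,
                total_gev=float(grp["total_gev"].iloc[0]),
                grand_mean_duration_ms=float(grp["grand_mean_duration_ms"].iloc[0]),
                grand_mean_occurrence_per_s=float(
                    grp["grand_mean_occurrence_per_s"].iloc[0]
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohort manifests


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    lines = ["subject_id\tgroup\tpath\tformat\tfs"]
    for subject, group, file_path, fmt in manifest.entries:
        lines.append(f"{subject}\t{group}\t{file_path}\t{fmt}\t{float(manifest.fs)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != ["subject_id", "group", "path", "format", "fs"]:
        raise FormatError(f"{path}: bad manifest header")
    entries = []
    fs = None
    for line in lines[1:]:
        if not line:
            continue
        subject, group, file_path, fmt, fs_text = line.split("\t")
        fs = float(fs_text)
        entry_path = Path(file_path)
        if not entry_path.is_absolute():
            entry_path = path.parent / entry_path
        if not entry_path.exists():
            raise FormatError(f"{path}: referenced file missing: {entry_path}")
        entries.append((subject, group, entry_path, fmt))
    if fs is None:
        raise FormatError(f"{path}: manifest lists no subjects")
    return CohortManifest(entries=entries, fs=fs)
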