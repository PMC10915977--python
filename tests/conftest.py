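"""Shared fixtures: synthetic templates, cohorts and on-disk format helpers.

All fixtures are generated programmatically and seeded; the heavier cohorts
are session-scoped so several tests can share one simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

import microstates as ms
from microstates.simulate import TEN_TWENTY_19


@pytest.fixture(scope="session")
def templates5() -> ms.TemplateSet:
    """Five orthogonal 19-channel generator templates labelled A-E."""
    return ms.make_templates(TEN_TWENTY_19, k=5, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject, 10-s cohort with class E boosted in the second group."""
    spec = ms.SyntheticCohortSpec(
        n_per_group={"control": 3, "poor_prognosis": 3},
        duration_s=10.0,
        seed=5,
        class_weights={"poor_prognosis": (1.0, 1.0, 1.0, 1.0, 1.5)},
    )
    return ms.simulate_cohort(spec)


@pytest.fixture
def rec_simple() -> ms.Recording:
    """Tiny deterministic 4-channel recording."""
    rng = np.random.default_rng(42)
    return ms.Recording(
        subject_id="simple",
        channel_names=("Fz", "Cz", "Pz", "Oz"),
        fs=250.0,
        data=rng.normal(0, 10, size=(4, 50)),
    )


def write_brainvision_fixture(directory, name, data_uv, fs, channel_names):
    """Write a minimal BrainVision triple (vhdr/vmrk/eeg, IEEE float32).

    Test-support writer only: the toolkit itself reads BrainVision through
    mne and never writes it.
    """
    import numpy as np

    vhdr = directory / f"{name}.vhdr"
    vmrk = directory / f"{name}.vmrk"
    eeg = directory / f"{name}.eeg"
    n_ch = len(channel_names)
    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={name}.eeg",
        f"MarkerFile={name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / fs:g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(channel_names, start=1):
        header.append(f"Ch{i}={ch},,1,µV")
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={name}.eeg\n"
        "[Marker Infos]\n"
        f"Mk1=New Segment,,1,1,0,00000000000000000000\n",
        encoding="utf-8",
    )
    interleaved = np.asarray(data_uv, dtype="<f4").T.reshape(-1)  # multiplexed
    eeg.write_bytes(interleaved.tobytes())
    return vhdr
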