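"""The shipped canonical A–E reference template set.

This is a *synthetic*, stylized construction of the five canonical resting
microstate topographies on the 19-channel 10-20 montage — not maps estimated
from any recorded cohort:

* **A** — left-posterior to right-anterior diagonal gradient;
* **B** — right-posterior to left-anterior diagonal gradient;
* **C** — posterior–anterior gradient;
* **D** — fronto-central focal maximum;
* **E** — frontal focal maximum.

It exists so that template matching, relabelling and the merged-class
book-keeping can run against a stable, documented reference without any
clinical data.  The packaged files ``data/reference_templates.tsv`` /
``.json`` are regenerated by ``scripts/make_reference_templates.py``.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .clustering import TemplateSet
from .io import read_template_set
from .simulate import TEN_TWENTY_19, electrode_positions
from .topography import TopographicMap

__all__ = ["build_canonical_maps", "load_reference_templates"]


def build_canonical_maps(montage: tuple[str, ...] = TEN_TWENTY_19) -> TemplateSet:
    """Construct the stylized canonical A–E maps analytically."""
    pos = electrode_positions(tuple(montage))
    x, y = pos[:, 0], pos[:, 1]
    patterns = {
        "A": (x + y) / np.sqrt(2),
        "B": (-x + y) / np.sqrt(2),
        "C": y,
        "D": np.exp(-(x**2 + (y - 0.2) ** 2) / 0.5),
        "E": np.exp(-(x**2 + (y - 0.9) ** 2) / 0.5),
    }
    maps = [
        TopographicMap(tuple(montage), values, label=label)
        for label, values in patterns.items()
    ]
    return TemplateSet(
        maps=maps,
        montage=tuple(montage),
        provenance={"kind": "reference", "generator": "synthetic-canonical"},
    )


def load_reference_templates() -> TemplateSet:
    """Load the packaged synthetic canonical A–E reference set."""
    data_dir = resources.files("microstates") / "data"
    with resources.as_file(data_dir / "reference_templates.tsv") as path:
        return read_template_set(path)
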