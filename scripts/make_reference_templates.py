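"""Regenerate the packaged synthetic canonical A-E reference template files."""

from pathlib import Path

from microstates.io import write_template_set
from microstates.reference import build_canonical_maps


def main() -> None:
    out_dir = Path(__file__).resolve().parents[1] / "src" / "microstates" / "data"
    out_dir.mkdir(exist_ok=True)
    write_template_set(build_canonical_maps(), out_dir / "reference_templates.tsv")
    print(f"wrote {out_dir / 'reference_templates.tsv'} (+ .json sidecar)")


if __name__ == "__main__":
    main()
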