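"""End-to-end pipeline: simulate/load → cluster → backfit → stats → compare →
evaluate, producing a deterministic artifact tree.

Stage layout under the output directory::

    data/       simulated cohort (when no input manifest is given)
    templates/  reference-group template set (canonically relabelled)
    labels/     per-subject label sequences
    stats/      per-subject statistics table + group comparisons
    eval/       prognosis evaluation summary (two-group cohorts)
    logs/       run log
    run.json    package version, config hash, seed

The reference-group templates are built by the two-level route — per-subject
AAHC on GFP peaks, then unweighted AAHC over the pooled subject templates —
and relabelled by matching against the shipped canonical A–E set (duplicate
matches get numeric suffixes, e.g. E1/E2, and are merged for statistics).
"""

from __future__ import annotations

import hashlib
import json
import logging
from configparser import ConfigParser
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np

from . import __version__
from .backfit import (
    backfit_conventional,
    backfit_individual,
    backfit_optimized,
)
from .clustering import (
    TemplateSet,
    aahc_cluster,
    aggregate_group_templates,
    match_templates,
)
from .errors import ConfigurationError, DataError
from .evaluate import SvmConfig, svm_crossval
from .io import (
    Recording,
    read_manifest,
    read_recording,
    write_label_sequence,
    write_stats_table,
    write_template_set,
)
from .reference import load_reference_templates
from .simulate import SyntheticCohortSpec, simulate_cohort
from .stats import compare_groups, summarize
from .topography import (
    TopographicMap,
    average_reference,
    detect_gfp_peaks,
    global_field_power,
)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

logger = logging.getLogger("microstates")


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run."""

    out_dir: str = "microstates_out"
    input_manifest: str = ""  # empty: simulate a cohort instead
    fs: float = 250.0
    k: int = 5
    method: str = "optimized"  # conventional | individual | optimized
    min_frames: int = 0  # 0: derive from fs (8 ms)
    smoothing: str = "split"  # split | drop | none
    polarity: str = "invariant"  # invariant | signed
    reference_group: str = "control"
    target_class: str = "E"
    exclude_boundary_runs: bool = False
    folds: int = 5
    seed: int = 0
    log_level: str = "info"
    simulate: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.method not in ("conventional", "individual", "optimized"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.smoothing not in ("split", "drop", "none"):
            raise ConfigurationError(f"unknown smoothing {self.smoothing!r}")
        if self.polarity not in ("invariant", "signed"):
            raise ConfigurationError(f"unknown polarity mode {self.polarity!r}")
        if self.log_level.lower() not in ("debug", "info", "warn", "warning"):
            raise ConfigurationError(f"unknown log level {self.log_level!r}")

    @property
    def smoothing_policy(self) -> str | None:
        return {"split": "split_to_neighbors", "drop": "drop", "none": None}[
            self.smoothing
        ]


_SIM_KEYS = {
    "fs": float,
    "duration_s": float,
    "k": int,
    "dwell_mean_ms": float,
    "amplitude_mean_uv": float,
    "noise_sd_uv": float,
    "polarity_flip_prob": float,
    "seed": int,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a key=value config file ([pipeline] + optional [simulate]).

    Unknown keys are rejected.  In [simulate], ``n_<group> = count`` sets the
    group sizes and ``weights_<group> = w1,w2,...`` the per-class onset
    weights.
    """
    parser = ConfigParser()
    read = parser.read(path)
    if not read:
        raise ConfigurationError(f"cannot read config file {path}")
    known = {f.name: f.type for f in dc_fields(PipelineConfig) if f.name != "simulate"}
    kwargs: dict = {}
    for section in parser.sections():
        if section not in ("pipeline", "simulate"):
            raise ConfigurationError(f"unknown config section [{section}]")
    if parser.has_section("pipeline"):
        for key, value in parser.items("pipeline"):
            if key not in known:
                raise ConfigurationError(f"unknown pipeline key {key!r}")
            if key in ("fs",):
                kwargs[key] = float(value)
            elif key in ("k", "min_frames", "folds", "seed"):
                kwargs[key] = int(value)
            elif key == "exclude_boundary_runs":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = value
    sim_kwargs: dict = {}
    n_per_group: dict[str, int] = {}
    class_weights: dict[str, tuple[float, ...]] = {}
    if parser.has_section("simulate"):
        for key, value in parser.items("simulate"):
            if key in _SIM_KEYS:
                sim_kwargs[key] = _SIM_KEYS[key](value)
            elif key.startswith("n_"):
                n_per_group[key[2:]] = int(value)
            elif key.startswith("weights_"):
                class_weights[key[8:]] = tuple(
                    float(x) for x in value.split(",")
                )
            else:
                raise ConfigurationError(f"unknown simulate key {key!r}")
    if n_per_group:
        sim_kwargs["n_per_group"] = n_per_group
    if class_weights:
        sim_kwargs["class_weights"] = class_weights
    if "seed" in kwargs and "seed" not in sim_kwargs:
        sim_kwargs["seed"] = kwargs["seed"]
    kwargs["simulate"] = SyntheticCohortSpec(**sim_kwargs)
    return PipelineConfig(**kwargs)


def _subject_templates(rec: Recording, k: int) -> TemplateSet:
    rec = average_reference(rec)
    gfp = detect_gfp_peaks(global_field_power(rec))
    if len(gfp.peak_indices) < k:
        raise DataError(
            f"subject {rec.subject_id}: {len(gfp.peak_indices)} GFP peaks < k={k}"
        )
    maps = [
        TopographicMap(rec.channel_names, rec.data[:, t]) for t in gfp.peak_indices
    ]
    return aahc_cluster(maps, k, weighting="gev")


def build_group_templates(recs: list[Recording], k: int) -> TemplateSet:
    """Two-level group templates: per-subject AAHC, then pooled re-clustering."""
    individual = [_subject_templates(rec, k) for rec in recs]
    if len(individual) == 1:
        return individual[0]
    return aggregate_group_templates(individual, k)


def relabel_canonically(templates: TemplateSet) -> TemplateSet:
    """Rename template maps after their best canonical match (A–E).

    Several maps matching one canonical class get numeric suffixes (E1, E2);
    downstream statistics merge them back into the single class.
    """
    canonical = load_reference_templates()
    mapping = match_templates(templates, canonical)
    counts: dict[str, int] = {}
    for _, ref, _ in mapping.pairs:
        counts[ref] = counts.get(ref, 0) + 1
    seen: dict[str, int] = {}
    new_maps = []
    for m, (_, ref, _) in zip(templates.maps, mapping.pairs):
        if counts[ref] > 1:
            seen[ref] = seen.get(ref, 0) + 1
            label = f"{ref}{seen[ref]}"
        else:
            label = ref
        new_maps.append(TopographicMap(templates.montage, m.values, label=label))
    return TemplateSet(
        maps=new_maps,
        montage=templates.montage,
        provenance={**templates.provenance, "canonical_relabel": True},
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the artifact directory.

    Deterministic for fixed config + seed.  Stage failures propagate as the
    toolkit's exceptions; the CLI maps them to exit codes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "logs").mkdir(exist_ok=True)
    handler = logging.FileHandler(out / "logs" / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(
        {"debug": logging.DEBUG, "info": logging.INFO}.get(
            config.log_level.lower(), logging.WARNING
        )
    )
    try:
        return _run_stages(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_stages(config: PipelineConfig, out: Path) -> Path:
    # --- acquire cohort
    if config.input_manifest:
        logger.info("loading cohort from %s", config.input_manifest)
        manifest = read_manifest(config.input_manifest)
        recordings = [
            read_recording(path, format=fmt, fs_override=manifest.fs,
                           subject_id=subject, group=group)
            for subject, group, path, fmt in manifest.entries
        ]
    else:
        logger.info("simulating cohort (seed %d)", config.simulate.seed)
        result = simulate_cohort(config.simulate, out_dir=out / "data")
        recordings = result.recordings

    groups: dict[str, list[Recording]] = {}
    for rec in recordings:
        groups.setdefault(rec.group or "all", []).append(rec)
    ref_group = config.reference_group
    if ref_group not in groups:
        ref_group = next(iter(groups))
        logger.warning("reference group not found; using %r", ref_group)

    # --- cluster
    (out / "templates").mkdir(exist_ok=True)
    reference = relabel_canonically(
        build_group_templates(groups[ref_group], config.k)
    )
    write_template_set(reference, out / "templates" / f"{ref_group}.tsv")
    canonical = load_reference_templates()
    merge_map = match_templates(reference, canonical)
    logger.info("reference templates: %s", ", ".join(reference.labels))

    polarity = config.polarity == "invariant"
    min_frames = config.min_frames or None
    smoothing = config.smoothing_policy

    # --- backfit + stats
    (out / "labels").mkdir(exist_ok=True)
    all_stats = []
    group_tpls: dict[str, TemplateSet] = {}
    for group_name, recs in groups.items():
        if config.method == "conventional":
            if group_name not in group_tpls:
                group_tpls[group_name] = relabel_canonically(
                    build_group_templates(recs, config.k)
                )
                write_template_set(
                    group_tpls[group_name], out / "templates" / f"{group_name}.tsv"
                )
            tpl = group_tpls[group_name]
            seqs = backfit_conventional(
                recs, tpl, min_frames=min_frames, smoothing=smoothing,
                polarity_invariant=polarity,
            )
            mm = match_templates(tpl, canonical)
            for rec, seq in zip(recs, seqs):
                write_label_sequence(seq, out / "labels" / f"{rec.subject_id}.tsv")
                all_stats.append(
                    summarize(rec, seq, tpl, merge_map=mm,
                              exclude_boundary_runs=config.exclude_boundary_runs)
                )
        elif config.method == "individual":
            for rec in recs:
                seq, own, own_seq, mapping = backfit_individual(
                    rec, reference, k_individual=config.k,
                    min_frames=min_frames, smoothing=smoothing,
                    polarity_invariant=polarity, return_details=True,
                )
                write_label_sequence(seq, out / "labels" / f"{rec.subject_id}.tsv")
                all_stats.append(
                    summarize(rec, own_seq, own, merge_map=mapping,
                              exclude_boundary_runs=config.exclude_boundary_runs)
                )
        else:  # optimized
            for rec in recs:
                seq = backfit_optimized(
                    rec, reference, min_frames=min_frames, smoothing=smoothing,
                    polarity_invariant=polarity,
                )
                write_label_sequence(seq, out / "labels" / f"{rec.subject_id}.tsv")
                all_stats.append(
                    summarize(rec, seq, reference, merge_map=merge_map,
                              exclude_boundary_runs=config.exclude_boundary_runs)
                )

    (out / "stats").mkdir(exist_ok=True)
    write_stats_table(all_stats, out / "stats" / "stats.tsv")

    # --- compare groups per class GEV
    subject_group = {rec.subject_id: rec.group or "all" for rec in recordings}
    comparisons = []
    if len(groups) >= 2:
        class_names = all_stats[0].class_names
        for cname in class_names:
            values = [st.per_class[cname].gev for st in all_stats]
            labels = [subject_group[st.subject_id] for st in all_stats]
            try:
                comparisons.append(
                    compare_groups(values, labels, variable=f"gev_{cname}")
                )
            except ConfigurationError as exc:
                logger.warning("skipping comparison for %s: %s", cname, exc)
        lines = ["variable\ttest\tstatistic\tp_raw\tcomparison\tp_adjusted"]
        for comp in comparisons:
            lines.append(
                f"{comp.variable}\t{comp.test}\t{comp.statistic!r}\t"
                f"{comp.p_value!r}\tomnibus\t"
            )
            for a, b, p_raw, p_adj in comp.pairwise:
                lines.append(
                    f"{comp.variable}\t{comp.test}\t\t{p_raw!r}\t{a}-vs-{b}\t{p_adj!r}"
                )
        (out / "stats" / "comparisons.tsv").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )

    # --- evaluate (two-group cohorts only)
    (out / "eval").mkdir(exist_ok=True)
    if len(groups) == 2:
        target = config.target_class
        names = list(groups)
        y = np.array(
            [0 if subject_group[st.subject_id] == names[0] else 1 for st in all_stats]
        )
        X = np.array([[st.per_class[target].gev] for st in all_stats])
        try:
            ev = svm_crossval(
                X, y, config=SvmConfig(folds=config.folds, seed=config.seed),
                feature_names=(f"gev_{target}",),
            )
            summary = {
                "feature_names": list(ev.feature_names),
                "model": ev.model,
                "auc": ev.auc,
                "sensitivity": ev.sensitivity,
                "specificity": ev.specificity,
                "accuracy": ev.accuracy,
                "folds": ev.folds,
                "seed": ev.seed,
                "positive_group": names[1],
            }
            (out / "eval" / "summary.json").write_text(
                json.dumps(summary, indent=2) + "\n", encoding="utf-8"
            )
        except ConfigurationError as exc:
            logger.warning("evaluation skipped: %s", exc)

    run_info = {
        "version": __version__,
        "seed": config.seed,
        "method": config.method,
        "config_hash": hashlib.sha256(
            json.dumps(
                {f.name: str(getattr(config, f.name)) for f in dc_fields(PipelineConfig)},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
    }
    (out / "run.json").write_text(json.dumps(run_info, indent=2) + "\n", encoding="utf-8")
    logger.info("pipeline complete: %s", out)
    return out
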