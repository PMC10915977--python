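"""Frame assignment, temporal smoothing and the three backfitting schemes."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microstates as ms
from microstates.backfit import UNASSIGNED, default_min_frames
from microstates.errors import ConfigurationError
from microstates.simulate import TEN_TWENTY_19
from microstates.topography import TopographicMap


def _brute_force_labels(rec, templates):
    """Independent per-frame argmax-|Pearson| oracle (loops + np.corrcoef)."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    labels = np.empty(rec.n_frames, dtype=int)
    for t in range(rec.n_frames):
        rs = []
        for m in templates.maps:
            rs.append(abs(np.corrcoef(data[:, t], m.values)[0, 1]))
        labels[t] = int(np.argmax(rs))
    return labels


def _exact_fit_recording(templates, labels, scales=None, seed=0):
    """Frames that are ±scaled copies of the labelled templates (no noise)."""
    rng = np.random.default_rng(seed)
    k = templates.k
    labels = np.asarray(labels)
    scales = rng.uniform(5, 20, size=len(labels)) if scales is None else scales
    signs = rng.choice([-1.0, 1.0], size=len(labels))
    data = templates.matrix[:, labels] * (signs * scales)[None, :]
    return ms.Recording("exact", templates.montage, 250.0, data)


def _seq(labels, fs=250.0, k=5):
    labels = np.asarray(labels, dtype=int)
    return ms.LabelSequence(
        labels=labels,
        corr=np.ones(len(labels)),
        fs=fs,
        method="optimized",
        class_names=tuple("ABCDE"[:k]),
    )


class TestAssignFrames:
    def test_exact_fit_recovers_truth(self, templates5):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 5, size=200)
        rec = _exact_fit_recording(templates5, truth, seed=1)
        seq = ms.assign_frames(rec, templates5)
        np.testing.assert_array_equal(seq.labels, truth)
        np.testing.assert_allclose(seq.corr, 1.0, atol=1e-9)

    def test_tie_goes_to_lower_template_index(self, templates5):
        # equal-weight mixture of templates 1 and 3 correlates equally with both
        mix = templates5.matrix[:, 1] + templates5.matrix[:, 3]
        data = np.column_stack([mix, mix])
        rec = ms.Recording("tie", templates5.montage, 250.0, data)
        seq = ms.assign_frames(rec, templates5)
        assert set(seq.labels.tolist()) == {1}

    def test_matches_brute_force_oracle_on_noise(self, templates5):
        rng = np.random.default_rng(7)
        rec = ms.Recording(
            "noise", templates5.montage, 250.0, rng.normal(size=(19, 300))
        )
        seq = ms.assign_frames(rec, templates5)
        np.testing.assert_array_equal(seq.labels, _brute_force_labels(rec, templates5))

    def test_min_corr_threshold_marks_unassigned(self, templates5):
        rng = np.random.default_rng(8)
        rec = ms.Recording(
            "noise", templates5.montage, 250.0, rng.normal(size=(19, 100))
        )
        seq = ms.assign_frames(rec, templates5, min_corr=2.0)  # unattainable
        assert np.all(seq.labels == UNASSIGNED)


class TestSmoothLabels:
    def test_short_run_between_same_neighbors_absorbed(self):
        seq = _seq([0] * 4 + [1] + [0] * 4)
        out = ms.smooth_labels(seq, min_frames=2)
        np.testing.assert_array_equal(out.labels, [0] * 9)

    def test_single_label_unchanged(self):
        seq = _seq([2] * 10)
        out = ms.smooth_labels(seq, min_frames=2)
        np.testing.assert_array_equal(out.labels, seq.labels)

    def test_boundary_run_absorbed_by_single_neighbor(self):
        seq = _seq([0] + [1] * 5)
        out = ms.smooth_labels(seq, min_frames=2)
        np.testing.assert_array_equal(out.labels, [1] * 6)

    def test_interior_run_split_at_midpoint(self):
        seq = _seq([0] * 3 + [2] * 2 + [1] * 3)
        out = ms.smooth_labels(seq, min_frames=3)
        np.testing.assert_array_equal(out.labels, [0, 0, 0, 0, 1, 1, 1, 1])

    def test_drop_policy_marks_unassigned(self):
        seq = _seq([0] * 4 + [1] + [0] * 4)
        out = ms.smooth_labels(seq, min_frames=2, policy="drop")
        np.testing.assert_array_equal(out.labels, [0] * 4 + [UNASSIGNED] + [0] * 4)

    def test_corr_values_unchanged(self):
        seq = _seq([0] * 4 + [1] + [0] * 4)
        seq.corr = np.linspace(0.1, 0.9, 9)
        out = ms.smooth_labels(seq, min_frames=2)
        np.testing.assert_array_equal(out.corr, seq.corr)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 4))
    @settings(max_examples=30, deadline=None)
    def test_no_new_class_and_all_runs_long_enough(self, seed, min_frames):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, size=rng.integers(5, 60))
        seq = _seq(labels, k=5)
        out = ms.smooth_labels(seq, min_frames=min_frames)
        assert set(out.labels.tolist()) <= set(labels.tolist())
        runs = out.runs()
        if len(runs) > 1:
            assert all(e - s >= min_frames for s, e, lab in runs if lab != UNASSIGNED)

    def test_min_frames_default_scales_with_fs(self):
        assert default_min_frames(250.0) == 2
        assert default_min_frames(500.0) == 4
        assert default_min_frames(100.0) == 1


class TestBackfitConventional:
    def test_single_template_labels_everything_zero(self, templates5):
        single = ms.TemplateSet(
            maps=[TopographicMap(templates5.montage, templates5.maps[0].values.copy(),
                                 label="only")],
            montage=templates5.montage,
        )
        rng = np.random.default_rng(3)
        rec = ms.Recording("r", templates5.montage, 250.0, rng.normal(size=(19, 50)))
        seqs = ms.backfit_conventional([rec], single)
        assert np.all(seqs[0].labels == 0)
        assert seqs[0].method == "conventional"

    def test_coverage_recovered_on_noise_free_simulation(self, templates5):
        spec = ms.SyntheticCohortSpec(duration_s=30.0, noise_sd_uv=0.0, seed=17)
        truth = ms.simulate_label_sequence(spec, "control", spec.n_frames, seed=17)
        rec, _ = ms.simulate_recording(templates5, truth, noise_sd_uv=0.0, seed=18)
        seq = ms.backfit_conventional([rec], templates5)[0]
        st_out = ms.duration_occurrence(seq)
        truth_cov = np.bincount(truth, minlength=5) / len(truth)
        for i, name in enumerate(st_out.class_names):
            assert st_out.per_class[name].coverage == pytest.approx(
                truth_cov[i], abs=0.02
            )


class TestBackfitIndividual:
    def test_one_to_one_matches_conventional_after_relabel(self, templates5):
        spec = ms.SyntheticCohortSpec(duration_s=20.0, seed=23, noise_sd_uv=1.0)
        truth = ms.simulate_label_sequence(spec, "control", spec.n_frames, seed=23)
        rec, _ = ms.simulate_recording(templates5, truth, noise_sd_uv=1.0, seed=24)
        seq, own, own_seq, mapping = ms.backfit_individual(
            rec, templates5, k_individual=5, return_details=True
        )
        # own templates recover the generators, so the mapping is one-to-one
        assert len({r for _, r, _ in mapping.pairs}) == 5
        assert all(r > 0.99 for _, _, r in mapping.pairs)
        conventional = ms.backfit_conventional([rec], own)[0]
        ref_index = {label: i for i, label in enumerate(templates5.labels)}
        translate = np.array(
            [ref_index[mapping.reference_label_for(label)] for label in own.labels]
        )
        np.testing.assert_array_equal(seq.labels, translate[conventional.labels])

    def test_merged_class_present_absent_class_zero(self, templates5):
        """Two own-templates mapping to one reference class merge; unmatched
        reference classes end up with zero coverage."""
        rng = np.random.default_rng(31)
        e = templates5.matrix[:, 4]
        mix = 0.93 * e + 0.37 * templates5.matrix[:, 3]  # still closest to E
        own_maps = [
            TopographicMap(templates5.montage, templates5.matrix[:, 0], label="m1"),
            TopographicMap(templates5.montage, templates5.matrix[:, 1], label="m2"),
            TopographicMap(templates5.montage, templates5.matrix[:, 2], label="m3"),
            TopographicMap(templates5.montage, e + rng.normal(0, 0.02, 19), label="m4"),
            TopographicMap(templates5.montage, mix, label="m5"),
        ]
        own = ms.TemplateSet(maps=own_maps, montage=templates5.montage)
        mapping = ms.match_templates(own, templates5)
        targets = [r for _, r, _ in mapping.pairs]
        assert targets.count("E") == 2 and "D" in mapping.unmatched_reference_labels
        truth = np.repeat(np.arange(5), 40)
        rec = _exact_fit_recording(own, truth, seed=32)
        seq = ms.backfit_individual(rec, templates5, k_individual=5)
        st_out = ms.duration_occurrence(seq)
        assert st_out.per_class["D"].coverage == 0.0

    def test_too_few_peaks_raises(self, templates5):
        rec = ms.Recording(
            "short", templates5.montage, 250.0,
            np.tile(templates5.matrix[:, :1], (1, 4)),
        )
        with pytest.raises(ConfigurationError, match="GFP peaks"):
            ms.backfit_individual(rec, templates5, k_individual=5)


class TestBackfitOptimized:
    def test_noise_free_accuracy_before_smoothing(self, templates5):
        spec = ms.SyntheticCohortSpec(duration_s=10.0, seed=41)
        truth = ms.simulate_label_sequence(spec, "control", spec.n_frames, seed=41)
        rec, _ = ms.simulate_recording(templates5, truth, noise_sd_uv=0.0, seed=42)
        seq = ms.backfit_optimized(rec, templates5, smoothing=None)
        np.testing.assert_array_equal(seq.labels, truth)

    def test_polarity_invariance_negated_recording(self, small_cohort):
        tpl = small_cohort.truth.templates
        rec = small_cohort.recordings[0]
        neg = ms.Recording(
            rec.subject_id, rec.channel_names, rec.fs, -rec.data, group=rec.group
        )
        seq = ms.backfit_optimized(rec, tpl)
        seq_neg = ms.backfit_optimized(neg, tpl)
        np.testing.assert_array_equal(seq.labels, seq_neg.labels)
        np.testing.assert_allclose(seq.corr, seq_neg.corr, atol=1e-12)

    def test_flipped_template_leaves_labels_unchanged(self, small_cohort):
        tpl = small_cohort.truth.templates
        flipped_maps = [
            TopographicMap(
                tpl.montage,
                (-1 if i == 2 else 1) * m.values,
                label=m.label,
            )
            for i, m in enumerate(tpl.maps)
        ]
        flipped = ms.TemplateSet(maps=flipped_maps, montage=tpl.montage)
        rec = small_cohort.recordings[1]
        np.testing.assert_array_equal(
            ms.backfit_optimized(rec, tpl).labels,
            ms.backfit_optimized(rec, flipped).labels,
        )

    def test_coincides_with_conventional_for_same_templates(self, small_cohort):
        tpl = small_cohort.truth.templates
        rec = small_cohort.recordings[2]
        opt = ms.backfit_optimized(rec, tpl)
        conv = ms.backfit_conventional([rec], tpl)[0]
        np.testing.assert_array_equal(opt.labels, conv.labels)

    def test_missing_generator_class_low_coverage(self, templates5):
        spec = ms.SyntheticCohortSpec(
            duration_s=20.0,
            seed=51,
            class_weights={"g": (1.0, 1.0, 1.0, 1.0, 0.0)},  # class E never occurs
        )
        truth = ms.simulate_label_sequence(spec, "g", spec.n_frames, seed=51)
        rec, _ = ms.simulate_recording(templates5, truth, noise_sd_uv=3.0, seed=52)
        seq = ms.backfit_optimized(rec, templates5)
        st_out = ms.duration_occurrence(seq)
        assert 0.0 <= st_out.per_class["E"].coverage < 0.05
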