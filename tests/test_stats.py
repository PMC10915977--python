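"""GEV, temporal statistics and group comparisons."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microstates as ms
from microstates.backfit import UNASSIGNED
from microstates.errors import ConfigurationError, DataError
from microstates.topography import TopographicMap


def _seq(labels, fs=250.0, names=("T1", "T2")):
    labels = np.asarray(labels, dtype=int)
    return ms.LabelSequence(
        labels=labels,
        corr=np.ones(len(labels)),
        fs=fs,
        method="optimized",
        class_names=tuple(names),
    )


@pytest.fixture
def worked_fixture():
    """Six frames on three channels against two orthogonal templates.

    The per-class GEV of this fixture was computed by hand with exact
    fractions: labels [T1,T1,T2,T1,T2,T1], GEV_T1 = 35/46, GEV_T2 = 15/92,
    total 85/92.
    """
    montage = ("c1", "c2", "c3")
    t1 = TopographicMap(montage, np.array([1.0, 0.0, -1.0]) / np.sqrt(2), label="T1")
    t2 = TopographicMap(montage, np.array([1.0, -2.0, 1.0]) / np.sqrt(6), label="T2")
    templates = ms.TemplateSet(maps=[t1, t2], montage=montage)
    frames = np.array(
        [
            [2.0, 0.0, -2.0],
            [-3.0, 0.0, 3.0],
            [1.0, -2.0, 1.0],
            [2.0, -1.0, -1.0],
            [0.0, 1.0, -1.0],
            [1.0, 1.0, -2.0],
        ]
    ).T
    rec = ms.Recording("worked", montage, 250.0, frames)
    return rec, templates


class TestGevPerClass:
    def test_hand_worked_fixture_exact(self, worked_fixture):
        rec, templates = worked_fixture
        seq = ms.assign_frames(rec, templates, method="optimized")
        np.testing.assert_array_equal(seq.labels, [0, 0, 1, 0, 1, 0])
        stats = ms.gev_per_class(rec, seq, templates)
        assert stats.per_class["T1"].gev == pytest.approx(
            float(Fraction(35, 46)), abs=1e-12
        )
        assert stats.per_class["T2"].gev == pytest.approx(
            float(Fraction(15, 92)), abs=1e-12
        )
        assert stats.total_gev == pytest.approx(float(Fraction(85, 92)), abs=1e-12)

    def test_noise_free_exact_fit_total_gev_one(self, templates5):
        rng = np.random.default_rng(61)
        truth = rng.integers(0, 5, size=500)
        scales = rng.uniform(5, 20, size=500)
        signs = rng.choice([-1.0, 1.0], size=500)
        data = templates5.matrix[:, truth] * (signs * scales)[None, :]
        rec = ms.Recording("exact", templates5.montage, 250.0, data)
        seq = ms.assign_frames(rec, templates5)
        stats = ms.gev_per_class(rec, seq, templates5)
        assert stats.total_gev == pytest.approx(1.0, abs=1e-9)
        # per-class GEV equals that class's share of total squared GFP
        gfp_sq = np.sum((data - data.mean(axis=0)) ** 2, axis=0)
        for i, name in enumerate(templates5.labels):
            share = gfp_sq[truth == i].sum() / gfp_sq.sum()
            assert stats.per_class[name].gev == pytest.approx(share, abs=1e-9)

    def test_frames_orthogonal_to_all_templates_give_zero(self):
        montage = ("c1", "c2", "c3", "c4")
        t1 = TopographicMap(montage, np.array([1.0, -1.0, 0.0, 0.0]), label="T1")
        t2 = TopographicMap(montage, np.array([0.0, 0.0, 1.0, -1.0]), label="T2")
        templates = ms.TemplateSet(maps=[t1, t2], montage=montage)
        ortho = np.array([1.0, 1.0, -1.0, -1.0])  # centered, ⟂ both templates
        data = np.column_stack([ortho, 2 * ortho, -ortho])
        rec = ms.Recording("orth", montage, 250.0, data)
        seq = _seq([0, 1, 0])
        stats = ms.gev_per_class(rec, seq, templates)
        assert stats.total_gev == pytest.approx(0.0, abs=1e-12)

    def test_sum_of_classes_equals_total(self, small_cohort):
        tpl = small_cohort.truth.templates
        rec = small_cohort.recordings[0]
        seq = ms.backfit_optimized(rec, tpl)
        stats = ms.gev_per_class(rec, seq, tpl)
        total = sum(stats.per_class[c].gev for c in stats.class_names)
        assert total == pytest.approx(stats.total_gev, abs=1e-10)
        assert 0.0 <= stats.total_gev <= 1.0

    def test_invariant_to_global_rescaling(self, small_cohort):
        tpl = small_cohort.truth.templates
        rec = small_cohort.recordings[1]
        seq = ms.backfit_optimized(rec, tpl)
        stats = ms.gev_per_class(rec, seq, tpl)
        scaled = ms.Recording(
            rec.subject_id, rec.channel_names, rec.fs, rec.data * 7.3, group=rec.group
        )
        stats_scaled = ms.gev_per_class(scaled, seq, tpl)
        for c in stats.class_names:
            assert stats_scaled.per_class[c].gev == pytest.approx(
                stats.per_class[c].gev, abs=1e-12
            )

    def test_merge_map_sums_numerators_exactly(self, templates5):
        """Merging split classes must equal the sum of their pre-merge GEVs."""
        ref = ms.load_reference_templates()
        mapping = ms.match_templates(templates5, ref)
        rng = np.random.default_rng(71)
        rec = ms.Recording(
            "m", templates5.montage, 250.0, rng.normal(size=(19, 400))
        )
        seq = ms.assign_frames(rec, templates5)
        plain = ms.gev_per_class(rec, seq, templates5)
        merged = ms.gev_per_class(rec, seq, templates5, merge_map=mapping)
        for ref_label in merged.class_names:
            expected = sum(
                plain.per_class[c].gev
                for c, r, _ in mapping.pairs
                if r == ref_label
            )
            assert merged.per_class[ref_label].gev == pytest.approx(
                expected, abs=1e-15
            )
        assert merged.total_gev == pytest.approx(plain.total_gev, abs=1e-12)

    def test_frame_count_mismatch_raises(self, worked_fixture):
        rec, templates = worked_fixture
        with pytest.raises(DataError, match="frame count"):
            ms.gev_per_class(rec, _seq([0, 1]), templates)

    def test_unassigned_frames_stay_in_denominator(self, worked_fixture):
        rec, templates = worked_fixture
        seq_full = ms.assign_frames(rec, templates)
        labels = seq_full.labels.copy()
        labels[0] = UNASSIGNED
        seq_missing = ms.LabelSequence(
            labels=labels, corr=seq_full.corr, fs=250.0,
            method="optimized", class_names=templates.labels,
        )
        full = ms.gev_per_class(rec, seq_full, templates)
        part = ms.gev_per_class(rec, seq_missing, templates)
        assert part.total_gev < full.total_gev  # numerator shrank, denominator fixed


class TestDurationOccurrence:
    def test_hand_counted_example(self):
        stats = ms.duration_occurrence(_seq([0, 0, 1, 1, 1, 0], fs=250.0))
        a, b = stats.per_class["T1"], stats.per_class["T2"]
        assert a.n_segments == 2
        assert a.mean_duration_ms == pytest.approx(1.5 / 250 * 1000)  # runs 2 and 1
        assert b.n_segments == 1
        assert b.mean_duration_ms == pytest.approx(12.0)
        assert a.coverage == pytest.approx(0.5)
        assert b.coverage == pytest.approx(0.5)

    def test_single_class_constants(self):
        stats = ms.duration_occurrence(_seq([0] * 250, fs=250.0))
        c = stats.per_class["T1"]
        assert c.mean_duration_ms == pytest.approx(1000.0)
        assert c.occurrence_per_s == pytest.approx(1.0)
        assert c.coverage == pytest.approx(1.0)

    def test_absent_class_reports_zeros(self):
        stats = ms.duration_occurrence(_seq([0] * 10))
        c = stats.per_class["T2"]
        assert (c.mean_duration_ms, c.occurrence_per_s, c.coverage) == (0.0, 0.0, 0.0)
        assert c.n_segments == 0

    def test_empty_sequence_raises(self):
        with pytest.raises(DataError):
            ms.duration_occurrence(
                ms.LabelSequence(
                    labels=np.empty(0, dtype=int), corr=np.empty(0), fs=250.0,
                    method="optimized", class_names=("A",),
                )
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_occurrence_duration_coverage_identity(self, seed):
        """With boundary runs excluded, occurrence × duration(s) = coverage."""
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 4, size=rng.integers(10, 200))
        seq = _seq(labels, fs=250.0, names=("A", "B", "C", "D"))
        stats = ms.duration_occurrence(seq, exclude_boundary_runs=True)
        for c in stats.class_names:
            cs = stats.per_class[c]
            product = cs.occurrence_per_s * cs.mean_duration_ms / 1000.0
            assert product == pytest.approx(cs.coverage, abs=1e-9)

    def test_boundary_exclusion_drops_edge_runs(self):
        stats_all = ms.duration_occurrence(_seq([0, 0, 1, 0, 0]))
        stats_excl = ms.duration_occurrence(
            _seq([0, 0, 1, 0, 0]), exclude_boundary_runs=True
        )
        assert stats_all.per_class["T1"].n_segments == 2
        assert stats_excl.per_class["T1"].n_segments == 0
        assert stats_excl.per_class["T2"].n_segments == 1


class TestCompareGroups:
    def test_identical_values_anova_f_zero_p_one(self):
        values = [5.0] * 9
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        result = ms.compare_groups(values, groups, test="one_way_anova")
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_separated_gaussians_tiny_p(self):
        rng = np.random.default_rng(81)
        values = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        groups = ["a"] * 50 + ["b"] * 50
        result = ms.compare_groups(values, groups, test="t_test")
        assert result.p_value < 1e-10

    def test_bonferroni_multiplies_by_pair_count(self):
        rng = np.random.default_rng(82)
        values = np.concatenate(
            [rng.normal(0, 1, 20), rng.normal(0.8, 1, 20), rng.normal(2, 1, 20)]
        )
        groups = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        result = ms.compare_groups(values, groups, test="one_way_anova")
        assert len(result.pairwise) == 3
        for _, _, p_raw, p_adj in result.pairwise:
            assert p_adj == pytest.approx(min(1.0, p_raw * 3))

    def test_auto_uses_kruskal_for_heavy_tailed_data(self):
        rng = np.random.default_rng(83)
        values = np.concatenate(
            [np.exp(rng.normal(0, 2.5, 60)), np.exp(rng.normal(0, 2.5, 60))]
        )
        groups = ["a"] * 60 + ["b"] * 60
        result = ms.compare_groups(values, groups, test="auto")
        assert result.test == "kruskal_wallis"

    def test_auto_uses_t_test_for_two_normal_groups(self):
        rng = np.random.default_rng(84)
        values = np.concatenate([rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)])
        groups = ["a"] * 40 + ["b"] * 40
        result = ms.compare_groups(values, groups, test="auto")
        assert result.test == "t_test"

    def test_chi_squared_on_categorical(self):
        values = ["m"] * 18 + ["f"] * 2 + ["m"] * 5 + ["f"] * 15
        groups = ["a"] * 20 + ["b"] * 20
        result = ms.compare_groups(values, groups, test="chi_squared")
        assert result.test == "chi_squared"
        assert result.p_value < 0.01

    def test_degenerate_group_named_in_error(self):
        with pytest.raises(ConfigurationError, match="tiny"):
            ms.compare_groups([1.0, 2.0, 3.0], ["a", "a", "tiny"], test="t_test")


class TestSummarize:
    def test_combines_gev_and_temporal_fields(self, small_cohort):
        tpl = small_cohort.truth.templates
        rec = small_cohort.recordings[0]
        seq = ms.backfit_optimized(rec, tpl)
        stats = ms.summarize(rec, seq, tpl)
        for c in stats.class_names:
            cs = stats.per_class[c]
            assert np.isfinite(cs.gev)
            assert np.isfinite(cs.mean_duration_ms)
        assert 0.0 < stats.total_gev <= 1.0
        assert stats.grand_mean_duration_ms > 0
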