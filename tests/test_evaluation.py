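"""Dice coefficient, LOOCV predictability, threshold selection and
reproducibility/correlation analytics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from funcatlas import (
    InsufficientDataError,
    SubjectLabelSet,
    UndefinedCorrelationError,
    VolumeGrid,
    compare_to_reference_atlas,
    dice,
    incremental_subject_analysis,
    loocv_predictability,
    reproducibility_dice,
    roi_size_table,
    select_threshold,
    size_dice_correlation,
    summarize_by_threshold,
    triangulated_grid_mesh,
)

sets = st.sets(st.integers(0, 50), max_size=30)


class TestDice:
    def test_identical_sets(self):
        assert dice({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_disjoint_sets(self):
        assert dice({1, 2}, {3, 4}) == 0.0

    def test_partial_overlap(self):
        assert dice({1, 2, 3, 4}, {3, 4, 5, 6, 7, 8}) == pytest.approx(0.4)

    def test_both_empty(self):
        assert dice(set(), set()) == 0.0

    @given(a=sets, b=sets)
    def test_symmetric_and_bounded(self, a, b):
        d = dice(a, b)
        assert d == dice(b, a)
        assert 0.0 <= d <= 1.0


class TestLOOCV:
    def test_hand_computed_three_fold(self, toy_cohort):
        _, subjects = toy_cohort
        rec = loocv_predictability(subjects, "A")
        got = {
            (row.fold, round(row.threshold, 3)): row.dice
            for row in rec.itertuples()
        }
        expected = {
            ("s1", 0.0): 4 / 9, ("s1", 0.5): 4 / 9, ("s1", 1.0): 2 / 7,
            ("s2", 0.0): 8 / 11, ("s2", 0.5): 8 / 11, ("s2", 1.0): 2 / 5,
            ("s3", 0.0): 6 / 10, ("s3", 0.5): 6 / 10, ("s3", 1.0): 2 / 6,
        }
        assert got.keys() == expected.keys()
        for key, val in expected.items():
            assert got[key] == pytest.approx(val), key

    def test_identical_subjects_give_dice_one(self):
        subjects = [
            SubjectLabelSet(f"s{i}", "t", {"A": frozenset({1, 2, 3})})
            for i in range(4)
        ]
        rec = loocv_predictability(subjects, "A")
        assert (rec["dice"] == 1.0).all()

    def test_disjoint_subjects_give_dice_zero(self):
        subjects = [
            SubjectLabelSet(f"s{i}", "t", {"A": frozenset({10 * i, 10 * i + 1})})
            for i in range(3)
        ]
        rec = loocv_predictability(subjects, "A")
        assert (rec["dice"] == 0.0).all()

    def test_folds_skip_subjects_without_roi(self):
        subjects = [
            SubjectLabelSet("s0", "t", {"A": frozenset({1})}),
            SubjectLabelSet("s1", "t", {"A": frozenset({1})}),
            SubjectLabelSet("s2", "t", {}),
        ]
        rec = loocv_predictability(subjects, "A")
        assert set(rec["fold"]) == {"s0", "s1"}

    def test_single_holder_raises(self):
        subjects = [
            SubjectLabelSet("s0", "t", {"A": frozenset({1})}),
            SubjectLabelSet("s1", "t", {}),
        ]
        with pytest.raises(InsufficientDataError):
            loocv_predictability(subjects, "A")

    def test_summary_matches_raw_recomputation(self, toy_cohort):
        _, subjects = toy_cohort
        rec = loocv_predictability(subjects, "A")
        summary = summarize_by_threshold(rec)
        for row in summary.itertuples():
            vals = rec.loc[rec["threshold"] == row.threshold, "dice"].to_numpy()
            assert row.mean_dice == pytest.approx(vals.mean())
            assert row.se == pytest.approx(vals.std(ddof=1) / np.sqrt(len(vals)))


class TestSelectThreshold:
    def _records(self, means_by_t):
        rows = [
            ("A", "", t, f"f{i}", v)
            for t, vals in means_by_t.items()
            for i, v in enumerate(vals)
        ]
        return pd.DataFrame(rows, columns=["roi", "group_factor", "threshold", "fold", "dice"])

    def test_argmax(self):
        rec = self._records({0.1: [0.3, 0.3], 0.4: [0.5, 0.5]})
        assert select_threshold(rec) == 0.4

    def test_tie_goes_to_lower_threshold(self):
        rec = self._records({0.2: [0.5], 0.6: [0.5]})
        assert select_threshold(rec) == 0.2

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            select_threshold(self._records({}))


class TestIncremental:
    def test_identical_subjects_dice_one_at_every_n(self):
        subjects = [
            SubjectLabelSet(f"s{i}", "t", {"A": frozenset({1, 2, 3, 4})})
            for i in range(6)
        ]
        table = incremental_subject_analysis(subjects, "A", [2, 3, 5], reps=3, seed=0)
        assert (table["mean_dice"] == 1.0).all()
        assert list(table["n"]) == [2, 3, 5]

    def test_two_disjoint_subjects_dice_zero(self):
        subjects = [
            SubjectLabelSet("s0", "t", {"A": frozenset({1})}),
            SubjectLabelSet("s1", "t", {"A": frozenset({2})}),
        ]
        table = incremental_subject_analysis(subjects, "A", [2], reps=2, seed=0)
        assert table.loc[0, "mean_dice"] == 0.0

    def test_oversized_subset_raises(self):
        subjects = [
            SubjectLabelSet(f"s{i}", "t", {"A": frozenset({1})}) for i in range(3)
        ]
        with pytest.raises(InsufficientDataError):
            incremental_subject_analysis(subjects, "A", [4], reps=1, seed=0)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        subjects = [
            SubjectLabelSet(
                f"s{i}", "t",
                {"A": frozenset(int(e) for e in rng.choice(30, size=8, replace=False))},
            )
            for i in range(6)
        ]
        t1 = incremental_subject_analysis(subjects, "A", [2, 4], reps=4, seed=9)
        t2 = incremental_subject_analysis(subjects, "A", [2, 4], reps=4, seed=9)
        pd.testing.assert_frame_equal(t1, t2)


class TestReproducibility:
    def test_identical_runs_give_one(self):
        runs = {"s0": [{1, 2, 3}] * 3}
        table = reproducibility_dice(runs)
        assert table.loc[0, "mean_dice"] == 1.0

    def test_mean_of_pairwise_dice(self):
        # pairs give 0.5, 0.25, 0.75 -> mean 0.5
        runs = {"s0": [{0, 1, 2, 3}, {2, 3, 4, 5}, {3, 4, 5, 6}]}
        assert reproducibility_dice(runs).loc[0, "mean_dice"] == pytest.approx(0.5)

    def test_region_mask_applied_before_dice(self):
        runs = {"s0": [{1, 2, 99}, {1, 2, 98}]}
        assert reproducibility_dice(runs, region_mask={1, 2}).loc[0, "mean_dice"] == 1.0

    def test_single_run_raises(self):
        with pytest.raises(InsufficientDataError):
            reproducibility_dice({"s0": [{1}]})


class TestAtlasComparison:
    def test_reference_equal_to_all_subjects(self):
        subjects = [
            SubjectLabelSet(f"s{i}", "t", {"A": frozenset({1, 2})}) for i in range(3)
        ]
        result = compare_to_reference_atlas(subjects, "A", {1, 2})
        assert (result.per_subject["dice"] == 1.0).all()
        assert result.mean == 1.0 and result.se == 0.0

    def test_disjoint_reference(self):
        subjects = [SubjectLabelSet("s0", "t", {"A": frozenset({1})})]
        result = compare_to_reference_atlas(subjects, "A", {9})
        assert result.mean == 0.0


class TestSizeDice:
    def test_perfect_positive_and_negative_correlation(self):
        sizes = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        up = {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4}
        down = {"a": 0.4, "b": 0.3, "c": 0.2, "d": 0.1}
        assert size_dice_correlation(sizes, up) == pytest.approx(1.0)
        assert size_dice_correlation(sizes, down) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            size_dice_correlation(
                {"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 0.1, "b": 0.2, "c": 0.3}
            )

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            size_dice_correlation({"a": 1.0, "b": 2.0}, {"a": 0.1, "b": 0.2})


class TestROISizes:
    def test_volume_size_is_voxel_count(self):
        space = VolumeGrid((4, 4, 4))
        subjects = [
            SubjectLabelSet("s0", "t", {"A": frozenset({0, 1, 2})}),
            SubjectLabelSet("s1", "t", {"A": frozenset({0})}),
        ]
        (rec,) = roi_size_table(subjects, space)
        assert rec.mean_area == 2.0

    def test_surface_size_uses_vertex_area_shares(self):
        mesh = triangulated_grid_mesh(3, 3, spacing_mm=1.0)
        all_vertices = frozenset(range(mesh.n_vertices))
        subjects = [SubjectLabelSet("s0", "t", {"A": all_vertices})]
        (rec,) = roi_size_table(subjects, mesh)
        assert rec.mean_area == pytest.approx(4.0)  # 2x2 cells of 1 mm^2
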