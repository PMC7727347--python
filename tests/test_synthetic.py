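"""Synthetic cohort generator: reproducibility, degeneracy and calibration."""

import numpy as np
import pytest

from funcatlas import (
    CohortConfig,
    ConfigurationError,
    GroundTruthAtlas,
    RoiSpec,
    VolumeGrid,
    dice,
    generate_cohort,
    generate_responses,
    generate_run_maps,
    geodesic_ball,
    triangulated_grid_mesh,
    winner_map,
)


@pytest.fixture(scope="module")
def two_roi_truth():
    grid = VolumeGrid((14, 14, 6))
    rois = {
        "alpha": RoiSpec(grid.to_linear((4, 4, 3)), 2, "faces"),
        "beta": RoiSpec(grid.to_linear((9, 9, 3)), 2, "bodies"),
    }
    return GroundTruthAtlas(grid, rois)


class TestGroundTruth:
    def test_overlapping_nominal_regions_rejected(self):
        grid = VolumeGrid((8, 8, 8))
        rois = {
            "a": RoiSpec(grid.to_linear((3, 3, 3)), 2, "x"),
            "b": RoiSpec(grid.to_linear((3, 4, 3)), 2, "y"),
        }
        with pytest.raises(ConfigurationError):
            GroundTruthAtlas(grid, rois)

    def test_geodesic_ball_is_l1_ball_on_grid(self):
        grid = VolumeGrid((9, 9, 9))
        center = grid.to_linear((4, 4, 4))
        ball = geodesic_ball(grid, center, 2)
        for e, d in ball.items():
            ijk = np.array(grid.to_ijk(e))
            assert int(np.abs(ijk - 4).sum()) == d

    def test_conditions_derived_from_preferences(self, two_roi_truth):
        assert two_roi_truth.conditions == ("faces", "bodies")


class TestGenerateCohort:
    def test_degenerate_config_reproduces_truth(self, two_roi_truth):
        cfg = CohortConfig(
            n_subjects=3, jitter_sd=0, size_sd=0, presence_prob=1.0, seed=0
        )
        cohort = generate_cohort(two_roi_truth, cfg)
        for subj in cohort:
            for name, spec in two_roi_truth.rois.items():
                truth_ball = set(
                    geodesic_ball(two_roi_truth.space, spec.seed_element, spec.radius)
                )
                assert subj.rois[name] == truth_ball

    def test_bit_reproducible(self, two_roi_truth):
        cfg = CohortConfig(n_subjects=5, jitter_sd=1.0, seed=33)
        c1 = generate_cohort(two_roi_truth, cfg)
        c2 = generate_cohort(two_roi_truth, cfg)
        assert [s.rois for s in c1] == [s.rois for s in c2]

    def test_presence_counts_near_binomial_expectation(self, two_roi_truth):
        cfg = CohortConfig(n_subjects=20, presence_prob=0.5, jitter_sd=0,
                           size_sd=0, seed=4)
        cohort = generate_cohort(two_roi_truth, cfg)
        for roi in two_roi_truth.rois:
            count = sum(roi in s.rois for s in cohort)
            # 99.99% binomial interval for n=20, p=0.5
            assert 2 <= count <= 18

    def test_large_jitter_destroys_overlap(self, two_roi_truth):
        cfg = CohortConfig(n_subjects=6, jitter_sd=8.0, size_sd=0,
                           presence_prob=1.0, seed=9)
        cohort = generate_cohort(two_roi_truth, cfg)
        pair_dice = [
            dice(cohort[i].rois["alpha"], cohort[j].rois["alpha"])
            for i in range(6)
            for j in range(i + 1, 6)
        ]
        assert np.mean(pair_dice) < 0.25

    def test_within_subject_rois_disjoint_under_jitter(self, two_roi_truth):
        cfg = CohortConfig(n_subjects=8, jitter_sd=3.0, size_sd=1.0,
                           presence_prob=1.0, seed=12)
        for subj in generate_cohort(two_roi_truth, cfg):
            rois = list(subj.rois.values())
            for i in range(len(rois)):
                for j in range(i + 1, len(rois)):
                    assert not (rois[i] & rois[j])

    def test_surface_cohort_generation(self):
        mesh = triangulated_grid_mesh(12, 12)
        rois = {
            "a": RoiSpec(2 * 12 + 6, 2, "x"),   # row 2, col 6
            "b": RoiSpec(9 * 12 + 6, 2, "y"),   # row 9, col 6
        }
        truth = GroundTruthAtlas(mesh, rois, space_id="mesh")
        cfg = CohortConfig(n_subjects=4, jitter_sd=1.0, presence_prob=1.0, seed=1)
        cohort = generate_cohort(truth, cfg)
        assert len(cohort) == 4
        assert all(s.rois for s in cohort)


class TestGenerateResponses:
    def test_noise_free_winner_is_preferred_condition(self, two_roi_truth):
        cfg = CohortConfig(n_subjects=2, jitter_sd=0, size_sd=0, presence_prob=1.0,
                           selectivity_effect=1.0, noise_sd=0.0, seed=0)
        cohort = generate_cohort(two_roi_truth, cfg)
        responses = generate_responses(cohort, two_roi_truth, cfg)
        subj, resp = cohort[0], responses[0]
        winners = winner_map(resp, subj.rois["beta"])
        assert set(winners.values()) == {"bodies"}

    def test_reproducible_from_seed(self, two_roi_truth):
        cfg = CohortConfig(n_subjects=2, seed=5)
        cohort = generate_cohort(two_roi_truth, cfg)
        r1 = generate_responses(cohort, two_roi_truth, cfg)
        r2 = generate_responses(cohort, two_roi_truth, cfg)
        for a, b in zip(r1, r2):
            for e in a.amplitudes:
                assert np.array_equal(a.amplitudes[e], b.amplitudes[e])


class TestGenerateRunMaps:
    def test_zero_noise_gives_identical_runs(self, two_roi_truth):
        cfg = CohortConfig(n_subjects=3, jitter_sd=0, size_sd=0, presence_prob=1.0,
                           seed=0)
        cohort = generate_cohort(two_roi_truth, cfg)
        runs = generate_run_maps(cohort, cfg, n_runs=3, run_noise_sd=0.0)
        for subj in cohort:
            full = frozenset(e for roi in subj.rois.values() for e in roi)
            assert runs[subj.subject_id] == [full] * 3

    def test_noise_shrinks_run_overlap(self, two_roi_truth):
        cfg = CohortConfig(n_subjects=4, jitter_sd=0, size_sd=0, presence_prob=1.0,
                           seed=3)
        cohort = generate_cohort(two_roi_truth, cfg)
        means = []
        for sd in (0.25, 2.0):
            runs = generate_run_maps(cohort, cfg, n_runs=3, run_noise_sd=sd)
            pair = []
            for subj_runs in runs.values():
                pair += [
                    dice(subj_runs[i], subj_runs[j])
                    for i in range(3)
                    for j in range(i + 1, 3)
                ]
            means.append(np.mean(pair))
        assert means[0] > means[1]
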