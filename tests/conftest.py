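import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from funcatlas import SubjectLabelSet, VolumeGrid, triangulated_grid_mesh

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def grid3() -> VolumeGrid:
    return VolumeGrid((3, 3, 3))


@pytest.fixture(scope="session")
def small_mesh():
    return triangulated_grid_mesh(6, 6)


@pytest.fixture()
def toy_cohort():
    """Three subjects with hand-checkable partial overlaps on a 10-element
    line of voxels (10x1x1 grid)."""
    space = VolumeGrid((10, 1, 1))
    subjects = [
        SubjectLabelSet("s1", "toy", {"A": frozenset({0, 1, 2, 3})}),
        SubjectLabelSet("s2", "toy", {"A": frozenset({2, 3, 4, 5})}),
        SubjectLabelSet("s3", "toy", {"A": frozenset({3, 4, 5, 6})}),
    ]
    return space, subjects


def random_label_sets(rng: np.random.Generator, n_subjects, n_elements, rois=("A",)):
    """Random disjoint per-subject ROI sets for oracle checks."""
    subjects = []
    for s in range(n_subjects):
        pool = rng.permutation(n_elements)
        out, start = {}, 0
        for roi in rois:
            size = int(rng.integers(1, max(2, n_elements // (2 * len(rois)))))
            out[roi] = frozenset(int(e) for e in pool[start : start + size])
            start += size
        subjects.append(SubjectLabelSet(f"s{s}", "rand", out))
    return subjects
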