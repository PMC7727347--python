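"""Per-ROI probabilistic group maps from multi-subject label data.

A probabilistic map assigns each surface vertex or voxel the fraction of
subjects whose functionally defined region (fROI) contains it. The
denominator is the number of subjects in which the fROI could be defined at
all — not the cohort size — so a probability of 1 always means "every
subject who has this region has it here".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import EmptyROIError

__all__ = [
    "SubjectLabelSet",
    "ProbabilisticMap",
    "compute_probabilistic_map",
    "threshold_map",
    "filter_rois_by_prevalence",
]


@dataclass(frozen=True)
class SubjectLabelSet:
    """One subject's binary ROI membership in a shared space.

    ``rois`` maps ROI name to the set of element indices the subject's fROI
    occupies; fROIs that could not be defined in this subject are simply
    missing keys. Within one subject an element may belong to at most one
    ROI.
    """

    subject_id: str
    space_id: str
    rois: Mapping[str, frozenset[int]]

    def __post_init__(self) -> None:
        frozen = {name: frozenset(elems) for name, elems in self.rois.items()}
        object.__setattr__(self, "rois", frozen)
        seen: dict[int, str] = {}
        for name in sorted(frozen):
            for e in frozen[name]:
                if e in seen:
                    raise ValueError(
                        f"subject {self.subject_id!r}: element {e} in both "
                        f"{seen[e]!r} and {name!r}"
                    )
                seen[e] = name


@dataclass(frozen=True)
class ProbabilisticMap:
    """Group probability map for one ROI.

    ``values[e]`` is the fraction of contributing subjects whose fROI
    contains element ``e``; every value is ``k / denominator`` for an
    integer ``1 <= k <= denominator``. Elements no subject contributed are
    absent.
    """

    roi_name: str
    denominator: int
    values: Mapping[int, float]
    space_id: str = ""
    subject_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))
        if self.denominator < 1:
            raise ValueError("denominator must be >= 1")

    @property
    def support(self) -> frozenset[int]:
        return frozenset(self.values)


def compute_probabilistic_map(
    subjects: Sequence[SubjectLabelSet], roi: str
) -> ProbabilisticMap:
    """Build the group probability map of ``roi`` across subjects.

    For each element, the number of subjects sharing it in the fROI divided
    by the total number of subjects possessing the fROI.

    Raises
    ------
    EmptyROIError
        If no subject possesses ``roi``.
    """
    holders = [s for s in subjects if roi in s.rois]
    if not holders:
        raise EmptyROIError(f"ROI {roi!r} absent in all {len(subjects)} subjects")
    counts: dict[int, int] = {}
    for s in holders:
        for e in s.rois[roi]:
            counts[e] = counts.get(e, 0) + 1
    n = len(holders)
    return ProbabilisticMap(
        roi_name=roi,
        denominator=n,
        values={e: k / n for e, k in counts.items()},
        space_id=holders[0].space_id,
        subject_ids=tuple(s.subject_id for s in holders),
    )


def threshold_map(pmap: ProbabilisticMap, threshold: float) -> frozenset[int]:
    """Elements with probability >= ``threshold``.

    A threshold of 0 denotes the liberal "at least one subject" map, i.e.
    the full support — identical to thresholding at ``1/denominator``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if threshold == 0.0:
        return pmap.support
    return frozenset(e for e, v in pmap.values.items() if v >= threshold)


def filter_rois_by_prevalence(
    subjects: Sequence[SubjectLabelSet], min_fraction: float = 0.5
) -> list[str]:
    """ROIs defined in strictly more than ``min_fraction`` of all subjects.

    The default 0.5 implements the atlas-inclusion rule that a region must
    be identifiable in more than half the cohort. The comparison is strict,
    and the denominator is the full cohort size (not per-ROI).
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    n = len(subjects)
    names = sorted({r for s in subjects for r in s.rois})
    return [
        name
        for name in names
        if sum(name in s.rois for s in subjects) > min_fraction * n
    ]
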