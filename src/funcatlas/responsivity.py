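"""Leave-subject-out winner-map responsivity of atlas fROIs.

For each subject an MPM atlas is built from the other N-1 subjects; within
each atlas fROI, every element of the left-out subject is assigned the
stimulus condition evoking its strongest response amplitude (the "winner").
The fraction of elements won by each condition — in particular by the
fROI's own preferred category — quantifies how functionally specific the
atlas is in data it has never seen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, MissingDataError
from .mpm import build_mpm
from .probmaps import SubjectLabelSet, compute_probabilistic_map
from .errors import EmptyROIError

__all__ = [
    "ResponseMap",
    "WinnerSummary",
    "winner_map",
    "summarize_winners",
    "max_responsivity_analysis",
    "ResponsivityResult",
]


@dataclass(frozen=True)
class ResponseMap:
    """Per-element condition-response amplitudes for one subject.

    ``amplitudes[e]`` is a vector with one amplitude per condition, in the
    order given by ``conditions``. Units are arbitrary (e.g. GLM betas);
    only the argmax matters downstream.
    """

    subject_id: str
    conditions: tuple[str, ...]
    amplitudes: Mapping[int, np.ndarray]

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        amps = {}
        k = len(self.conditions)
        for e, vec in self.amplitudes.items():
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (k,):
                raise ValueError(
                    f"element {e}: amplitude vector of length {arr.shape} "
                    f"does not match {k} conditions"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"element {e}: non-finite amplitude")
            amps[int(e)] = arr
        object.__setattr__(self, "amplitudes", amps)


@dataclass(frozen=True)
class WinnerSummary:
    """Percent of a fROI's elements won by each condition (sums to 100)."""

    roi: str
    percentages: Mapping[str, float]


def winner_map(
    response: ResponseMap, elements: AbstractSet[int]
) -> dict[int, str]:
    """Assign each element the condition with its maximal amplitude.

    Exact amplitude ties are broken by condition order (the first-listed
    condition wins), keeping the assignment deterministic.

    Raises
    ------
    MissingDataError
        If an element has no amplitude vector (e.g. outside the subject's
        brain coverage).
    """
    out = {}
    for e in sorted(elements):
        vec = response.amplitudes.get(e)
        if vec is None:
            raise MissingDataError(
                f"subject {response.subject_id!r}: no amplitudes at element {e}"
            )
        out[e] = response.conditions[int(np.argmax(vec))]
    return out


def summarize_winners(
    roi: str, winners: Mapping[int, str], conditions: Sequence[str]
) -> WinnerSummary:
    """Tally a winner map into per-condition percentages of the fROI."""
    n = len(winners)
    if n == 0:
        raise InsufficientDataError(f"fROI {roi!r} has no elements to tally")
    counts = {c: 0 for c in conditions}
    for cond in winners.values():
        counts[cond] += 1
    return WinnerSummary(roi, {c: 100.0 * counts[c] / n for c in conditions})


class ResponsivityResult(NamedTuple):
    #: tidy per-fold table: subject, roi, condition, percent (NaN if the
    #: leave-one-out fROI was empty for that fold)
    per_fold: pd.DataFrame
    #: across-subject mean percent per (roi, condition)
    mean: pd.DataFrame


def max_responsivity_analysis(
    subjects: Sequence[SubjectLabelSet],
    responses: Sequence[ResponseMap],
    threshold: float,
    space,
    mode: str | None = None,
    rois: Sequence[str] | None = None,
) -> ResponsivityResult:
    """Leave-subject-out maximum responsivity of every atlas fROI.

    For each left-out subject an MPM is built from the other N-1 subjects
    at ``threshold``; within each MPM fROI the left-out subject's winner
    map is tallied into condition percentages. Folds where a fROI is empty
    in the leave-one-out MPM are recorded as NaN.
    """
    if len(subjects) < 2:
        raise InsufficientDataError("need >= 2 subjects for leave-one-out MPMs")
    resp_by_subject = {r.subject_id: r for r in responses}
    missing = [s.subject_id for s in subjects if s.subject_id not in resp_by_subject]
    if missing:
        raise MissingDataError(f"no response map for subjects {missing}")
    conditions = responses[0].conditions

    rows = []
    for left in subjects:
        others = [s for s in subjects if s is not left]
        roi_names = (
            list(rois)
            if rois is not None
            else sorted({r for s in others for r in s.rois})
        )
        pmaps = []
        for name in roi_names:
            try:
                pmaps.append(compute_probabilistic_map(others, name))
            except EmptyROIError:
                continue
        atlas = build_mpm(pmaps, threshold, space, mode)
        response = resp_by_subject[left.subject_id]
        for name in roi_names:
            elems = atlas.roi_elements(name)
            if not elems:
                for c in conditions:
                    rows.append((left.subject_id, name, c, float("nan")))
                continue
            summary = summarize_winners(
                name, winner_map(response, elems), conditions
            )
            for c in conditions:
                rows.append((left.subject_id, name, c, summary.percentages[c]))

    per_fold = pd.DataFrame(rows, columns=["subject", "roi", "condition", "percent"])
    mean = (
        per_fold.groupby(["roi", "condition"], sort=True)["percent"]
        .mean()
        .reset_index()
    )
    return ResponsivityResult(per_fold, mean)
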