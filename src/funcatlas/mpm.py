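"""Maximum probability maps: a unique, non-overlapping ROI tiling.

Probabilistic group maps of neighboring fROIs overlap along their borders.
The maximum probability map (MPM) resolves this by assigning every element
claimed by more than one thresholded map to the ROI with the highest
probability there. Exact probability ties are broken by averaging each tied
ROI's probabilities over an expanding graph neighborhood of the element
until one ROI pulls ahead. Finally, stray elements with no same-label
company nearby are reassigned to the runner-up ROI present in their
immediate neighborhood, or dropped to background.

Surface and volume variants differ only in the cleanup search radius:
graph distance <= 3 on meshes, <= 1 (the 6-connected shell) on voxel grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ConfigurationError
from .geometry import SurfaceMesh, VolumeGrid, neighbors_within_degree
from .probmaps import ProbabilisticMap, threshold_map

__all__ = ["MaxProbabilityMap", "build_mpm", "resolve_tie", "cleanup_isolated"]

#: Cap on the neighbor-averaging degree before the lexicographic fallback.
TIE_DEGREE_MAX = 10

_TOL = 1e-12


@dataclass(frozen=True)
class MaxProbabilityMap:
    """Non-overlapping tiling: element index -> exactly one ROI label."""

    space_id: str
    labels: Mapping[int, str]
    threshold_used: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", dict(self.labels))

    def roi_elements(self, roi: str) -> frozenset[int]:
        return frozenset(e for e, name in self.labels.items() if name == roi)

    @property
    def roi_names(self) -> list[str]:
        return sorted(set(self.labels.values()))


def _infer_mode(space) -> str:
    if isinstance(space, VolumeGrid):
        return "volume"
    if isinstance(space, SurfaceMesh):
        return "surface"
    raise ConfigurationError(
        f"cannot infer mode for space of type {type(space).__name__}; pass mode="
    )


def _cleanup_radius(mode: str) -> int:
    if mode == "surface":
        return 3
    if mode == "volume":
        return 1
    raise ConfigurationError(f"unknown mode {mode!r}; expected 'surface' or 'volume'")


def resolve_tie(
    element: int,
    tied_rois: Sequence[str],
    pmaps: Mapping[str, ProbabilisticMap] | Sequence[ProbabilisticMap],
    space,
    d_max: int = TIE_DEGREE_MAX,
) -> str:
    """Break an exact probability tie at ``element`` between ``tied_rois``.

    For degree d = 1, 2, ... compute each tied ROI's mean probability over
    the elements within graph distance <= d (elements outside a map's
    support contribute 0), and return the ROI with the strictly highest
    mean at the first degree where it is unique. Perfectly symmetric
    configurations that survive to ``d_max`` fall back to the
    lexicographically smallest ROI name, keeping the result deterministic.
    """
    by_name = _as_name_map(pmaps)
    candidates = sorted(tied_rois)
    for d in range(1, d_max + 1):
        hood = neighbors_within_degree(space, element, d)
        if not hood:
            break
        means = {
            roi: sum(by_name[roi].values.get(e, 0.0) for e in hood) / len(hood)
            for roi in candidates
        }
        best = max(means.values())
        leaders = [roi for roi in candidates if means[roi] >= best - _TOL]
        if len(leaders) == 1:
            return leaders[0]
        candidates = leaders  # drop ROIs already strictly dominated
    return candidates[0]


def build_mpm(
    pmaps: Sequence[ProbabilisticMap],
    threshold: float,
    space,
    mode: str | None = None,
) -> MaxProbabilityMap:
    """Tile thresholded probability maps into a unique-label MPM.

    Pipeline: (1) threshold each map; (2) give contested elements to the
    ROI with the highest probability; (3) break exact ties with
    :func:`resolve_tie`; (4) apply :func:`cleanup_isolated`.
    """
    mode = mode or _infer_mode(space)
    _cleanup_radius(mode)  # validates mode early
    names = [p.roi_name for p in pmaps]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate ROI names in pmaps: {names}")
    space_ids = {p.space_id for p in pmaps if p.space_id}
    if len(space_ids) > 1:
        raise ConfigurationError(f"pmaps span multiple spaces: {sorted(space_ids)}")
    by_name = {p.roi_name: p for p in pmaps}

    claims: dict[int, list[str]] = {}
    for pmap in pmaps:
        for e in threshold_map(pmap, threshold):
            if not 0 <= e < space.n_elements:
                raise ConfigurationError(
                    f"map {pmap.roi_name!r} references element {e} outside space"
                )
            claims.setdefault(e, []).append(pmap.roi_name)

    labels: dict[int, str] = {}
    for e in sorted(claims):
        rois = claims[e]
        if len(rois) == 1:
            labels[e] = rois[0]
            continue
        probs = {roi: by_name[roi].values[e] for roi in rois}
        best = max(probs.values())
        tied = sorted(roi for roi, v in probs.items() if v >= best - _TOL)
        labels[e] = tied[0] if len(tied) == 1 else resolve_tie(e, tied, by_name, space)

    mpm = MaxProbabilityMap(
        space_id=space_ids.pop() if space_ids else "",
        labels=labels,
        threshold_used=threshold,
    )
    return cleanup_isolated(mpm, pmaps, space, mode)


def cleanup_isolated(
    mpm: MaxProbabilityMap,
    pmaps: Mapping[str, ProbabilisticMap] | Sequence[ProbabilisticMap],
    space,
    mode: str | None = None,
) -> MaxProbabilityMap:
    """Reassign or drop labeled elements isolated from their own ROI.

    An element violates the connectivity rule when no element of the same
    label lies within the rescue radius (graph distance <= 3 on surfaces,
    <= 1 on volumes). Violators are detected on a frozen snapshot and
    reassigned simultaneously: each goes to the highest-probability other
    ROI that both claims it with probability > 0 and has same-label
    elements in the violator's immediate (distance-1) neighborhood; if no
    ROI satisfies both conditions the element becomes background. The scan
    repeats until no violators remain (bounded by the element count).
    """
    mode = mode or _infer_mode(space)
    radius = _cleanup_radius(mode)
    by_name = _as_name_map(pmaps)
    labels = dict(mpm.labels)

    for _ in range(len(labels) + 1):
        violators = [
            e
            for e, roi in labels.items()
            if not any(
                labels.get(n) == roi
                for n in neighbors_within_degree(space, e, radius)
            )
        ]
        if not violators:
            break
        snapshot = dict(labels)
        for e in violators:
            current = snapshot[e]
            immediate_labels = {
                snapshot[n]
                for n in neighbors_within_degree(space, e, 1)
                if n in snapshot
            }
            candidates = sorted(
                (
                    (roi, pmap.values[e])
                    for roi, pmap in by_name.items()
                    if roi != current and pmap.values.get(e, 0.0) > 0.0
                ),
                key=lambda rv: (-rv[1], rv[0]),
            )
            new_label = next(
                (roi for roi, _ in candidates if roi in immediate_labels), None
            )
            if new_label is None:
                del labels[e]
            else:
                labels[e] = new_label

    return MaxProbabilityMap(
        space_id=mpm.space_id, labels=labels, threshold_used=mpm.threshold_used
    )


def _as_name_map(
    pmaps: Mapping[str, ProbabilisticMap] | Sequence[ProbabilisticMap],
) -> Mapping[str, ProbabilisticMap]:
    if isinstance(pmaps, Mapping):
        return pmaps
    return {p.roi_name: p for p in pmaps}
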