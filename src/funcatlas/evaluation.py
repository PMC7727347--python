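"""Dice-coefficient analytics for atlas predictability and reproducibility.

The Dice coefficient DSC = 2|I ∩ G| / (|I| + |G|) measures the overlap
between a left-out subject's individual fROI *I* and a thresholded group
probabilistic fROI *G* built from the remaining subjects. This module
implements the coefficient itself, the leave-one-out cross-validated (LOOCV)
predictability sweep across group-map thresholds, global threshold
selection, the incremental-subject-count analysis, within-subject
run-to-run reproducibility, comparison of individual fROIs against a fixed
reference atlas region, and the ROI-size vs. Dice correlation.

All tabular results are tidy :class:`pandas.DataFrame` objects with one
Dice value per row, so every summary statistic can be recomputed from the
raw records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import AbstractSet, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedCorrelationError
from .geometry import SurfaceMesh, VolumeGrid
from .probmaps import SubjectLabelSet, compute_probabilistic_map, threshold_map

__all__ = [
    "dice",
    "loocv_predictability",
    "summarize_by_threshold",
    "select_threshold",
    "incremental_subject_analysis",
    "reproducibility_dice",
    "compare_to_reference_atlas",
    "AtlasComparison",
    "roi_size_table",
    "ROISizeRecord",
    "size_dice_correlation",
]

RECORD_COLUMNS = ["roi", "group_factor", "threshold", "fold", "dice"]


def dice(a: AbstractSet[int], b: AbstractSet[int]) -> float:
    """Dice similarity 2|a ∩ b| / (|a| + |b|); 0 when both sets are empty."""
    denom = len(a) + len(b)
    if denom == 0:
        return 0.0
    return 2.0 * len(a & b) / denom


def loocv_predictability(
    subjects: Sequence[SubjectLabelSet],
    roi: str,
    thresholds: Sequence[float] | None = None,
    group_factor: str = "",
) -> pd.DataFrame:
    """Leave-one-out predictability of a group map for one ROI.

    Folds iterate over the subjects that possess the ROI. In each fold the
    group map G is built from the other holders and thresholded; the record
    is the Dice coefficient between G and the left-out subject's fROI I.

    When ``thresholds`` is None the per-fold grid is ``k/(N-1)`` for
    ``k = 0..N-1`` (N holders): from the liberal at-least-one-subject map
    (threshold 0) up to requiring all N-1 remaining subjects.
    """
    holders = [s for s in subjects if roi in s.rois]
    if len(holders) < 2:
        raise InsufficientDataError(
            f"ROI {roi!r} present in {len(holders)} subject(s); need >= 2"
        )
    n = len(holders)
    rows = []
    for left in holders:
        others = [s for s in holders if s is not left]
        pmap = compute_probabilistic_map(others, roi)
        grid = thresholds if thresholds is not None else [k / (n - 1) for k in range(n)]
        individual = left.rois[roi]
        for t in grid:
            group = threshold_map(pmap, t)
            rows.append((roi, group_factor, float(t), left.subject_id, dice(individual, group)))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def summarize_by_threshold(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of Dice per threshold, across all records.

    SE is the sample standard deviation divided by sqrt(number of folds).
    """
    grouped = records.groupby("threshold")["dice"]
    out = grouped.agg(mean_dice="mean", n="size")
    out["se"] = grouped.std(ddof=1).fillna(0.0) / np.sqrt(out["n"])
    return out.reset_index()


def select_threshold(records: pd.DataFrame) -> float:
    """Threshold with the highest grand-mean Dice (ties go to the lower one).

    The grand mean pools every record — all ROIs, group factors and folds —
    yielding one Dice value per threshold level.
    """
    if len(records) == 0:
        raise InsufficientDataError("no Dice records provided")
    means = records.groupby("threshold")["dice"].mean().sort_index()
    return float(means.index[np.argmax(means.to_numpy())])


def incremental_subject_analysis(
    subjects: Sequence[SubjectLabelSet],
    roi: str,
    n_range: Sequence[int],
    reps: int,
    seed: int,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """LOOCV Dice as a function of the number of subjects in the atlas.

    For each n, ``reps`` random size-n subsets of the ROI's holders are
    drawn without replacement (seeded); each subset is scored by its mean
    LOOCV Dice at the fixed ``threshold``. Returns per-n mean and SE across
    repetitions.
    """
    holders = [s for s in subjects if roi in s.rois]
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_range:
        if n < 2 or n > len(holders):
            raise InsufficientDataError(
                f"subset size {n} infeasible with {len(holders)} holders"
            )
        rep_means = []
        for _ in range(reps):
            idx = sorted(rng.choice(len(holders), size=n, replace=False))
            subset = [holders[i] for i in idx]
            rec = loocv_predictability(subset, roi, thresholds=[threshold])
            rep_means.append(rec["dice"].mean())
        rep_means = np.asarray(rep_means)
        se = rep_means.std(ddof=1) / math.sqrt(reps) if reps > 1 else 0.0
        rows.append((int(n), float(rep_means.mean()), float(se)))
    return pd.DataFrame(rows, columns=["n", "mean_dice", "se"])


def reproducibility_dice(
    run_maps: Mapping[str, Sequence[AbstractSet[int]]],
    region_mask: AbstractSet[int] | None = None,
) -> pd.DataFrame:
    """Within-subject run-to-run overlap: mean pairwise Dice per subject.

    Each subject contributes >= 2 thresholded contrast maps (runs); maps
    are intersected with ``region_mask`` (e.g. a ventral or lateral
    occipito-temporal anatomical expanse) before computing Dice over every
    unordered run pair. Thresholding (t > 0 liberal, or a fixed t cutoff)
    happens upstream.
    """
    rows = []
    for subject in sorted(run_maps):
        runs = [frozenset(r) for r in run_maps[subject]]
        if len(runs) < 2:
            raise InsufficientDataError(
                f"subject {subject!r} has {len(runs)} run(s); need >= 2"
            )
        if region_mask is not None:
            runs = [r & frozenset(region_mask) for r in runs]
        pair_dices = [
            dice(runs[i], runs[j])
            for i in range(len(runs))
            for j in range(i + 1, len(runs))
        ]
        rows.append((subject, len(runs), float(np.mean(pair_dices))))
    return pd.DataFrame(rows, columns=["subject", "n_runs", "mean_dice"])


class AtlasComparison(NamedTuple):
    per_subject: pd.DataFrame
    mean: float
    se: float


def compare_to_reference_atlas(
    subjects: Sequence[SubjectLabelSet],
    roi: str,
    reference_region: AbstractSet[int],
) -> AtlasComparison:
    """Dice between each subject's fROI and a fixed reference atlas region."""
    reference = frozenset(reference_region)
    rows = [
        (s.subject_id, roi, dice(s.rois[roi], reference))
        for s in subjects
        if roi in s.rois
    ]
    df = pd.DataFrame(rows, columns=["subject", "roi", "dice"])
    if len(df) == 0:
        return AtlasComparison(df, float("nan"), float("nan"))
    vals = df["dice"].to_numpy()
    se = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
    return AtlasComparison(df, float(vals.mean()), float(se))


@dataclass(frozen=True)
class ROISizeRecord:
    roi: str
    group_factor: str
    mean_area: float  # mm² on surfaces, element count on volumes


def roi_size_table(
    subjects: Sequence[SubjectLabelSet],
    space,
    group_factor: str = "",
) -> list[ROISizeRecord]:
    """Mean fROI size per ROI across the subjects possessing it.

    On a :class:`SurfaceMesh` with coordinates, size is surface area in mm²
    (per-vertex area shares summed over the fROI); otherwise it is the
    element count (voxels on a :class:`VolumeGrid`).
    """
    if isinstance(space, SurfaceMesh) and space.coordinates is not None:
        shares = space.vertex_areas()
        measure = lambda elems: float(sum(shares[e] for e in elems))  # noqa: E731
    elif isinstance(space, VolumeGrid):
        measure = lambda elems: float(len(elems))  # noqa: E731
    else:
        measure = lambda elems: float(len(elems))  # noqa: E731
    names = sorted({r for s in subjects for r in s.rois})
    records = []
    for name in names:
        sizes = [measure(s.rois[name]) for s in subjects if name in s.rois]
        records.append(ROISizeRecord(name, group_factor, float(np.mean(sizes))))
    return records


def size_dice_correlation(
    sizes: Sequence[ROISizeRecord] | Mapping[str, float],
    dices: Mapping[str, float],
) -> float:
    """Pearson correlation between mean fROI size and mean Dice across ROIs.

    Pairs are matched by ROI name; at least three paired observations are
    required, and either variable having zero variance makes the
    correlation undefined.
    """
    if isinstance(sizes, Mapping):
        size_by_roi = dict(sizes)
    else:
        size_by_roi = {rec.roi: rec.mean_area for rec in sizes}
    common = sorted(set(size_by_roi) & set(dices))
    if len(common) < 3:
        raise InsufficientDataError(
            f"need >= 3 paired ROI observations, got {len(common)}"
        )
    x = np.array([size_by_roi[r] for r in common])
    y = np.array([dices[r] for r in common])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in size or Dice values")
    return float(sps.pearsonr(x, y).statistic)
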