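"""Synthetic multi-subject cohorts with the variability structure the
atlas pipeline assumes.

A :class:`GroundTruthAtlas` fixes a set of disjoint "true" fROIs on a
shared space (graph-geodesic balls around seed elements). A cohort draws,
per subject and ROI: presence (Bernoulli), a spatially jittered seed, and a
perturbed radius — emulating that not every region can be identified in
every subject, that regions drift across subjects after alignment, and
that their sizes vary. Category-selective response amplitudes and noisy
repeated-run contrast maps are generated on top, so every pipeline stage
(probability maps, MPM tiling, LOOCV Dice, winner maps, reproducibility)
can be exercised end to end without any external data.

Default cohort parameters mirror the study conditions the pipeline is
meant for: 19 subjects, four stimulus categories (faces, bodies, places,
characters), regions present in most but not all subjects, and a
selectivity effect of three noise standard deviations.

All randomness flows from a single integer seed via
:class:`numpy.random.SeedSequence`, so identical inputs give bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, GeometryError
from .geometry import SurfaceMesh, VolumeGrid
from .probmaps import SubjectLabelSet
from .responsivity import ResponseMap

__all__ = [
    "RoiSpec",
    "GroundTruthAtlas",
    "CohortConfig",
    "geodesic_ball",
    "generate_cohort",
    "generate_responses",
    "generate_run_maps",
    "default_volume_atlas",
]

#: Stimulus categories of a standard functional localizer.
DEFAULT_CONDITIONS = ("faces", "bodies", "places", "characters")

_JITTER_RETRIES = 8


@dataclass(frozen=True)
class RoiSpec:
    """One true region: seed element, nominal radius (graph steps), and the
    stimulus condition it prefers."""

    seed_element: int
    radius: int
    preferred_condition: str

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")


@dataclass(frozen=True)
class GroundTruthAtlas:
    """The cohort's true functional topology on a shared space."""

    space: SurfaceMesh | VolumeGrid
    rois: Mapping[str, RoiSpec]
    space_id: str = "synthetic"
    conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "rois", dict(self.rois))
        if not self.conditions:
            prefs = []
            for name in sorted(self.rois):
                c = self.rois[name].preferred_condition
                if c not in prefs:
                    prefs.append(c)
            object.__setattr__(self, "conditions", tuple(prefs))
        claimed: dict[int, str] = {}
        for name in sorted(self.rois):
            spec = self.rois[name]
            for e in geodesic_ball(self.space, spec.seed_element, spec.radius):
                if e in claimed:
                    raise ConfigurationError(
                        f"true regions {claimed[e]!r} and {name!r} overlap at "
                        f"element {e}; nominal regions must be disjoint"
                    )
                claimed[e] = name
            if spec.preferred_condition not in (self.conditions or (spec.preferred_condition,)):
                raise ConfigurationError(
                    f"ROI {name!r} prefers unknown condition "
                    f"{spec.preferred_condition!r}"
                )


@dataclass(frozen=True)
class CohortConfig:
    """Between-subject variability parameters (defaults = study conditions).

    jitter_sd and size_sd are in graph/voxel steps; selectivity_effect is
    an amplitude offset for a region's preferred condition, expressed in
    units of the amplitude noise SD (noise_sd defaults to 1 so the two
    coincide numerically).
    """

    n_subjects: int = 19
    jitter_sd: float = 1.5
    size_sd: float = 1.0
    presence_prob: float = 0.85
    selectivity_effect: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValueError("presence_prob must be in [0, 1]")
        if min(self.jitter_sd, self.size_sd, self.noise_sd) < 0:
            raise ValueError("SDs must be >= 0")


def geodesic_ball(space, seed_element: int, radius: int) -> dict[int, int]:
    """Breadth-first ball: element -> graph distance from the seed (<= radius)."""
    if not 0 <= seed_element < space.n_elements:
        raise GeometryError(f"seed element {seed_element} outside space")
    depth = {int(seed_element): 0}
    frontier = [int(seed_element)]
    for d in range(1, radius + 1):
        nxt = []
        for v in frontier:
            for u in space.neighbors(v):
                if u not in depth:
                    depth[u] = d
                    nxt.append(u)
        if not nxt:
            break
        frontier = nxt
    return depth


def _jitter_seed_volume(
    grid: VolumeGrid, seed_element: int, jitter_sd: float, rng: np.random.Generator
) -> int:
    ijk = np.array(grid.to_ijk(seed_element))
    for _ in range(_JITTER_RETRIES):
        step = np.rint(rng.normal(0.0, jitter_sd, size=3)).astype(int)
        if grid.contains_ijk(ijk + step):
            return grid.to_linear(ijk + step)
    clamped = np.clip(ijk + step, 0, np.array(grid.shape) - 1)
    return grid.to_linear(clamped)


def _jitter_seed_surface(
    mesh: SurfaceMesh, seed_element: int, jitter_sd: float, rng: np.random.Generator
) -> int:
    # Meshes carry no displacement frame in-scope, so an isotropic Gaussian
    # step becomes a random walk of |round(N(0, sd))| adjacency steps.
    n_steps = int(abs(round(rng.normal(0.0, jitter_sd))))
    v = int(seed_element)
    for _ in range(n_steps):
        nbrs = sorted(mesh.neighbors(v))
        if not nbrs:
            break
        v = nbrs[rng.integers(len(nbrs))]
    return v


def generate_cohort(
    truth: GroundTruthAtlas, config: CohortConfig
) -> list[SubjectLabelSet]:
    """Draw a cohort of subject label sets from the ground truth.

    Per subject and ROI (sorted name order for reproducibility): the ROI is
    present with probability ``presence_prob``; if present, a region is
    grown as a geodesic ball around the jittered seed with radius
    ``max(1, nominal + round(N(0, size_sd)))``. Where a subject's regions
    would overlap, each contested element goes to the ROI whose jittered
    seed is nearest in graph distance (ties to the lexicographically
    smaller name), so each element belongs to at most one ROI.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    space = truth.space
    is_volume = isinstance(space, VolumeGrid)
    subjects = []
    for s in range(config.n_subjects):
        depth_maps: dict[str, dict[int, int]] = {}
        for name in sorted(truth.rois):
            spec = truth.rois[name]
            present = rng.random() < config.presence_prob
            if not present:
                continue
            if is_volume:
                seed = _jitter_seed_volume(space, spec.seed_element, config.jitter_sd, rng)
            else:
                seed = _jitter_seed_surface(space, spec.seed_element, config.jitter_sd, rng)
            radius = max(1, int(spec.radius + round(rng.normal(0.0, config.size_sd))))
            depth_maps[name] = geodesic_ball(space, seed, radius)
        # nearest-jittered-seed resolution of within-subject overlaps
        owner: dict[int, tuple[int, str]] = {}
        for name in sorted(depth_maps):
            for e, d in depth_maps[name].items():
                best = owner.get(e)
                if best is None or (d, name) < best:
                    owner[e] = (d, name)
        rois: dict[str, set[int]] = {name: set() for name in depth_maps}
        for e, (_, name) in owner.items():
            rois[name].add(e)
        subjects.append(
            SubjectLabelSet(
                subject_id=f"sub-{s:02d}",
                space_id=truth.space_id,
                rois={n: frozenset(v) for n, v in rois.items() if v},
            )
        )
    return subjects


def generate_responses(
    subject_maps: Sequence[SubjectLabelSet],
    truth: GroundTruthAtlas,
    config: CohortConfig,
) -> list[ResponseMap]:
    """Category-selective response amplitudes with additive Gaussian noise.

    Every element of the space gets, per condition, an amplitude drawn from
    N(0, noise_sd); elements inside a subject's true region additionally
    receive ``selectivity_effect`` on that region's preferred condition.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    conditions = truth.conditions
    k = len(conditions)
    cond_index = {c: i for i, c in enumerate(conditions)}
    n = truth.space.n_elements
    out = []
    for subj in subject_maps:
        amps = rng.normal(0.0, config.noise_sd, size=(n, k))
        for name in sorted(subj.rois):
            spec = truth.rois.get(name)
            if spec is None:
                continue
            j = cond_index[spec.preferred_condition]
            for e in subj.rois[name]:
                amps[e, j] += config.selectivity_effect
        out.append(
            ResponseMap(
                subject_id=subj.subject_id,
                conditions=conditions,
                amplitudes={e: amps[e] for e in range(n)},
            )
        )
    return out


def generate_run_maps(
    subject_maps: Sequence[SubjectLabelSet],
    config: CohortConfig,
    n_runs: int = 3,
    contrast: float = 1.0,
    run_noise_sd: float | None = None,
    threshold: float = 0.5,
) -> dict[str, list[frozenset[int]]]:
    """Noisy repeated-run contrast maps per subject (for reproducibility Dice).

    Each run perturbs the subject's underlying contrast (``contrast`` at
    every element of the subject's regions) with independent
    N(0, run_noise_sd) noise and keeps elements exceeding ``threshold``.
    With zero noise all runs equal the subject's map; growing noise drives
    the run-pair overlap toward the random baseline.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    sd = config.noise_sd if run_noise_sd is None else run_noise_sd
    out: dict[str, list[frozenset[int]]] = {}
    for subj in subject_maps:
        elems = sorted(e for roi in subj.rois.values() for e in roi)
        runs = []
        for _ in range(n_runs):
            noise = rng.normal(0.0, sd, size=len(elems)) if sd > 0 else np.zeros(len(elems))
            runs.append(
                frozenset(
                    e for e, z in zip(elems, noise) if contrast + z > threshold
                )
            )
        out[subj.subject_id] = runs
    return out


def default_volume_atlas(
    shape: tuple[int, int, int] = (20, 20, 20)
) -> GroundTruthAtlas:
    """A compact volumetric ground truth with eight category-selective
    regions spread over the grid, two per stimulus category.

    Seeds sit at fixed fractional grid positions spaced so the nominal
    regions (radius 3-4 voxel geodesic balls) are disjoint, echoing the
    mosaic of face-, body-, place- and character-selective patches in
    occipito-temporal cortex.
    """
    grid = VolumeGrid(shape)
    ni, nj, nk = shape

    def at(fi: float, fj: float, fk: float) -> int:
        return grid.to_linear(
            (int(round(fi * (ni - 1))), int(round(fj * (nj - 1))), int(round(fk * (nk - 1))))
        )

    rois = {
        "mFus-faces": RoiSpec(at(0.25, 0.25, 0.30), 3, "faces"),
        "pFus-faces": RoiSpec(at(0.25, 0.70, 0.30), 3, "faces"),
        "OTS-bodies": RoiSpec(at(0.70, 0.25, 0.30), 4, "bodies"),
        "LOS-bodies": RoiSpec(at(0.70, 0.72, 0.30), 3, "bodies"),
        "CoS-places": RoiSpec(at(0.25, 0.25, 0.75), 4, "places"),
        "TOS-places": RoiSpec(at(0.25, 0.72, 0.75), 3, "places"),
        "pOTS-characters": RoiSpec(at(0.70, 0.25, 0.75), 3, "characters"),
        "IOS-characters": RoiSpec(at(0.70, 0.72, 0.75), 3, "characters"),
    }
    return GroundTruthAtlas(grid, rois, space_id="synthetic-volume",
                            conditions=DEFAULT_CONDITIONS)
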