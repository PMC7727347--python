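"""Readers and writers for the standard neuroimaging formats the pipeline
consumes and produces.

Volume data travels as NIfTI (integer label images, float probability
maps, 4-D response maps) via nibabel. Surface meshes are read from GIFTI
or OFF-style text; surface labels are newline-delimited 0-based vertex
indices, one file per ROI (FreeSurfer-label-like, without RAS
coordinates). Tables are tidy CSV; label lookups and manifests are JSON.
All element indices are 0-based internally; any 1-based external
convention is converted here at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, GeometryError
from .geometry import SurfaceMesh, VolumeGrid
from .mpm import MaxProbabilityMap
from .probmaps import ProbabilisticMap, SubjectLabelSet

__all__ = [
    "read_surface_mesh",
    "grid_from_nifti",
    "write_subject_labels_nifti",
    "read_subject_labels_nifti",
    "write_prob_map_nifti",
    "write_mpm_nifti",
    "write_vertex_labels",
    "read_vertex_labels",
    "write_color_lut",
    "read_color_lut",
]


# ---------------------------------------------------------------- surfaces

def read_surface_mesh(path: str | Path) -> SurfaceMesh:
    """Load a triangulated mesh from a GIFTI surface or an OFF text file."""
    path = Path(path)
    if path.suffix == ".gii" or path.name.endswith(".surf.gii"):
        img = nib.load(str(path))
        coords = faces = None
        for arr in img.darrays:
            if arr.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                coords = np.asarray(arr.data, dtype=float)
            elif arr.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                faces = np.asarray(arr.data, dtype=np.int64)
        if coords is None or faces is None:
            raise GeometryError(f"{path}: GIFTI file lacks pointset/triangle arrays")
        return SurfaceMesh(len(coords), faces, coordinates=coords)
    return _read_off(path)


def _read_off(path: Path) -> SurfaceMesh:
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise GeometryError(f"{path}: not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4  # skip n_edges
    coords = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    faces = []
    for _ in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise GeometryError(f"{path}: only triangle faces supported, got {k}-gon")
        faces.append([int(t) for t in tokens[pos + 1 : pos + 4]])
        pos += 1 + k
    return SurfaceMesh(nv, np.array(faces), coordinates=coords)


def write_vertex_labels(
    directory: str | Path, subject: SubjectLabelSet
) -> dict[str, str]:
    """Write one index file per ROI; returns roi -> relative filename."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {}
    for roi in sorted(subject.rois):
        fname = f"{subject.subject_id}_{roi}.label.txt"
        with open(directory / fname, "w") as fh:
            for e in sorted(subject.rois[roi]):
                fh.write(f"{e}\n")
        index[roi] = fname
    return index


def read_vertex_labels(
    directory: str | Path,
    subject_id: str,
    roi_files: Mapping[str, str],
    space_id: str = "",
    one_based: bool = False,
) -> SubjectLabelSet:
    directory = Path(directory)
    offset = 1 if one_based else 0
    rois = {}
    for roi, fname in roi_files.items():
        with open(directory / fname) as fh:
            rois[roi] = frozenset(int(line) - offset for line in fh if line.strip())
    return SubjectLabelSet(subject_id=subject_id, space_id=space_id, rois=rois)


# ----------------------------------------------------------------- volumes

def grid_from_nifti(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    shape = tuple(int(s) for s in img.shape[:3])
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(shape, zooms)


def _labels_to_volume(
    grid: VolumeGrid, labels: Mapping[int, int]
) -> np.ndarray:
    vol = np.zeros(grid.shape, dtype=np.int16)
    flat = vol.reshape(-1)
    for e, v in labels.items():
        flat[e] = v
    return vol


def write_subject_labels_nifti(
    path: str | Path, grid: VolumeGrid, subject: SubjectLabelSet
) -> dict[str, int]:
    """Integer-label NIfTI (0 = background) plus sidecar JSON name table."""
    roi_codes = {roi: i + 1 for i, roi in enumerate(sorted(subject.rois))}
    labels = {e: roi_codes[roi] for roi, elems in subject.rois.items() for e in elems}
    affine = np.diag(list(grid.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(_labels_to_volume(grid, labels), affine), str(path))
    sidecar = Path(str(path).removesuffix(".nii.gz").removesuffix(".nii") + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"subject_id": subject.subject_id, "space_id": subject.space_id,
                   "roi_codes": roi_codes}, fh, indent=2, sort_keys=True)
    return roi_codes


def read_subject_labels_nifti(path: str | Path) -> SubjectLabelSet:
    img = nib.load(str(path))
    sidecar = Path(str(path).removesuffix(".nii.gz").removesuffix(".nii") + ".json")
    if not sidecar.exists():
        raise ConfigurationError(f"missing sidecar name table {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    data = np.asarray(img.dataobj).astype(int).reshape(-1)
    code_to_roi = {int(code): roi for roi, code in meta["roi_codes"].items()}
    rois: dict[str, set[int]] = {roi: set() for roi in meta["roi_codes"]}
    for e in np.flatnonzero(data):
        rois[code_to_roi[int(data[e])]].add(int(e))
    return SubjectLabelSet(
        subject_id=meta["subject_id"],
        space_id=meta.get("space_id", ""),
        rois={r: frozenset(v) for r, v in rois.items() if v},
    )


def write_prob_map_nifti(
    path: str | Path, grid: VolumeGrid, pmap: ProbabilisticMap
) -> None:
    """Float probability image plus sidecar metadata (ROI, denominator,
    contributing subjects)."""
    vol = np.zeros(grid.shape, dtype=np.float32)
    flat = vol.reshape(-1)
    for e, v in pmap.values.items():
        flat[e] = v
    affine = np.diag(list(grid.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    sidecar = Path(str(path).removesuffix(".nii.gz").removesuffix(".nii") + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"roi_name": pmap.roi_name, "denominator": pmap.denominator,
                   "subject_ids": list(pmap.subject_ids)}, fh, indent=2, sort_keys=True)


def write_mpm_nifti(
    path: str | Path, grid: VolumeGrid, mpm: MaxProbabilityMap
) -> dict[str, int]:
    """Integer-label NIfTI of the MPM with a JSON label-name lookup."""
    roi_codes = {roi: i + 1 for i, roi in enumerate(mpm.roi_names)}
    labels = {e: roi_codes[roi] for e, roi in mpm.labels.items()}
    affine = np.diag(list(grid.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(_labels_to_volume(grid, labels), affine), str(path))
    sidecar = Path(str(path).removesuffix(".nii.gz").removesuffix(".nii") + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"space_id": mpm.space_id, "threshold": mpm.threshold_used,
                   "roi_codes": roi_codes}, fh, indent=2, sort_keys=True)
    return roi_codes


# -------------------------------------------------------------- color LUTs

def write_color_lut(path: str | Path, roi_names: Sequence[str]) -> None:
    """FreeSurfer-style color lookup table with deterministic colors."""
    rng = np.random.default_rng(0)
    with open(path, "w") as fh:
        fh.write("# index name R G B A\n")
        fh.write("0 background 0 0 0 0\n")
        for i, name in enumerate(roi_names, start=1):
            r, g, b = rng.integers(32, 224, size=3)
            fh.write(f"{i} {name} {r} {g} {b} 255\n")


def read_color_lut(path: str | Path) -> dict[int, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            out[int(parts[0])] = parts[1]
    return out
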