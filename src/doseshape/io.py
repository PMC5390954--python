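"""Container formats: NRRD grids, CSV fluence, sparse influence, configs.

Masks and dose grids are exchanged as NRRD (one file per structure,
header carrying spacing and origin) through SimpleITK. Fluence maps are
plain CSV, one file per beam. The dose-influence operator is persisted
as a compressed sparse container with a JSON sidecar describing the
geometry it was built for. Phantom specs, prescriptions and run
configurations are YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import List, Tuple

import numpy as np
import scipy.sparse as sp
import SimpleITK as sitk
import yaml

from .dose import BeamSet, BixelGrid, DoseInfluence, FluenceMap, KernelParams
from .phantom import OrganSpec, PhantomSpec, VoxelGrid

__all__ = [
    "write_nrrd",
    "read_nrrd",
    "write_fluence_csv",
    "read_fluence_csv",
    "save_influence",
    "load_influence",
    "save_yaml",
    "load_phantom_spec",
    "config_hash",
]


def write_nrrd(path, array: np.ndarray, grid: VoxelGrid) -> None:
    """Write a 3D array (mask or dose, x-y-z index order) as NRRD."""
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    # SimpleITK expects (z, y, x) axis order
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_nrrd(path) -> Tuple[np.ndarray, VoxelGrid]:
    """Read an NRRD volume back into (x, y, z) order plus its grid."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    grid = VoxelGrid(
        dims=tuple(int(d) for d in arr.shape),
        spacing=tuple(float(s) for s in img.GetSpacing()),
        origin=tuple(float(o) for o in img.GetOrigin()),
    )
    return arr, grid


def write_fluence_csv(directory, fluence: FluenceMap, prefix: str = "beam") -> List[Path]:
    """One CSV per beam, rows = u bixels, columns = v bixels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for b, m in enumerate(fluence.maps):
        p = directory / f"{prefix}{b:02d}.csv"
        np.savetxt(p, m, delimiter=",", fmt="%.17g")
        paths.append(p)
    return paths


def read_fluence_csv(directory, n_beams: int, prefix: str = "beam") -> FluenceMap:
    directory = Path(directory)
    maps = []
    for b in range(n_beams):
        m = np.loadtxt(directory / f"{prefix}{b:02d}.csv", delimiter=",", ndmin=2)
        maps.append(m)
    return FluenceMap(maps)


def save_influence(path, influence: DoseInfluence) -> None:
    """Persist the sparse operator plus a JSON geometry sidecar."""
    path = Path(path)
    sp.save_npz(path.with_suffix(".npz"), influence.matrix_csc)
    sidecar = {
        "grid": {
            "dims": list(influence.grid.dims),
            "spacing": list(influence.grid.spacing),
            "origin": list(influence.grid.origin),
        },
        "beams": {
            "gantry_angles_deg": list(influence.beams.gantry_angles_deg),
            "sad_mm": influence.beams.sad_mm,
            "isocenter_mm": list(influence.beams.isocenter_mm) if influence.beams.isocenter_mm else None,
            "bixel_size_mm": list(influence.beams.bixel_size_mm),
        },
        "kernel": dataclasses.asdict(influence.kernel),
        "bixel_grids": [dataclasses.asdict(g) for g in influence.bixel_grids],
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def load_influence(path) -> DoseInfluence:
    path = Path(path)
    mat = sp.load_npz(path.with_suffix(".npz")).tocsc()
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    grid = VoxelGrid(
        dims=tuple(meta["grid"]["dims"]),
        spacing=tuple(meta["grid"]["spacing"]),
        origin=tuple(meta["grid"]["origin"]),
    )
    beams = BeamSet(
        gantry_angles_deg=tuple(meta["beams"]["gantry_angles_deg"]),
        sad_mm=meta["beams"]["sad_mm"],
        isocenter_mm=tuple(meta["beams"]["isocenter_mm"]) if meta["beams"]["isocenter_mm"] else None,
        bixel_size_mm=tuple(meta["beams"]["bixel_size_mm"]),
    )
    kernel = KernelParams(**meta["kernel"])
    grids = [BixelGrid(**g) for g in meta["bixel_grids"]]
    return DoseInfluence(grid=grid, beams=beams, kernel=kernel, bixel_grids=grids, matrix_csc=mat)


def save_yaml(path, obj) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def load_phantom_spec(path) -> PhantomSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for organ in ("body", "ptv", "boost", "rectum", "bladder"):
        if organ in d and isinstance(d[organ], dict):
            o = d[organ]
            d[organ] = OrganSpec(
                center_mm=tuple(o["center_mm"]),
                radii_mm=tuple(o["radii_mm"]),
                exponent=o.get("exponent", 2.2),
            )
    for key in ("dims", "spacing"):
        if key in d:
            d[key] = tuple(d[key])
    return PhantomSpec(**d)


def config_hash(config: dict) -> str:
    """Stable short hash of a (JSON-serializable) run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
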