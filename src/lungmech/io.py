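"""NIfTI I/O for volumes and displacement fields.

Volumes are stored with spacing on the affine diagonal and origin in the
translation column. Displacement fields are 4D NIfTI with the last axis
holding the three vector components, values in mm in physical space; a
JSON sidecar records the direction convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import DisplacementField, Grid, Volume

__all__ = ["read_volume", "write_volume", "read_dvf", "write_dvf"]

DVF_CONVENTION = {
    "components": "last axis, (x, y, z)",
    "units": "mm",
    "direction": "u(x) maps reference (expiration) voxel x to x + u(x) in the moving (inspiration) frame",
}


def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_img(img) -> Grid:
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError("NIfTI header has non-positive spacing")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Grid(tuple(img.shape[:3]), tuple(float(z) for z in zooms), origin)


def write_volume(vol: Volume, path: str | Path) -> None:
    data = np.asarray(vol.data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(vol.grid))
    img.header.set_zooms(vol.grid.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path, kind: str = "map") -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    return Volume(data, _grid_from_img(img), kind)


def write_dvf(dvf: DisplacementField, path: str | Path, sidecar: bool = True) -> None:
    img = nib.Nifti1Image(dvf.vectors.astype(np.float32), _affine(dvf.grid))
    img.header.set_zooms(dvf.grid.spacing + (1.0,))
    nib.save(img, str(path))
    if sidecar:
        side = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
        meta = dict(DVF_CONVENTION)
        meta["shape"] = list(dvf.grid.shape)
        meta["spacing_mm"] = list(dvf.grid.spacing)
        Path(f"{side}.json").write_text(json.dumps(meta, indent=2))


def read_dvf(path: str | Path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"displacement field must be 4D with 3 components, got {data.shape}"
        )
    return DisplacementField(data.astype(float), _grid_from_img(img))
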