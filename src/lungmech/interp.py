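"""Resampling helpers shared by the phantom, registration and QA stages."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grid import DisplacementField, Grid

__all__ = ["sample_at_points", "sample_volume", "invert_displacement"]


def sample_at_points(
    data: np.ndarray,
    grid: Grid,
    points: np.ndarray,
    order: int = 1,
    mode: str = "nearest",
) -> np.ndarray:
    """Sample a gridded scalar field at physical points (mm).

    ``order=1`` gives trilinear interpolation, ``order=0`` nearest neighbour
    (use for label maps). Points outside the grid take the edge value.
    """
    pts = np.asarray(points, dtype=float)
    idx = grid.physical_to_index(pts)
    flat = idx.reshape(-1, 3).T
    out = ndimage.map_coordinates(
        np.asarray(data, dtype=float), flat, order=order, mode=mode
    )
    return out.reshape(pts.shape[:-1])


def sample_volume(vol, points: np.ndarray, order: int = 1) -> np.ndarray:
    return sample_at_points(vol.data, vol.grid, points, order=order)


def invert_displacement(
    dvf: DisplacementField,
    tol_voxel: float = 1e-3,
    max_iter: int = 50,
) -> DisplacementField:
    """Invert a displacement field by fixed-point iteration.

    Given u with forward map phi(x) = x + u(x), returns v on the same grid
    with phi^-1(y) = y + v(y), i.e. x = y + v(y) solves x + u(x) = y.
    Iterates x <- y - u(x) starting from x = y until the update falls below
    ``tol_voxel`` voxels (or ``max_iter`` sweeps).
    """
    grid = dvf.grid
    y = grid.coords()
    x = y.copy()
    tol_mm = tol_voxel * min(grid.spacing)
    for _ in range(max_iter):
        u_at_x = np.stack(
            [sample_at_points(dvf.vectors[..., c], grid, x) for c in range(3)],
            axis=-1,
        )
        x_new = y - u_at_x
        step = np.abs(x_new - x).max()
        x = x_new
        if step < tol_mm:
            break
    return DisplacementField(x - y, grid)
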