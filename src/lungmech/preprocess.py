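"""Volume standardization and vessel enhancement.

Mirrors the standard lung-CT preparation chain: resample to an isotropic
grid, crop to the union bounding box of the two lung masks, enhance tubular
structures with a multiscale Hessian vesselness filter, and binarize the
vesselness map with Otsu's threshold.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import frangi, sato, threshold_otsu

from .grid import Grid, Volume
from .interp import sample_at_points

__all__ = [
    "resample_isotropic",
    "union_crop",
    "vesselness",
    "otsu",
]


def resample_isotropic(v: Volume, spacing: float, order: int | None = None) -> Volume:
    """Resample onto an isotropic grid covering the input extent.

    Trilinear interpolation for scalar volumes, nearest-neighbour for label
    volumes (``kind == "label"``). When the input is already isotropic at
    the target spacing the values pass through unchanged.
    """
    if spacing <= 0:
        raise ValueError("target spacing must be positive")
    if order is None:
        order = 0 if v.kind == "label" else 1
    old = v.grid
    new_shape = tuple(
        max(1, int(np.floor(e / spacing)) + 1) for e in old.extent
    )
    new_grid = Grid(new_shape, (spacing,) * 3, old.origin)
    pts = new_grid.coords()
    data = sample_at_points(v.data, old, pts, order=order)
    if v.kind == "label":
        data = data.astype(np.asarray(v.data).dtype)
    return Volume(data, new_grid, v.kind)


def union_crop(
    maskA: Volume,
    maskB: Volume,
    margin: int = 0,
    payloads: list[Volume] | None = None,
) -> list[Volume]:
    """Crop payloads to the bounding box of ``maskA | maskB`` plus a margin.

    The margin (voxels) is clipped to the grid; returns the cropped payloads
    (defaulting to the two masks themselves when none are given).
    """
    if not maskA.grid.compatible(maskB.grid):
        raise ValueError("masks must share a grid")
    union = np.asarray(maskA.data, dtype=bool) | np.asarray(maskB.data, dtype=bool)
    if not union.any():
        raise ValueError("union of masks is empty; nothing to crop to")
    nz = np.argwhere(union)
    lo = np.maximum(nz.min(axis=0) - margin, 0)
    hi = np.minimum(nz.max(axis=0) + margin + 1, np.array(maskA.grid.shape))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    if payloads is None:
        payloads = [maskA, maskB]
    out = []
    for p in payloads:
        if not p.grid.compatible(maskA.grid):
            raise ValueError("payload grid differs from mask grid")
        origin = tuple(
            p.grid.origin[a] + lo[a] * p.grid.spacing[a] for a in range(3)
        )
        g = Grid(tuple(int(b - a) for a, b in zip(lo, hi)), p.grid.spacing, origin)
        out.append(Volume(np.asarray(p.data)[sl].copy(), g, p.kind))
    return out


def vesselness(
    v: Volume, scales: list[float], method: str = "frangi"
) -> Volume:
    """Multiscale Hessian tubularness map in [0, 1].

    At each scale (mm) the image is smoothed with a Gaussian of that width
    and the Hessian eigenvalues scored for the bright-tube pattern (one
    near-zero eigenvalue, two similar large-magnitude negative ones); the
    final map is the voxelwise maximum over scales. The exact eigenvalue
    functional is pluggable (``"frangi"`` or ``"sato"``); both respond to
    relative, not absolute, intensity, so the map is invariant to constant
    offsets. Requires an isotropic grid.
    """
    if not scales:
        raise ValueError("at least one scale is required")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive (mm)")
    sp = v.grid.spacing
    if not np.allclose(sp, sp[0]):
        raise ValueError("vesselness requires an isotropic grid; resample first")
    sigmas = [s / sp[0] for s in scales]
    data = np.asarray(v.data, dtype=float)
    if method == "frangi":
        out = frangi(data, sigmas=sigmas, black_ridges=False)
    elif method == "sato":
        out = sato(data, sigmas=sigmas, black_ridges=False)
        m = out.max()
        if m > 0:
            out = out / m
    else:
        raise ValueError(f"unknown vesselness method {method!r}")
    out = np.clip(out, 0.0, 1.0)
    return Volume(out, v.grid, kind="probability")


def otsu(v: Volume, nbins: int = 256) -> Volume:
    """Binarize at the threshold maximizing between-class variance.

    Uses a ``nbins``-bin histogram; output is ``v >= threshold``.
    Constant input is rejected (no threshold separates one class).
    """
    data = np.asarray(v.data, dtype=float)
    if np.ptp(data) == 0:
        raise ValueError("Otsu threshold undefined for constant input")
    t = threshold_otsu(data, nbins=nbins)
    return Volume(data >= t, v.grid, kind="label")


def dilate_mask(mask: Volume, voxels: int) -> Volume:
    """Binary dilation by a given number of voxels (used to build Omega)."""
    m = ndimage.binary_dilation(
        np.asarray(mask.data, dtype=bool), iterations=max(0, voxels)
    )
    return Volume(m, mask.grid, kind="label")
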