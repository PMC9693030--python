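"""Biomechanical maps from displacement fields.

Given a displacement field u(x) (mm, on a regular grid), the deformation
gradient is F = I + grad(u). The right Cauchy-Green tensor C = F^T F has
eigenvalues lambda_i^2 with principal stretches lambda_1 >= lambda_2 >=
lambda_3 > 0. From the stretches we derive three maps:

* J = lambda_1 * lambda_2 * lambda_3, the Jacobian determinant — local
  volume change (> 1 expansion, < 1 contraction);
* ADI = sqrt(((l1-l2)/l2)^2 + ((l2-l3)/l3)^2), the anisotropic deformation
  index — magnitude of directional non-uniformity; zero iff the stretch is
  isotropic;
* SRI = arctan(l3 (l1-l2) / (l2 (l2-l3))) / (pi/2), the slab-rod index in
  [0, 1] — 0 for slab-like (two-direction) stretch, 1 for rod-like
  (one-direction) stretch; undefined when ADI = 0.

The alpha/beta shape coordinates place each voxel in a polar-like diagram
with ADI as radius and SRI as angle:
alpha = sign(J - 1) * (l2/l3 - 1), beta = sign(J - 1) * (l1/l2 - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DisplacementField, Grid, Volume

__all__ = [
    "TensorField",
    "StretchField",
    "BiomechMaps",
    "deformation_gradient",
    "principal_stretches",
    "jacobian_map",
    "adi_map",
    "sri_map",
    "alpha_beta_map",
    "compute_biomech_maps",
    "jacobian_from_field",
    "interior_mask",
]

#: eigenvalues below this are clipped and the voxel marked invalid
EIG_FLOOR = 1e-12


@dataclass
class TensorField:
    """Per-voxel deformation gradient F (dimensionless), shape + (3, 3)."""

    F: np.ndarray
    grid: Grid


@dataclass
class StretchField:
    """Sorted principal stretches lambda1 >= lambda2 >= lambda3 (> 0 where valid)."""

    lam: np.ndarray  # shape + (3,), descending
    valid: np.ndarray  # boolean
    grid: Grid

    @property
    def lam1(self) -> np.ndarray:
        return self.lam[..., 0]

    @property
    def lam2(self) -> np.ndarray:
        return self.lam[..., 1]

    @property
    def lam3(self) -> np.ndarray:
        return self.lam[..., 2]


@dataclass
class BiomechMaps:
    """The J/ADI/SRI maps plus alpha/beta coordinates and validity masks."""

    J: Volume
    ADI: Volume
    SRI: Volume
    sri_valid: np.ndarray
    alpha: Volume
    beta: Volume
    valid: np.ndarray
    direction: str = "reference-to-moving"


def deformation_gradient(dvf: DisplacementField) -> TensorField:
    """F = I + grad(u), spacing-aware.

    Central differences at interior voxels, one-sided at the boundary.
    ``F[..., a, b]`` is ``delta_ab + d u_a / d x_b``.
    """
    grid = dvf.grid
    if min(grid.shape) < 3:
        raise ValueError("each grid dimension must be >= 3 to form a stencil")
    shape = grid.shape
    F = np.zeros(shape + (3, 3))
    for a in range(3):
        grads = np.gradient(dvf.vectors[..., a], *grid.spacing)
        for b in range(3):
            F[..., a, b] = grads[b]
    F[..., 0, 0] += 1.0
    F[..., 1, 1] += 1.0
    F[..., 2, 2] += 1.0
    return TensorField(F, grid)


def principal_stretches(tf: TensorField) -> StretchField:
    """Square roots of the descending eigenvalues of F^T F.

    Voxels with non-finite entries or det F <= 0 are marked invalid
    (their stretches are clipped to the numerical floor, not trusted).
    """
    F = tf.F
    finite = np.isfinite(F).all(axis=(-1, -2))
    Fsafe = np.where(finite[..., None, None], F, np.eye(3))
    detF = np.linalg.det(Fsafe)
    C = np.einsum("...ba,...bc->...ac", Fsafe, Fsafe)  # F^T F
    eigs = np.linalg.eigvalsh(C)  # ascending
    eigs = eigs[..., ::-1]  # descending
    clipped = eigs < EIG_FLOOR
    lam = np.sqrt(np.clip(eigs, EIG_FLOOR, None))
    valid = finite & (detF > 0) & ~clipped.any(axis=-1)
    return StretchField(lam, valid, tf.grid)


def jacobian_map(sf: StretchField) -> Volume:
    """J = lambda1 * lambda2 * lambda3; invalid voxels become NaN."""
    J = sf.lam1 * sf.lam2 * sf.lam3
    J = np.where(sf.valid, J, np.nan)
    return Volume(J, sf.grid, kind="map")


def adi_map(sf: StretchField) -> Volume:
    """ADI = sqrt(((l1-l2)/l2)^2 + ((l2-l3)/l3)^2); NaN where invalid."""
    a = (sf.lam1 - sf.lam2) / sf.lam2
    b = (sf.lam2 - sf.lam3) / sf.lam3
    adi = np.sqrt(a * a + b * b)
    adi = np.where(sf.valid, adi, np.nan)
    return Volume(adi, sf.grid, kind="map")


def sri_map(sf: StretchField, adi: Volume) -> tuple[Volume, np.ndarray]:
    """SRI = arctan(l3 (l1-l2) / (l2 (l2-l3))) / (pi/2), in [0, 1].

    Implemented with arctan2 so the rod-like limit lambda2 = lambda3 <
    lambda1 evaluates to 1 exactly. SRI is undefined (masked) where
    ADI = 0, i.e. where the stretch is isotropic.
    """
    num = sf.lam3 * (sf.lam1 - sf.lam2)
    den = sf.lam2 * (sf.lam2 - sf.lam3)
    sri = np.arctan2(num, den) / (np.pi / 2.0)
    sri_valid = sf.valid & ~np.isclose(np.nan_to_num(adi.data), 0.0)
    sri = np.where(sri_valid, sri, np.nan)
    return Volume(sri, sf.grid, kind="map"), sri_valid


def alpha_beta_map(sf: StretchField, J: Volume) -> tuple[Volume, Volume]:
    """Shape coordinates alpha = sign(J-1)(l2/l3 - 1), beta = sign(J-1)(l1/l2 - 1).

    Both parenthesised ratios are >= 1 by the eigenvalue ordering, so alpha
    and beta share the sign of J - 1 (positive quadrant for expansion,
    negative for contraction). Voxels with J = 1 have sign 0.
    """
    s = np.sign(np.nan_to_num(J.data, nan=1.0) - 1.0)
    alpha = s * (sf.lam2 / sf.lam3 - 1.0)
    beta = s * (sf.lam1 / sf.lam2 - 1.0)
    alpha = np.where(sf.valid, alpha, np.nan)
    beta = np.where(sf.valid, beta, np.nan)
    return (
        Volume(alpha, sf.grid, kind="map"),
        Volume(beta, sf.grid, kind="map"),
    )


def compute_biomech_maps(
    dvf: DisplacementField, direction: str = "reference-to-moving"
) -> BiomechMaps:
    """Full pipeline: F -> stretches -> J, ADI, SRI, alpha, beta."""
    tf = deformation_gradient(dvf)
    sf = principal_stretches(tf)
    J = jacobian_map(sf)
    ADI = adi_map(sf)
    SRI, sri_valid = sri_map(sf, ADI)
    alpha, beta = alpha_beta_map(sf, J)
    return BiomechMaps(J, ADI, SRI, sri_valid, alpha, beta, sf.valid, direction)


def jacobian_from_field(dvf: DisplacementField) -> np.ndarray:
    """det(I + grad u) directly from the tensor field (no eigendecomposition)."""
    return np.linalg.det(deformation_gradient(dvf).F)


def interior_mask(grid: Grid, shell: int = 1) -> np.ndarray:
    """True away from the ``shell``-voxel boundary (one-sided-stencil region)."""
    m = np.zeros(grid.shape, dtype=bool)
    m[shell:-shell or None, shell:-shell or None, shell:-shell or None] = True
    return m
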