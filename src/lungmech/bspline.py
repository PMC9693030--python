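"""Cubic B-spline parameterized displacement fields.

The transform stores a lattice of control-point displacement coefficients
(mm) on uniform knots spanning the image domain. The dense displacement at
the voxel centres is the separable tensor-product spline

    u_c(x, y, z) = sum_ijk Bx[x, i] By[y, j] Bz[z, k] p[i, j, k, c]

which makes the dense field, its analytic spatial gradient, and the adjoint
projection of a dense cost gradient back onto the coefficients all cheap
einsum contractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .grid import DisplacementField, Grid

__all__ = ["BSplineTransform"]


def _basis_matrices(
    coords: np.ndarray, knots: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Value and first-derivative design matrices of the cubic basis."""
    n_ctrl = len(knots) - 4
    B = np.zeros((len(coords), n_ctrl))
    dB = np.zeros((len(coords), n_ctrl))
    x = np.clip(coords, knots[3], knots[-4])
    for i in range(n_ctrl):
        c = np.zeros(n_ctrl)
        c[i] = 1.0
        spl = BSpline(knots, c, 3, extrapolate=False)
        B[:, i] = np.nan_to_num(spl(x))
        dB[:, i] = np.nan_to_num(spl.derivative()(x))
    return B, dB


def _axis_knots(origin: float, extent: float, spacing_mm: float) -> np.ndarray:
    m = max(1, int(np.ceil(extent / spacing_mm)))
    return origin + spacing_mm * np.arange(-3, m + 4, dtype=float)


@dataclass
class BSplineTransform:
    """Cubic B-spline displacement u(x) (mm) over a grid domain."""

    grid: Grid
    knot_spacing: float
    coeffs: np.ndarray = None  # (ni, nj, nk, 3)

    def __post_init__(self) -> None:
        if self.knot_spacing <= 0:
            raise ValueError("knot spacing must be positive")
        self._knots = [
            _axis_knots(self.grid.origin[a], self.grid.extent[a], self.knot_spacing)
            for a in range(3)
        ]
        self._n_ctrl = tuple(len(t) - 4 for t in self._knots)
        if self.coeffs is None:
            self.coeffs = np.zeros(self._n_ctrl + (3,))
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != self._n_ctrl + (3,):
            raise ValueError(
                f"coefficient shape {self.coeffs.shape} != {self._n_ctrl + (3,)}"
            )
        self._B, self._dB = zip(
            *(
                _basis_matrices(self.grid.axis_coords(a), self._knots[a])
                for a in range(3)
            )
        )

    # -- identity / fitting -------------------------------------------------

    @classmethod
    def identity(cls, grid: Grid, knot_spacing: float) -> "BSplineTransform":
        return cls(grid, knot_spacing)

    @classmethod
    def fit(
        cls, dense: np.ndarray, grid: Grid, knot_spacing: float
    ) -> "BSplineTransform":
        """Least-squares fit of coefficients to a dense displacement field.

        The tensor-product structure factorizes the pseudo-inverse, so the
        exact least-squares solution is three axis-wise applications of the
        1D pseudo-inverses.
        """
        t = cls(grid, knot_spacing)
        out = np.asarray(dense, dtype=float)
        for a in range(3):
            pinv = np.linalg.pinv(t._B[a])
            out = np.moveaxis(
                np.tensordot(pinv, np.moveaxis(out, a, 0), axes=(1, 0)), 0, a
            )
        t.coeffs = out
        return t

    # -- evaluation ---------------------------------------------------------

    def dense_displacement(self) -> np.ndarray:
        """Displacement (mm) at every voxel centre, shape ``grid.shape + (3,)``."""
        return np.einsum(
            "xi,yj,zk,ijkc->xyzc",
            self._B[0],
            self._B[1],
            self._B[2],
            self.coeffs,
            optimize=True,
        )

    def displacement_gradient(self) -> np.ndarray:
        """Analytic spatial gradient d u_a / d x_b, shape + (3, 3) with [a, b]."""
        G = np.empty(self.grid.shape + (3, 3))
        mats = [self._B[0], self._B[1], self._B[2]]
        for b in range(3):
            use = list(mats)
            use[b] = self._dB[b]
            G[..., :, b] = np.einsum(
                "xi,yj,zk,ijkc->xyzc", use[0], use[1], use[2], self.coeffs,
                optimize=True,
            )
        return G

    def displacement_on(self, grid: Grid) -> np.ndarray:
        """Evaluate the continuous spline on another grid (same physical map)."""
        mats = [
            _basis_matrices(grid.axis_coords(a), self._knots[a])[0] for a in range(3)
        ]
        return np.einsum(
            "xi,yj,zk,ijkc->xyzc", mats[0], mats[1], mats[2], self.coeffs,
            optimize=True,
        )

    def to_field(self) -> DisplacementField:
        return DisplacementField(self.dense_displacement(), self.grid)

    def jacobian_map(self) -> np.ndarray:
        """det(I + grad u) from the analytic B-spline derivatives."""
        G = self.displacement_gradient()
        M = G + np.eye(3)
        return np.linalg.det(M)

    # -- adjoint ------------------------------------------------------------

    def project_gradient(
        self, g_point: np.ndarray, g_grad: np.ndarray | None = None
    ) -> np.ndarray:
        """Pull a dense cost gradient back onto the coefficients.

        ``g_point``: dC/du at voxels, shape + (3,).
        ``g_grad``: dC/d(du_a/dx_b) at voxels, shape + (3, 3), optional.
        """
        out = np.einsum(
            "xi,yj,zk,xyzc->ijkc",
            self._B[0],
            self._B[1],
            self._B[2],
            g_point,
            optimize=True,
        )
        if g_grad is not None:
            mats = [self._B[0], self._B[1], self._B[2]]
            for b in range(3):
                use = list(mats)
                use[b] = self._dB[b]
                out += np.einsum(
                    "xi,yj,zk,xyzc->ijkc",
                    use[0],
                    use[1],
                    use[2],
                    g_grad[..., :, b],
                    optimize=True,
                )
        return out

    def with_coeffs(self, coeffs: np.ndarray) -> "BSplineTransform":
        t = BSplineTransform.__new__(BSplineTransform)
        t.grid = self.grid
        t.knot_spacing = self.knot_spacing
        t.coeffs = np.asarray(coeffs, dtype=float)
        t._knots = self._knots
        t._n_ctrl = self._n_ctrl
        t._B = self._B
        t._dB = self._dB
        return t
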