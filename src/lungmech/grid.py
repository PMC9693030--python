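"""Core spatial containers shared across the pipeline.

All physical quantities are in millimetres. Arrays are indexed ``(x, y, z)``
(axis 0..2), and physical coordinates of voxel ``(i, j, k)`` are
``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Grid", "Volume", "DisplacementField", "LOBE_LABELS", "REGIONS"]

#: Lobe label convention: 1..5 = RUL, RML, RLL, LUL, LLL; 0 = background.
LOBE_LABELS = {1: "RUL", 2: "RML", 3: "RLL", 4: "LUL", 5: "LLL"}

#: Region names accepted by regional summaries; LUNG is the union of lobes.
REGIONS = ("LUNG", "RUL", "RML", "RLL", "LUL", "LLL")


@dataclass(frozen=True)
class Grid:
    """Regular 3D sampling grid: shape (voxels), spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size spanned by voxel centres along each axis (mm)."""
        return tuple((n - 1) * h for n, h in zip(self.shape, self.spacing))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def meshgrid(self, sparse: bool = True) -> tuple[np.ndarray, ...]:
        axes = [self.axis_coords(a) for a in range(3)]
        return np.meshgrid(*axes, indexing="ij", sparse=sparse)

    def coords(self) -> np.ndarray:
        """Dense ``shape + (3,)`` array of physical voxel-centre coordinates."""
        xs = self.meshgrid(sparse=False)
        return np.stack(xs, axis=-1)

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of physical points (mm), same shape."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def compatible(self, other: "Grid", rtol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=rtol)
            and np.allclose(self.origin, other.origin, rtol=rtol)
        )


@dataclass
class Volume:
    """3D scalar field on a :class:`Grid`.

    ``kind`` records the value semantics (``"hu"``, ``"density"``,
    ``"probability"``, ``"label"``, ``"map"``); it is metadata only.
    """

    data: np.ndarray
    grid: Grid
    kind: str = "map"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "Volume":
        return Volume(data, self.grid, kind if kind is not None else self.kind)


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors u(x) in mm on a fixed-image grid.

    The convention used throughout the package: a reference (expiration)
    voxel at physical position x corresponds to the moving (inspiration)
    position ``x + u(x)``.  The deformation gradient is ``F = I + grad(u)``
    and ``J = det F > 1`` indicates expansion from the reference state.
    """

    vectors: np.ndarray  # shape + (3,), mm
    grid: Grid

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != self.grid.shape + (3,):
            raise ValueError(
                f"vector field shape {self.vectors.shape} incompatible with "
                f"grid {self.grid.shape}"
            )

    def target_points(self) -> np.ndarray:
        """Physical positions x + u(x), shape ``grid.shape + (3,)``."""
        return self.grid.coords() + self.vectors

    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.vectors, axis=-1).max())
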