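"""Registration quality metrics.

Four measures quantify how well two segmentations agree after registration:

* LDC — lung lobe Dice coefficient: the unweighted mean Dice overlap of the
  five lobes;
* W10SE — worst 10% surface error: for each vertex of one lung surface the
  closest-point distance to the other surface (closest point may lie inside
  a triangle face) is computed; the mean of the largest 10% of distances is
  taken in each direction and the two directions averaged;
* VTPE — vessel tree position error: symmetric mean closest-point distance
  between binary vessel segmentations (voxel centres, Euclidean distance
  transform);
* SCSE — symmetric closest skeleton error: the same symmetric mean
  closest-point distance computed on vessel-tree skeletons.

All distances are in millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes
from skimage.morphology import skeletonize as _sk_skeletonize

from .grid import DisplacementField, Grid, Volume
from .interp import sample_at_points

__all__ = [
    "SurfaceMesh",
    "Skeleton",
    "dice",
    "lobe_dice",
    "extract_surface",
    "worst10_surface_error",
    "vessel_tree_position_error",
    "skeletonize",
    "skeleton_error",
    "warp_labels",
    "qa_table",
]


@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices (N, 3) in mm, triangles (M, 3) indices."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    @property
    def area(self) -> float:
        return float(self.to_trimesh().area)


@dataclass
class Skeleton:
    """Medial voxel set of a tubular structure; points in mm."""

    points: np.ndarray  # (K, 3) mm
    voxels: np.ndarray | None = None  # (K, 3) integer indices, optional

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)


def dice(L1: np.ndarray, L2: np.ndarray) -> float:
    """Dice coefficient 2|L1 ^ L2| / (|L1| + |L2|); undefined for two empties."""
    a = np.asarray(L1, dtype=bool)
    b = np.asarray(L2, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise ValueError("Dice undefined: both regions empty")
    return 2.0 * float(np.logical_and(a, b).sum()) / denom


def lobe_dice(A: Volume, B: Volume, labels: tuple[int, ...] = (1, 2, 3, 4, 5)) -> float:
    """Unweighted mean of the per-lobe Dice coefficients."""
    a = np.asarray(A.data)
    b = np.asarray(B.data)
    vals = []
    for lab in labels:
        vals.append(dice(a == lab, b == lab))
    return float(np.mean(vals))


def extract_surface(mask: Volume, level: float = 0.5) -> SurfaceMesh:
    """Closed iso-surface triangulation of a binary mask at the 0.5 level.

    The mask is zero-padded by one voxel so the surface is closed even when
    the structure touches the grid boundary; vertex coordinates are in mm.
    """
    m = np.asarray(mask.data, dtype=float)
    if not np.any(m > 0):
        raise ValueError("cannot extract a surface from an empty mask")
    spacing = mask.grid.spacing
    padded = np.pad(m, 1, mode="constant")
    verts, faces, _, _ = marching_cubes(padded, level=level, spacing=spacing)
    # undo the pad offset and move into physical coordinates
    verts = verts - np.asarray(spacing) + np.asarray(mask.grid.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    return SurfaceMesh(np.asarray(mesh.vertices), np.asarray(mesh.faces))


def closest_point_on_triangles(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Closest point to ``p`` on each triangle (a, b, c); all inputs (N, 3).

    Vectorized barycentric region classification (vertex / edge / face),
    exact up to floating point.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        denom_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
        denom = va + vb + vc
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)

    candidates = [
        ((d1 <= 0) & (d2 <= 0), a),
        ((d3 >= 0) & (d4 <= d3), b),
        ((d6 >= 0) & (d5 <= d6), c),
        ((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t_ab[:, None] * ab),
        ((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t_ac[:, None] * ac),
        ((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + t_bc[:, None] * (c - b)),
    ]
    out = a + v[:, None] * ab + w[:, None] * ac  # face interior
    assigned = np.zeros(len(p), dtype=bool)
    for cond, val in candidates:
        take = cond & ~assigned
        out[take] = val[take]
        assigned |= cond
    return out


def point_to_mesh_distances(points: np.ndarray, mesh: SurfaceMesh, k: int = 32) -> np.ndarray:
    """Exact closest-point distance from each point to the mesh surface.

    The closest point may lie on a face, an edge or a vertex. A KD-tree on
    triangle centroids prunes candidates; any point whose pruned minimum
    cannot be certified exact (the uninspected triangles could still be
    closer) falls back to a radius query that is guaranteed to contain the
    true closest triangle.
    """
    if len(mesh.triangles) == 0:
        raise ValueError("mesh has no triangles")
    pts = np.asarray(points, dtype=float)
    tri = mesh.vertices[mesh.triangles]  # (M, 3, 3)
    centroids = tri.mean(axis=1)
    r_max = float(np.linalg.norm(tri - centroids[:, None, :], axis=2).max())
    tree = cKDTree(centroids)
    M = len(tri)
    kk = min(k, M)
    dk, ik = tree.query(pts, k=kk)
    if kk == 1:
        dk = dk[:, None]
        ik = ik[:, None]
    cand = tri[ik]  # (N, kk, 3, 3)
    rep = np.repeat(pts, kk, axis=0)
    cp = closest_point_on_triangles(
        rep,
        cand[..., 0, :].reshape(-1, 3),
        cand[..., 1, :].reshape(-1, 3),
        cand[..., 2, :].reshape(-1, 3),
    )
    d = np.linalg.norm(rep - cp, axis=1).reshape(len(pts), kk).min(axis=1)
    if kk < M:
        # a triangle beyond the k-th centroid is at least (dk_max - r_max) away
        uncertain = np.nonzero(d > dk[:, -1] - r_max)[0]
        for i in uncertain:
            idx = tree.query_ball_point(pts[i], d[i] + r_max)
            t = tri[idx]
            cp_i = closest_point_on_triangles(
                np.broadcast_to(pts[i], (len(t), 3)).copy(),
                t[:, 0],
                t[:, 1],
                t[:, 2],
            )
            d[i] = np.linalg.norm(pts[i] - cp_i, axis=1).min()
    return d


def _directed_worst10(source: SurfaceMesh, target: SurfaceMesh) -> float:
    if len(source.triangles) == 0 or len(target.triangles) == 0:
        raise ValueError("meshes must have triangles")
    dists = np.sort(point_to_mesh_distances(source.vertices, target))[::-1]
    k = math.ceil(0.1 * len(dists))
    return float(np.mean(dists[:k]))


def worst10_surface_error(S1: SurfaceMesh, S2: SurfaceMesh) -> float:
    """Symmetric worst-10% surface error (mm): average of both directions."""
    return 0.5 * (_directed_worst10(S1, S2) + _directed_worst10(S2, S1))


def _directed_mask_distance(src: np.ndarray, dst: np.ndarray, spacing) -> float:
    # exact Euclidean distance from every src voxel centre to the nearest
    # dst voxel centre, via the distance transform of the complement
    dt = ndimage.distance_transform_edt(~dst, sampling=spacing)
    return float(dt[src].mean())


def vessel_tree_position_error(M1: Volume, M2: Volume) -> float:
    """Symmetric mean closest-voxel distance between binary masks (mm)."""
    a = np.asarray(M1.data, dtype=bool)
    b = np.asarray(M2.data, dtype=bool)
    if not a.any() or not b.any():
        raise ValueError("both masks must be nonempty")
    sp = M1.grid.spacing
    return 0.5 * (
        _directed_mask_distance(a, b, sp) + _directed_mask_distance(b, a, sp)
    )


def skeletonize(mask: Volume) -> Skeleton:
    """Thin a binary mask to its medial voxel set (3D topological thinning)."""
    m = np.asarray(mask.data, dtype=bool)
    if not m.any():
        raise ValueError("cannot skeletonize an empty mask")
    sk = _sk_skeletonize(m)
    vox = np.argwhere(sk)
    pts = np.asarray(mask.grid.origin) + vox * np.asarray(mask.grid.spacing)
    return Skeleton(points=pts, voxels=vox)


def skeleton_error(K1: Skeleton, K2: Skeleton) -> float:
    """Symmetric mean closest-point distance between skeleton point sets (mm)."""
    if len(K1.points) == 0 or len(K2.points) == 0:
        raise ValueError("both skeletons must be nonempty")
    d12 = cKDTree(K2.points).query(K1.points)[0].mean()
    d21 = cKDTree(K1.points).query(K2.points)[0].mean()
    return 0.5 * float(d12 + d21)


def warp_labels(
    labels: Volume, dvf: DisplacementField, mode: str = "forward"
) -> Volume:
    """Nearest-neighbour resampling of a label map through a displacement field.

    ``mode="forward"`` samples the labels at x + u(x) — the pull-back of the
    moving-frame labels onto the fixed grid (the operation needed to compare
    warped moving lobes against fixed lobes). ``mode="inverse"`` samples at
    x - u(x).
    """
    if not labels.grid.compatible(dvf.grid):
        raise ValueError("label map and displacement field grids differ")
    coords = labels.grid.coords()
    if mode == "forward":
        pts = coords + dvf.vectors
    elif mode == "inverse":
        pts = coords - dvf.vectors
    else:
        raise ValueError(f"unknown mode {mode!r}")
    warped = sample_at_points(labels.data, labels.grid, pts, order=0)
    return Volume(
        warped.astype(np.asarray(labels.data).dtype), labels.grid, kind="label"
    )


def qa_table(
    fixed_lobes: Volume,
    warped_lobes: Volume,
    fixed_vessels: Volume,
    warped_vessels: Volume,
) -> dict[str, float]:
    """All four QA metrics for a registered pair; distances in mm."""
    fixed_lung = Volume(np.asarray(fixed_lobes.data) > 0, fixed_lobes.grid, "label")
    warped_lung = Volume(np.asarray(warped_lobes.data) > 0, warped_lobes.grid, "label")
    s1 = extract_surface(fixed_lung)
    s2 = extract_surface(warped_lung)
    return {
        "LDC": lobe_dice(fixed_lobes, warped_lobes),
        "W10SE": worst10_surface_error(s1, s2),
        "VTPE": vessel_tree_position_error(fixed_vessels, warped_vessels),
        "SCSE": skeleton_error(
            skeletonize(fixed_vessels), skeletonize(warped_vessels)
        ),
    }
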