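"""Registration QA metrics: exact constructions and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import lungmech as lm
from lungmech.regqa import (
    Skeleton,
    SurfaceMesh,
    closest_point_on_triangles,
    dice,
    extract_surface,
    lobe_dice,
    point_to_mesh_distances,
    skeleton_error,
    skeletonize,
    vessel_tree_position_error,
    warp_labels,
    worst10_surface_error,
    qa_table,
)


def _vol(arr, spacing=(1.0, 1.0, 1.0), kind="label"):
    return lm.Volume(np.asarray(arr), lm.Grid(np.asarray(arr).shape, spacing), kind)


def _plane_mesh(z, nx=8, ny=8):
    """Regular triangulated rectangle in the plane z = const."""
    xs, ys = np.meshgrid(
        np.arange(nx, dtype=float), np.arange(ny, dtype=float), indexing="ij"
    )
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.full(nx * ny, float(z))])
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b = i * ny + j, (i + 1) * ny + j
            c, d = i * ny + j + 1, (i + 1) * ny + j + 1
            tris += [[a, b, c], [b, d, c]]
    return SurfaceMesh(verts, np.asarray(tris))


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0

    def test_half_overlap(self):
        assert dice(np.array([1, 1, 0, 0]), np.array([0, 1, 1, 0])) == 0.5

    def test_both_empty_rejected(self):
        z = np.zeros((3, 3, 3), bool)
        with pytest.raises(ValueError, match="empty"):
            dice(z, z)

    def test_lobe_dice_mean_of_shifted_lines(self):
        lab = np.zeros((7, 5, 12), int)
        for lobe in range(1, 6):
            lab[lobe, 2, 1:11] = lobe  # five 10-voxel lines
        shifted = np.roll(lab, 2, axis=2)  # overlap 8 of 10 per lobe
        assert lobe_dice(_vol(lab), _vol(shifted)) == pytest.approx(0.8)
        assert lobe_dice(_vol(lab), _vol(lab)) == 1.0


class TestSurfaceExtraction:
    def test_box_area_close_to_analytic(self):
        m = np.zeros((16, 18, 20), bool)
        m[3:11, 3:13, 3:15] = True  # 8 x 10 x 12 voxel box
        mesh = extract_surface(_vol(m))
        analytic = 2 * (8 * 10 + 10 * 12 + 12 * 8)
        assert abs(mesh.area - analytic) / analytic < 0.10
        assert mesh.to_trimesh().is_watertight

    def test_sphere_area_close_to_analytic(self):
        g = lm.Grid((32, 32, 32))
        c = np.array([15.5] * 3)
        r = 10.0
        d2 = sum((x - ci) ** 2 for x, ci in zip(g.meshgrid(), c))
        mesh = extract_surface(_vol(d2 <= r**2))
        analytic = 4 * np.pi * r**2
        assert abs(mesh.area - analytic) / analytic < 0.10

    def test_single_voxel_closed_surface(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        mesh = extract_surface(_vol(m))
        assert mesh.to_trimesh().is_watertight
        assert mesh.area > 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_surface(_vol(np.zeros((4, 4, 4), bool)))


class TestPointToMesh:
    def test_single_triangle_vs_dense_barycentric_sampling(self):
        rng = np.random.default_rng(0)
        a, b, c = rng.normal(size=(3, 3))
        pts = rng.normal(scale=2.0, size=(20, 3))
        cp = closest_point_on_triangles(
            pts,
            np.broadcast_to(a, (20, 3)).copy(),
            np.broadcast_to(b, (20, 3)).copy(),
            np.broadcast_to(c, (20, 3)).copy(),
        )
        d = np.linalg.norm(pts - cp, axis=1)
        # independent check: dense barycentric sampling of the triangle
        t = np.linspace(0, 1, 201)
        uu, vv = np.meshgrid(t, t)
        keep = uu + vv <= 1.0
        samples = (
            a
            + uu[keep][:, None] * (b - a)
            + vv[keep][:, None] * (c - a)
        )
        d_ref = cdist(pts, samples).min(axis=1)
        assert np.all(d <= d_ref + 1e-12)
        assert np.max(d_ref - d) < 5e-3

    def test_pruned_distances_match_all_triangle_brute_force(self):
        g = lm.Grid((16, 16, 16))
        c = np.array([7.5] * 3)
        d2 = sum((x - ci) ** 2 for x, ci in zip(g.meshgrid(), c))
        mesh = extract_surface(_vol(d2 <= 5.0**2))
        assert len(mesh.triangles) <= 5000
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 15, size=(60, 3))
        fast = point_to_mesh_distances(pts, mesh, k=8)
        tri = mesh.vertices[mesh.triangles]
        brute = np.empty(len(pts))
        for i, p in enumerate(pts):
            cp = closest_point_on_triangles(
                np.broadcast_to(p, (len(tri), 3)).copy(),
                tri[:, 0],
                tri[:, 1],
                tri[:, 2],
            )
            brute[i] = np.linalg.norm(p - cp, axis=1).min()
        assert np.abs(fast - brute).max() < 1e-9


class TestW10SE:
    def test_identical_meshes_give_zero(self):
        mesh = _plane_mesh(0.0)
        assert worst10_surface_error(mesh, mesh) == 0.0

    def test_parallel_planes_give_exact_offset(self):
        # identical footprints: every vertex projects onto the other plane
        m1 = _plane_mesh(0.0)
        m2 = _plane_mesh(3.0)
        assert worst10_surface_error(m1, m2) == pytest.approx(3.0, abs=1e-12)

    def test_worst_fraction_dominates(self):
        # one plane bent: 10% of vertices lifted by 5 -> directed error > offset
        m1 = _plane_mesh(0.0)
        m2 = _plane_mesh(1.0)
        lifted = m2.vertices.copy()
        k = int(np.ceil(0.1 * len(lifted)))
        lifted[:k, 2] += 5.0
        m2b = SurfaceMesh(lifted, m2.triangles)
        assert worst10_surface_error(m1, m2b) > worst10_surface_error(m1, m2)

    def test_empty_mesh_rejected(self):
        m = _plane_mesh(0.0)
        bad = SurfaceMesh(m.vertices, np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            worst10_surface_error(m, bad)


class TestVTPE:
    def test_identity_zero(self):
        m = np.zeros((8, 8, 8), bool)
        m[2:6, 4, 4] = True
        v = _vol(m)
        assert vessel_tree_position_error(v, v) == 0.0

    def test_parallel_lines_exact_offset(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[1:9, 2, 5] = True
        b[1:9, 5, 5] = True  # same x samples, 3 mm apart in y
        assert vessel_tree_position_error(_vol(a), _vol(b)) == pytest.approx(3.0)

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(3)
        a = rng.random((12, 12, 12)) < 0.04
        b = rng.random((12, 12, 12)) < 0.04
        a[0, 0, 0] = b[5, 5, 5] = True  # guarantee nonempty
        sp = (1.0, 0.8, 1.3)
        pa = np.argwhere(a) * np.array(sp)
        pb = np.argwhere(b) * np.array(sp)
        D = cdist(pa, pb)
        brute = 0.5 * (D.min(axis=1).mean() + D.min(axis=0).mean())
        got = vessel_tree_position_error(_vol(a, sp), _vol(b, sp))
        assert got == pytest.approx(brute, abs=1e-9)

    def test_empty_mask_rejected(self):
        m = np.zeros((6, 6, 6), bool)
        full = m.copy()
        full[3, 3, 3] = True
        with pytest.raises(ValueError, match="nonempty"):
            vessel_tree_position_error(_vol(m), _vol(full))


class TestSkeleton:
    def test_straight_tube_skeleton_on_axis(self):
        m = np.zeros((24, 11, 11), bool)
        yy, zz = np.meshgrid(np.arange(11), np.arange(11), indexing="ij")
        disk = (yy - 5) ** 2 + (zz - 5) ** 2 <= 9
        m[2:22] = disk
        sk = skeletonize(_vol(m))
        interior = sk.points[(sk.points[:, 0] > 5) & (sk.points[:, 0] < 18)]
        assert len(interior) > 0
        lateral = np.linalg.norm(interior[:, 1:] - np.array([5.0, 5.0]), axis=1)
        assert lateral.max() <= np.sqrt(2.0)  # within one voxel of the axis

    def test_single_voxel(self):
        m = np.zeros((5, 5, 5), bool)
        m[1, 2, 3] = True
        sk = skeletonize(_vol(m))
        assert np.array_equal(sk.points, [[1.0, 2.0, 3.0]])

    def test_y_branch_has_three_endpoints(self):
        m = np.zeros((20, 20, 7), bool)
        m[2:10, 10, 3] = True  # trunk
        for t in range(8):  # two diverging branches
            m[10 + t, 10 + t, 3] = True
            m[10 + t, 10 - t, 3] = True
        sk = skeletonize(_vol(m))
        vox = set(map(tuple, sk.voxels))
        ends = 0
        for v in vox:
            nbrs = sum(
                (v[0] + dx, v[1] + dy, v[2] + dz) in vox
                for dx in (-1, 0, 1)
                for dy in (-1, 0, 1)
                for dz in (-1, 0, 1)
                if (dx, dy, dz) != (0, 0, 0)
            )
            ends += nbrs == 1
        assert ends == 3

    def test_skeleton_error_parallel_lines(self):
        xs = np.arange(10, dtype=float)
        k1 = Skeleton(np.column_stack([xs, np.zeros(10), np.zeros(10)]))
        k2 = Skeleton(np.column_stack([xs, np.full(10, 4.0), np.zeros(10)]))
        assert skeleton_error(k1, k2) == pytest.approx(4.0)

    def test_skeleton_error_matches_brute_force(self):
        rng = np.random.default_rng(5)
        p1 = rng.normal(size=(40, 3))
        p2 = rng.normal(size=(55, 3))
        D = cdist(p1, p2)
        brute = 0.5 * (D.min(axis=1).mean() + D.min(axis=0).mean())
        assert skeleton_error(Skeleton(p1), Skeleton(p2)) == pytest.approx(
            brute, abs=1e-9
        )

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            skeletonize(_vol(np.zeros((4, 4, 4), bool)))
        with pytest.raises(ValueError, match="nonempty"):
            skeleton_error(Skeleton(np.zeros((0, 3))), Skeleton(np.zeros((1, 3))))


class TestWarpLabels:
    def test_identity(self):
        lab = np.arange(27).reshape(3, 3, 3)
        v = _vol(lab)
        dvf = lm.DisplacementField(np.zeros((3, 3, 3, 3)), v.grid)
        assert np.array_equal(warp_labels(v, dvf).data, lab)

    def test_integer_translation_shifts_labels(self):
        rng = np.random.default_rng(8)
        lab = rng.integers(0, 5, size=(8, 8, 8))
        v = _vol(lab)
        u = np.zeros((8, 8, 8, 3))
        u[..., 0] = 2.0  # sample at x + 2 voxels
        warped = warp_labels(v, lm.DisplacementField(u, v.grid))
        assert np.array_equal(warped.data[:-2], lab[2:])

    def test_inverse_mode_shifts_other_way(self):
        lab = np.arange(6 * 6 * 6).reshape(6, 6, 6)
        v = _vol(lab)
        u = np.zeros((6, 6, 6, 3))
        u[..., 1] = 1.0
        warped = warp_labels(v, lm.DisplacementField(u, v.grid), mode="inverse")
        assert np.array_equal(warped.data[:, 1:], lab[:, :-1])

    def test_grid_mismatch_and_bad_mode_rejected(self):
        v = _vol(np.zeros((4, 4, 4), int))
        other = lm.DisplacementField(np.zeros((4, 4, 4, 3)), lm.Grid((4, 4, 4), (2, 2, 2)))
        with pytest.raises(ValueError, match="grid"):
            warp_labels(v, other)
        ok = lm.DisplacementField(np.zeros((4, 4, 4, 3)), v.grid)
        with pytest.raises(ValueError, match="mode"):
            warp_labels(v, ok, mode="sideways")

    def test_true_field_warp_recovers_fixed_lobes(self, phantom_pair):
        warped = warp_labels(
            phantom_pair["moving_lobes"], phantom_pair["true_dvf"], mode="forward"
        )
        assert lobe_dice(phantom_pair["lobes"], warped) >= 0.98


class TestQATable:
    def test_metrics_degrade_with_growing_misalignment(self, phantom64):
        lobes, vessels, lung = phantom64
        tables = []
        for off in (0, 2, 5):
            moved_lobes = _vol(np.roll(lobes.data, off, axis=0))
            moved_vessels = _vol(np.roll(vessels.data, off, axis=0))
            tables.append(qa_table(lobes, moved_lobes, vessels, moved_vessels))
        assert set(tables[0]) == {"LDC", "W10SE", "VTPE", "SCSE"}
        assert tables[0]["LDC"] == 1.0
        assert tables[0]["VTPE"] == 0.0
        ldc = [t["LDC"] for t in tables]
        assert ldc[0] > ldc[1] > ldc[2]
        for key in ("W10SE", "VTPE", "SCSE"):
            vals = [t[key] for t in tables]
            assert vals[0] < vals[1] < vals[2]
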