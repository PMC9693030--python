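"""Synthetic lung phantoms with known ground-truth deformations.

This module generates every input the downstream pipeline consumes:

* analytic deformations (affine / sinusoidal / radial) with closed-form
  deformation gradients, so numerical tensor metrics can be checked against
  exact values;
* a five-lobe two-lung geometry with a branching vessel tree;
* expiration/inspiration CT-like image pairs in which tissue volume is
  conserved voxel-for-voxel (the modelling assumption behind the SSTVD
  similarity cost: air content changes with breathing, tissue does not);
* staged cohorts whose mean regional expansion decreases with disease
  severity, emulating the decline of residual-volume-to-total-lung-capacity
  expansion across COPD severity groups.

All generators are deterministic given their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .grid import DisplacementField, Grid, Volume
from .interp import sample_at_points

__all__ = [
    "AnalyticDeformation",
    "AffineDeformation",
    "SinusoidalDeformation",
    "RadialDeformation",
    "SumDeformation",
    "PhantomSubject",
    "make_affine_dvf",
    "make_sinusoidal_dvf",
    "make_lung_phantom",
    "synthesize_image_pair",
    "make_cohort",
    "simulate_subject_means",
]

#: Tissue fractions at expiration: parenchyma has low tissue content,
#: vessels and extra-pulmonary soft tissue are (nearly) pure tissue.
FRACTION_PARENCHYMA = 0.2
FRACTION_VESSEL = 1.0
FRACTION_BODY = 1.0

HU_AIR = -1000.0
HU_TISSUE = 55.0


# ---------------------------------------------------------------------------
# Analytic deformations
# ---------------------------------------------------------------------------


class AnalyticDeformation:
    """A smooth map phi(x) = x + u(x) with closed-form deformation gradient.

    Subclasses implement :meth:`displacement_at` and :meth:`gradient_at`
    at arbitrary physical points; grid-sampled fields and Jacobian maps
    derive from those.
    """

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def gradient_at(self, points: np.ndarray) -> np.ndarray:
        """Deformation gradient F = I + du/dx, shape ``points.shape[:-1] + (3, 3)``."""
        raise NotImplementedError

    def to_field(self, grid: Grid) -> DisplacementField:
        return DisplacementField(self.displacement_at(grid.coords()), grid)

    def jacobian_at(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.det(self.gradient_at(points))

    def jacobian_map(self, grid: Grid) -> np.ndarray:
        return self.jacobian_at(grid.coords())

    def inverse_at(
        self,
        points: np.ndarray,
        tol_mm: float = 1e-3,
        max_iter: int = 50,
        x0: np.ndarray | None = None,
    ) -> np.ndarray:
        """phi^-1 by Newton iteration x <- x - F(x)^-1 (phi(x) - y).

        Newton handles large-gradient fields (e.g. strong affine maps) where
        the plain fixed-point update x <- y - u(x) is non-contractive and
        diverges; for the smooth fields used here it converges in a few
        iterations.
        """
        y = np.asarray(points, dtype=float)
        x = y.copy() if x0 is None else np.asarray(x0, dtype=float).copy()
        for _ in range(max_iter):
            r = x + self.displacement_at(x) - y
            if np.abs(r).max() < tol_mm:
                break
            F = self.gradient_at(x)
            x = x - np.linalg.solve(F, r[..., None])[..., 0]
        return x


@dataclass
class AffineDeformation(AnalyticDeformation):
    """phi(x) = A x (about the origin); u(x) = (A - I) x, F = A everywhere."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("affine matrix must be 3x3")
        if np.linalg.det(self.matrix) <= 0:
            raise ValueError("affine deformation must have det(A) > 0")

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ (self.matrix - np.eye(3)).T

    def gradient_at(self, points: np.ndarray) -> np.ndarray:
        shape = np.asarray(points).shape[:-1]
        return np.broadcast_to(self.matrix, shape + (3, 3)).copy()


@dataclass
class SinusoidalDeformation(AnalyticDeformation):
    """Single-component field u_axis(x) = a sin(k x_axis).

    F = I + a k cos(k x_axis) e_axis e_axis^T, hence
    J(x) = 1 + a k cos(k x_axis); invertibility requires ``|a k| < 1``.
    """

    amplitude: float  # mm
    wavenumber: float  # 1/mm
    axis: int = 0

    def __post_init__(self) -> None:
        if abs(self.amplitude * self.wavenumber) >= 1:
            raise ValueError(
                "sinusoidal deformation requires |amplitude * wavenumber| < 1 "
                "for invertibility"
            )
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        u = np.zeros_like(pts)
        u[..., self.axis] = self.amplitude * np.sin(
            self.wavenumber * pts[..., self.axis]
        )
        return u

    def gradient_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        shape = pts.shape[:-1]
        F = np.zeros(shape + (3, 3))
        F[..., 0, 0] = F[..., 1, 1] = F[..., 2, 2] = 1.0
        F[..., self.axis, self.axis] += (
            self.amplitude
            * self.wavenumber
            * np.cos(self.wavenumber * pts[..., self.axis])
        )
        return F


@dataclass
class RadialDeformation(AnalyticDeformation):
    """Radial expansion/contraction with Gaussian falloff about a centre.

    u(x) = s * w(x) * (x - c) with w(x) = exp(-|x - c|^2 / (2 sigma^2)).
    F = I + s w (I - d d^T / sigma^2) with d = x - c; closed-form throughout.
    ``s > 0`` expands around the centre, ``s < 0`` contracts.
    """

    center: np.ndarray
    amplitude: float
    sigma: float  # mm

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def _weight(self, d: np.ndarray) -> np.ndarray:
        return np.exp(-np.sum(d * d, axis=-1) / (2.0 * self.sigma**2))

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points, dtype=float) - self.center
        return self.amplitude * self._weight(d)[..., None] * d

    def gradient_at(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points, dtype=float) - self.center
        w = self._weight(d)
        shape = d.shape[:-1]
        F = np.zeros(shape + (3, 3))
        eye = np.eye(3)
        sw = self.amplitude * w
        outer = d[..., :, None] * d[..., None, :] / self.sigma**2
        F += eye
        F += sw[..., None, None] * (eye - outer)
        return F


@dataclass
class SumDeformation(AnalyticDeformation):
    """Superposition of displacement fields; F = I + sum_i (F_i - I)."""

    parts: list

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        u = np.zeros_like(np.asarray(points, dtype=float))
        for p in self.parts:
            u += p.displacement_at(points)
        return u

    def gradient_at(self, points: np.ndarray) -> np.ndarray:
        shape = np.asarray(points).shape[:-1]
        F = np.broadcast_to(np.eye(3), shape + (3, 3)).copy()
        for p in self.parts:
            F += p.gradient_at(points)
            F -= np.eye(3)
        return F


@dataclass
class ScaledDeformation(AnalyticDeformation):
    """A deformation with its displacement scaled by a constant factor."""

    base: AnalyticDeformation
    factor: float

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        return self.factor * self.base.displacement_at(points)

    def gradient_at(self, points: np.ndarray) -> np.ndarray:
        shape = np.asarray(points).shape[:-1]
        F = self.base.gradient_at(points)
        return np.broadcast_to(np.eye(3), shape + (3, 3)) + self.factor * (
            F - np.eye(3)
        )


def make_affine_dvf(A: np.ndarray, grid: Grid) -> DisplacementField:
    """Displacement field of the affine map x -> A x; requires det(A) > 0."""
    return AffineDeformation(A).to_field(grid)


def make_sinusoidal_dvf(
    amplitude: float, wavenumber: float, axis: int, grid: Grid
) -> DisplacementField:
    """Single-axis sinusoidal displacement; requires |a*k| < 1."""
    return SinusoidalDeformation(amplitude, wavenumber, axis).to_field(grid)


# ---------------------------------------------------------------------------
# Lung geometry
# ---------------------------------------------------------------------------


def _ellipsoid_mask(grid: Grid, center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    xs = grid.meshgrid(sparse=True)
    q = np.zeros(grid.shape)
    for a in range(3):
        q = q + ((xs[a] - center[a]) / semiaxes[a]) ** 2
    return q <= 1.0


def _rasterize_tube(
    out: np.ndarray, grid: Grid, p0: np.ndarray, p1: np.ndarray, radius: float
) -> None:
    """OR a capsule (cylinder with spherical caps) into a boolean array."""
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    i0 = np.maximum(np.floor(grid.physical_to_index(lo)).astype(int), 0)
    i1 = np.minimum(
        np.ceil(grid.physical_to_index(hi)).astype(int) + 1, np.array(grid.shape)
    )
    if np.any(i0 >= i1):
        return
    axes = [
        grid.origin[a] + grid.spacing[a] * np.arange(i0[a], i1[a]) for a in range(3)
    ]
    xs = np.meshgrid(*axes, indexing="ij", sparse=True)
    d = p1 - p0
    L2 = float(d @ d)
    # closest-point parameter along the segment, clipped to [0, 1]
    t = np.zeros(tuple(i1 - i0))
    if L2 > 0:
        for a in range(3):
            t = t + (xs[a] - p0[a]) * d[a]
        t = np.clip(t / L2, 0.0, 1.0)
    dist2 = np.zeros(tuple(i1 - i0))
    for a in range(3):
        dist2 = dist2 + (xs[a] - (p0[a] + t * d[a])) ** 2
    region = dist2 <= radius**2
    out[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]] |= region


def _grow_tree(
    out: np.ndarray,
    grid: Grid,
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    radius: float,
    generations: int,
    rng: np.random.Generator,
    radius_decay: float = 0.7,
    length_decay: float = 0.72,
    branch_angle: float = 0.55,
) -> None:
    """Recursive binary branching tube tree (depth = ``generations`` splits)."""
    end = start + length * direction
    _rasterize_tube(out, grid, start, end, radius)
    if generations == 0:
        return
    # two children, tilted by branch_angle in opposite azimuthal directions
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n1 = np.cross(direction, ref)
    n1 /= np.linalg.norm(n1)
    phi = rng.uniform(0, np.pi)
    n2 = np.cross(direction, n1)
    for sign in (+1.0, -1.0):
        axis = np.cos(phi) * n1 + np.sin(phi) * n2
        child_dir = np.cos(branch_angle) * direction + sign * np.sin(
            branch_angle
        ) * axis
        child_dir /= np.linalg.norm(child_dir)
        jitter = rng.normal(scale=0.05, size=3)
        child_dir = child_dir + jitter
        child_dir /= np.linalg.norm(child_dir)
        _grow_tree(
            out,
            grid,
            end,
            child_dir,
            length * length_decay,
            radius * radius_decay,
            generations - 1,
            rng,
            radius_decay,
            length_decay,
            branch_angle,
        )


def lung_centers(grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Physical centres of the right and left phantom lungs."""
    ext = np.array(grid.extent)
    org = np.array(grid.origin)
    right = org + ext * np.array([0.5, 0.28, 0.5])
    left = org + ext * np.array([0.5, 0.72, 0.5])
    return right, left


def make_lung_phantom(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
) -> tuple[Volume, Volume, Volume]:
    """Two ellipsoidal lungs with five lobes and a branching vessel tree.

    Returns ``(lobes, vessel_mask, lung_mask)``.  The right lung is split
    by two oblique planes into upper/middle/lower lobes, the left by one
    plane into upper/lower; labels follow the RUL..LLL convention.  The
    vessel tree has three generations of binary branching with radius
    decay 0.7.  Deterministic given the seed.
    """
    if min(shape) < 48:
        raise ValueError("phantom shape must be at least 48 voxels per axis")
    grid = Grid(tuple(shape), tuple(spacing))
    rng = np.random.default_rng(seed)
    ext = np.array(grid.extent)
    c_right, c_left = lung_centers(grid)

    jitter = 1.0 + rng.uniform(-0.03, 0.03, size=(2, 3))
    ax_right = ext * np.array([0.22, 0.155, 0.38]) * jitter[0]
    ax_left = ext * np.array([0.22, 0.150, 0.36]) * jitter[1]

    right = _ellipsoid_mask(grid, c_right, ax_right)
    left = _ellipsoid_mask(grid, c_left, ax_left)
    lung = right | left
    if not (right.any() and left.any()):
        raise ValueError("phantom shape too small to hold both lungs")

    coords = grid.coords()
    lobes = np.zeros(grid.shape, dtype=np.int16)
    # oblique split score: mostly apico-basal (z) with an oblique x component
    score = coords[..., 2] + 0.35 * coords[..., 0]
    r_scores = score[right]
    q_low, q_high = np.quantile(r_scores, [0.40, 0.75])
    lobes[right & (score > q_high)] = 1  # RUL
    lobes[right & (score <= q_high) & (score > q_low)] = 2  # RML
    lobes[right & (score <= q_low)] = 3  # RLL
    l_scores = score[left]
    q_mid = np.quantile(l_scores, 0.5)
    lobes[left & (score > q_mid)] = 4  # LUL
    lobes[left & (score <= q_mid)] = 5  # LLL
    if len(np.unique(lobes)) != 6:
        raise ValueError("phantom shape too small to hold 5 non-empty lobes")

    vessels = np.zeros(grid.shape, dtype=bool)
    for center, axlen in ((c_right, ax_right), (c_left, ax_left)):
        start = center + np.array([0.0, 0.0, 0.55 * axlen[2]])
        direction = np.array([0.0, 0.0, -1.0])
        _grow_tree(
            vessels,
            grid,
            start,
            direction,
            length=0.45 * axlen[2],
            radius=0.035 * ext[2],
            generations=3,
            rng=rng,
        )
    vessels &= lung

    return (
        Volume(lobes, grid, kind="label"),
        Volume(vessels, grid, kind="label"),
        Volume(lung, grid, kind="label"),
    )


# ---------------------------------------------------------------------------
# Tissue-conserving image synthesis
# ---------------------------------------------------------------------------


#: width (voxels) of the partial-volume blur applied to vessels in the image
VESSEL_PV_SIGMA = 0.7


def _fraction_parts(lung_mask: Volume, vessel_mask: Volume) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant base fraction and smooth vessel excess.

    The base is parenchyma inside the lung, soft tissue outside. Vessels
    contribute a compactly smoothed excess on top of the parenchyma
    (partial-volume model, as in CT): the blur conserves the vessel tissue
    total while making the in-lung fraction piecewise smooth, which keeps
    discrete tissue sums accurate after warping. The excess is clipped to
    the lung so the body fraction stays exactly FRACTION_BODY.
    """
    from scipy.ndimage import gaussian_filter

    in_lung = lung_mask.data.astype(bool)
    base = np.where(in_lung, FRACTION_PARENCHYMA, FRACTION_BODY).astype(float)
    hard = np.where(
        vessel_mask.data.astype(bool), FRACTION_VESSEL - FRACTION_PARENCHYMA, 0.0
    )
    excess = gaussian_filter(hard, sigma=VESSEL_PV_SIGMA, truncate=2.0, mode="constant")
    excess = np.where(in_lung, np.clip(excess, 0.0, 1.0 - FRACTION_PARENCHYMA), 0.0)
    return base, excess


def tissue_fraction_image(lung_mask: Volume, vessel_mask: Volume) -> Volume:
    """Expiration-state tissue fraction: parenchyma 0.2, body 1.0, vessels
    a partial-volume peak on top of the parenchyma."""
    base, excess = _fraction_parts(lung_mask, vessel_mask)
    return Volume(base + excess, lung_mask.grid, kind="density")


def fraction_to_hu(
    fraction: np.ndarray, hu_air: float = HU_AIR, hu_tissue: float = HU_TISSUE
) -> np.ndarray:
    """Linear air/tissue mixture: HU = hu_air + f * (hu_tissue - hu_air)."""
    return hu_air + fraction * (hu_tissue - hu_air)


def synthesize_image_pair(
    lung_mask: Volume,
    vessel_mask: Volume,
    deformation,
    hu_air: float = HU_AIR,
    hu_tissue: float = HU_TISSUE,
) -> tuple[Volume, Volume]:
    """Build an expiration/inspiration HU pair conserving tissue volume.

    ``deformation`` may be an :class:`AnalyticDeformation` (closed-form
    inverse gradients are used) or a :class:`DisplacementField` (numerical
    differentiation and interpolation are used).  The inspiration image at
    voxel y is the expiration tissue fraction pulled back through phi^-1
    and divided by the local volume change J(phi^-1(y)), so that total
    tissue volume is conserved under the deformation.
    """
    grid = lung_mask.grid
    base, excess = _fraction_parts(lung_mask, vessel_mask)
    f_exp = Volume(base + excess, grid, kind="density")

    if isinstance(deformation, DisplacementField):
        from .tensor_metrics import deformation_gradient, jacobian_from_field

        jac = jacobian_from_field(deformation)
        from .interp import invert_displacement

        inv = invert_displacement(deformation)
        x_inv = grid.coords() + inv.vectors
        j_at_inv = sample_at_points(jac, grid, x_inv)
        j_on_grid = jac
    else:
        y = grid.coords()
        x_inv = deformation.inverse_at(y, tol_mm=1e-3 * min(grid.spacing))
        j_at_inv = deformation.jacobian_at(x_inv)
        j_on_grid = deformation.jacobian_map(grid)

    if np.any(j_on_grid[lung_mask.data.astype(bool)] <= 0):
        raise ValueError("deformation folds (J <= 0) inside the lung")

    # the piecewise-constant base (body vs parenchyma) is looked up by
    # nearest neighbour so no body/parenchyma contrast bleeds across the
    # lung boundary; the smooth vessel excess is interpolated trilinearly;
    # the 1/J factor varies smoothly.
    base_at_inv = sample_at_points(base, grid, x_inv, order=0)
    excess_at_inv = sample_at_points(excess, grid, x_inv, order=1)
    f_insp = (base_at_inv + excess_at_inv) / j_at_inv
    ct_exp = Volume(fraction_to_hu(f_exp.data, hu_air, hu_tissue), grid, kind="hu")
    ct_insp = Volume(fraction_to_hu(f_insp, hu_air, hu_tissue), grid, kind="hu")
    return ct_exp, ct_insp


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class PhantomSubject:
    """One synthetic subject: geometry, ground-truth deformation, CT pair."""

    subject_id: str
    stage: int
    lobes: Volume
    vessel_mask: Volume
    lung_mask: Volume
    deformation: AnalyticDeformation
    true_dvf: DisplacementField
    target_mean_j: float
    ct_expiration: Volume | None = None
    ct_inspiration: Volume | None = None


def _cohort_deformation(grid: Grid, rng: np.random.Generator) -> SumDeformation:
    """Unit-amplitude cohort deformation: per-lung radial expansion plus a
    low-frequency sinusoidal perturbation for spatial heterogeneity."""
    ext = np.array(grid.extent)
    c_right, c_left = lung_centers(grid)
    sigma = 0.30 * float(np.mean(ext))
    parts = [
        RadialDeformation(c_right, 1.0, sigma),
        RadialDeformation(c_left, 1.0, sigma),
    ]
    # small fixed-amplitude long-wavelength perturbation, seeded per subject
    k = 2.0 * np.pi / (1.5 * float(ext[2]))
    amp = 0.01 * float(ext[2]) * rng.uniform(0.5, 1.0)
    parts.append(SinusoidalDeformation(amp, k, axis=int(rng.integers(0, 3))))
    return SumDeformation(parts)


def _calibrate_expansion(
    base: SumDeformation, lung_pts: np.ndarray, target_mean_j: float
) -> ScaledDeformation:
    """Scale the radial parts so the lung-mean closed-form J hits the target."""
    radial = SumDeformation(base.parts[:2])
    perturb = base.parts[2]

    def mean_j(s: float) -> float:
        d = SumDeformation([ScaledDeformation(radial, s), perturb])
        return float(np.mean(d.jacobian_at(lung_pts)))

    f = lambda s: mean_j(s) - target_mean_j
    s_lo, s_hi = 0.0, 0.05
    while f(s_hi) < 0 and s_hi < 4.0:
        s_hi *= 2.0
    s = optimize.brentq(f, s_lo, s_hi, xtol=1e-6)
    scaled = SumDeformation([ScaledDeformation(radial, s), perturb])
    return scaled


def moving_frame_labels(labels: Volume, deformation: AnalyticDeformation) -> Volume:
    """Push a reference-frame label map into the moving (inspiration) frame.

    The moving-frame map at y is the reference label at phi^-1(y)
    (nearest-neighbour); this is how the phantom's inspiration-state lobes
    and vessels are produced from the expiration-state segmentations.
    """
    grid = labels.grid
    x_inv = deformation.inverse_at(grid.coords(), tol_mm=1e-3 * min(grid.spacing))
    data = sample_at_points(labels.data, grid, x_inv, order=0)
    return Volume(data.astype(np.asarray(labels.data).dtype), grid, kind="label")


def make_cohort(
    n_per_stage: int,
    stage_expansion_means: tuple[float, ...] = (1.8, 1.6, 1.4, 1.2, 1.05),
    noise_sd: float = 0.05,
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    with_images: bool = True,
) -> list[PhantomSubject]:
    """Staged cohort with decreasing mean expansion across disease stages.

    Subject i in stage s receives a smooth radial deformation calibrated so
    its lung-mean closed-form J equals a draw from
    Normal(stage_expansion_means[s], noise_sd^2) (truncated above 1).
    Deterministic given the seed.
    """
    means = np.asarray(stage_expansion_means, dtype=float)
    if np.any(np.diff(means) >= 0):
        raise ValueError("stage_expansion_means must be strictly decreasing")
    if np.any(means <= 1):
        raise ValueError("stage_expansion_means must all exceed 1")
    subjects: list[PhantomSubject] = []
    for stage, mean in enumerate(means):
        for i in range(n_per_stage):
            ss = np.random.SeedSequence([seed, stage, i])
            rng = np.random.default_rng(ss)
            geom_seed = int(rng.integers(0, 2**31 - 1))
            lobes, vessels, lung = make_lung_phantom(shape, spacing, seed=geom_seed)
            grid = lung.grid
            target = float(max(1.01, rng.normal(mean, noise_sd)))
            base = _cohort_deformation(grid, rng)
            lung_pts = grid.coords()[lung.data.astype(bool)]
            deformation = _calibrate_expansion(base, lung_pts, target)
            dvf = deformation.to_field(grid)
            ct_exp = ct_insp = None
            if with_images:
                ct_exp, ct_insp = synthesize_image_pair(lung, vessels, deformation)
            subjects.append(
                PhantomSubject(
                    subject_id=f"S{stage}{i:03d}",
                    stage=stage,
                    lobes=lobes,
                    vessel_mask=vessels,
                    lung_mask=lung,
                    deformation=deformation,
                    true_dvf=dvf,
                    target_mean_j=target,
                    ct_expiration=ct_exp,
                    ct_inspiration=ct_insp,
                )
            )
    return subjects


def simulate_subject_means(
    n_per_stage: int,
    stage_expansion_means: tuple[float, ...] = (1.8, 1.6, 1.4, 1.2, 1.05),
    noise_sd: float = 0.05,
    seed: int = 0,
) -> "np.ndarray":
    """Subject-level mean-J draws at summary scale (no images).

    Returns an array of shape ``(n_stages, n_per_stage)`` using the same
    per-subject noise model as :func:`make_cohort`; used for trend power
    simulations where building image volumes would add nothing.
    """
    means = np.asarray(stage_expansion_means, dtype=float)
    if np.any(np.diff(means) >= 0):
        raise ValueError("stage_expansion_means must be strictly decreasing")
    out = np.empty((len(means), n_per_stage))
    for stage, mean in enumerate(means):
        for i in range(n_per_stage):
            rng = np.random.default_rng(np.random.SeedSequence([seed, stage, i]))
            rng.integers(0, 2**31 - 1)  # keep draw order aligned with make_cohort
            out[stage, i] = max(1.01, rng.normal(mean, noise_sd))
    return out
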