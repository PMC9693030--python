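# Methods

This note records the models, conventions and numerical choices behind
`lungmech`, and the known limits of the synthetic data generator.

## 1. Deformation model and conventions

All analysis starts from a displacement field `u(x)` defined on the
reference (end-expiration) grid, mapping a reference point `x` to its
corresponding point `x + u(x)` in the moving (end-inspiration) frame.
Values are millimetres in physical space. With this convention the
deformation gradient is `F = I + ∇u` and the Jacobian determinant
`J = det F` exceeds 1 where the lung expands during inhalation. The
convention is recorded in the JSON sidecar written next to every stored
displacement field.

Spatial derivatives of `u` are central second-order finite differences in
mm (one-sided at the grid boundary); regional summaries exclude the
one-voxel boundary shell where the one-sided stencils apply.

## 2. Tensor metrics

Principal stretches `λ1 ≥ λ2 ≥ λ3` are square roots of the eigenvalues of
the right Cauchy–Green tensor `C = FᵀF` (symmetric eigensolver). Voxels
with `det F ≤ 0` or non-finite entries are marked invalid and excluded.

Derived maps:

- `J = λ1 λ2 λ3` (also available directly as `det(I + ∇u)`; both routes
  agree to floating-point accuracy and this is tested);
- anisotropic deformation index
  `ADI = sqrt(((λ1−λ2)/λ2)² + ((λ2−λ3)/λ3)²)`, zero iff the local
  deformation is isotropic;
- slab–rod index
  `SRI = (2/π)·arctan(λ3(λ1−λ2) / (λ2(λ2−λ3)))`, computed with `arctan2`
  so the rod limit `λ2 = λ3` evaluates to exactly 1 and the slab limit
  `λ1 = λ2` to exactly 0. Where `ADI = 0` the ratio is 0/0 and the local
  shape is undefined; SRI is set to NaN with an explicit validity mask.
- distortion components `α = sign(J−1)(λ2/λ3 − 1)` and
  `β = sign(J−1)(λ1/λ2 − 1)`; both vanish for isotropic deformation and
  share the sign of the volume change.

## 3. Tissue-volume-preserving registration

The registration minimizes

```
C = γ1/|Ω| Σ_Ω (I_f(x) − J(x) I_m(x+u(x)))²          (SSTVD)
  + γ2/|Ω| Σ_Ω (V_f(x) − V_m(x+u(x)))²               (SSVMD)
  + γ3/|Ω_i| Σ_{Ω_i} ‖L u(x)‖²                        (elastic)
```

where `I_f`, `I_m` are tissue-density images obtained from HU by the
air/tissue mixture model `ρ = clamp((HU + 1000)/1055, 0, 1)`, `V_f`, `V_m`
are multiscale Frangi vesselness maps, `Ω` is the dilated fixed lung mask
and `L = −0.75∇² − 0.25∇(∇·)` is a linear elasticity operator.
`γ1 = γ2 = 1`; `γ3 = 0.05` was fixed a priori so the elastic term
contributes a few percent of the initial similarity cost on the phantom.

`u` is a cubic B-spline free-form deformation. Displacements, their
spatial gradients and hence `J` are evaluated analytically from the
tensor-product basis; the cost gradient with respect to the coefficients
is the exact adjoint projection of the voxelwise gradients (the
`∂J/∂∇u` term uses the cofactor matrix of `I + ∇u`). The elastic
operator uses symmetric stencils with zero padding, which makes the
discrete operator self-adjoint and the elastic gradient exact; the full
analytic gradient is verified against finite differences in the test
suite using globally linear images, for which the interpolant's image
gradient is exact and no discretization error enters the check.

Optimization is multiresolution gradient descent with Armijo
backtracking (accepted costs are monotone non-increasing by
construction, and the trace of accepted costs per level is returned).
Each level downsamples by an integer factor after Gaussian smoothing and
refits the current transform's coefficients on the finer level by an
exact axis-wise least-squares fit. The default desk-scale schedule is
`(factor 4, knots 8 mm, 80 it) → (2, 8 mm, 60) → (1, 4 mm, 40)`,
keeping a coarse-to-fine structure with knot refinement at sizes
tractable on one CPU; larger volumes warrant more levels.

## 4. Registration quality metrics

- **LDC** — unweighted mean Dice coefficient over the five lobes.
- **W10SE** — for each vertex of one lung surface, the exact
  closest-point distance to the other triangulated surface (the closest
  point may lie inside a face or on an edge/vertex; a vectorized
  barycentric-region classification computes it). The mean of the worst
  10% of distances is taken per direction and the directions averaged.
  A KD-tree on triangle centroids prunes candidate triangles; a point is
  only accepted when the pruned minimum is certifiably exact
  (`d ≤ d_k_max − r_max`), otherwise a radius query guaranteed to contain
  the true nearest triangle is used, so the pruned computation equals
  brute force exactly (tested to 1e−9).
- **VTPE** — symmetric mean distance between binary vessel masks, using
  the exact Euclidean distance transform of voxel centres with physical
  spacing.
- **SCSE** — symmetric mean closest-point distance between vessel
  skeletons obtained by 3D topological thinning.

Surfaces come from marching cubes on the zero-padded mask (so they are
closed even when the structure touches the grid edge), with degenerate
faces removed.

## 5. Preprocessing

Isotropic resampling (trilinear for intensities, nearest-neighbour for
labels), union-bounding-box cropping with margin, multiscale Hessian
vesselness (Frangi by default; scale in mm is converted to Gaussian σ in
voxels on the isotropic grid), and Otsu binarization on a 256-bin
histogram with `value ≥ threshold`. Constant images are rejected rather
than thresholded. A caveat found while testing: exhaustive cut-point
search can tie exactly across empty histogram bins between well-separated
classes; any tied cut induces the same partition, and the tests compare
partitions rather than raw thresholds.

## 6. Synthetic data generator

The phantom is first-class, tested code:

- **Geometry.** Two jittered ellipsoidal lungs; the right lung is split
  by oblique-plane quantiles into three lobes, the left into two; a
  three-generation branching vessel tree of capsules (radius and length
  decay per generation) rasterized inside each lung.
- **Deformation.** Per-lung radial expansions with Gaussian falloff plus
  a low-frequency sinusoidal perturbation; displacement, deformation
  gradient and Jacobian have closed forms throughout, so the generator
  provides exact ground truth for every map. The amplitude is calibrated
  by root finding so the lung-mean analytic `J` hits a target drawn from
  `Normal(stage mean, noise SD)` per subject; stage means decrease with
  disease stage.
- **Images.** The expiration image is a tissue fraction: a
  piecewise-constant base (parenchyma 0.2 inside the lung, soft tissue
  1.0 outside) plus a vessel excess blurred with a compact Gaussian
  (σ = 0.7 voxel, sum-preserving) — a partial-volume model, as in real
  CT. HU follows from the air/tissue mixture. The inspiration image
  enforces tissue conservation: `f_insp(y) = f_exp(φ⁻¹(y)) / J(φ⁻¹(y))`.
  The base is looked up by nearest neighbour (a trilinear lookup would
  blend body and parenchyma fractions across the lung boundary and break
  conservation), the smooth vessel excess is interpolated trilinearly,
  and the piecewise-smooth integrand keeps the discrete tissue sum
  accurate to well under 1% at 64³. Folding deformations (`J ≤ 0`
  anywhere) are rejected.

Realism limits: no airways, no sliding at the pleura, piecewise-constant
materials, smooth single-mode deformations, no noise or reconstruction
artifacts, and desk-scale resolution (≥48³). The generator supports
methodological validation — recovery of known fields and trends — not
claims about clinical effect sizes.

## 7. Cohort statistics

Per region (five lobes and whole lung), six measures: mean, SD, RMS and
64-bin Shannon entropy (bits) of `J`, mean ADI, and entropy of SRI.
Entropy uses fixed ranges (`J`: [0, 4] clipped, `SRI`: [0, 1],
`ADI`: [0, 4]) so values are comparable across subjects; SD uses the
n−1 denominator. Stage trends are reported as group means with a strict
monotonicity flag plus Spearman rank correlation as an effect size.
Method agreement uses Bland–Altman limits `mean difference ± 1.96 SD`
of the paired differences. Failed subjects are recorded with a reason
and excluded; the remainder of the cohort is processed.

One terminology note: some sources refer interchangeably to the
"entropy" and "energy" of SRI; this package implements entropy as
defined above.

## 8. Numerical choices worth knowing

- Eigenvalues of `C` are floored at 1e−12 before the square root;
  non-physical voxels are masked, not clipped into plausibility.
- The analytic inverse `inverse_at` uses Newton iteration
  `x ← x − F(x)⁻¹(φ(x) − y)` (closed-form `F`), tolerance 1e−3 voxel,
  max 50 iterations: exact for affines and quadratically convergent on
  the smooth cohort fields, where a plain fixed-point update would
  diverge for gradients of order one. Dense displacement fields without
  closed forms are inverted by fixed-point iteration
  (`invert_displacement`), which suffices for the small smooth fields it
  is used on.
- All randomness flows through `numpy.random.Generator` seeded by
  explicit `SeedSequence` hierarchies; every generator output is
  deterministic given its seed, and the optimizer itself is
  deterministic.
- The phantom's trend-power simulation draws subject-level mean-J values
  at summary scale with the same RNG stream alignment as the image-level
  generator, so summary-scale and image-level cohorts share targets
  exactly (tested).
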