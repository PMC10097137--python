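# Methods

`longtbss` implements a longitudinal white-matter microstructure analysis
for two-visit diffusion MRI: per-visit diffusion-tensor maps, unbiased
participant-midspace registration, skeleton-restricted group statistics on
baseline-minus-final change maps, and permutation inference with
threshold-free cluster enhancement (TFCE). A synthetic cohort generator
with complete ground truth closes the loop: every stage of the pipeline is
validated against quantities it must, by construction, recover.

## Diffusion tensor model

The signal model is monoexponential Stejskal–Tanner,
`S_i = S0 · exp(−b_i · gᵢᵀ D gᵢ)`, with `D` the symmetric 3×3 diffusion
tensor in mm²/s. Fitting is ordinary least squares on the log signal with
the standard 7-column design (log S0 plus the six unique tensor
components); weighted variants were deliberately not implemented — OLS is
deterministic, exactly invertible on noiseless data (the round-trip test
holds to 1e-9), and is the default of the widely used reference tools.
Multiple b=0 volumes enter the regression as separate rows (no
pre-averaging), preserving the noise model. Voxels with nonpositive
diffusion-weighted intensities lose those rows if at least 7 usable,
rank-sufficient rows remain; otherwise the voxel is dropped from the mask
and counted. Negative eigenvalues (a noise effect) are clamped to zero for
the scalar maps, with the raw tensor retained; the clamp count is logged.
Scalar maps use the standard definitions: FA is the normalized eigenvalue
dispersion (0 where all eigenvalues vanish), MD the eigenvalue mean, AD
the largest eigenvalue, RD the mean of the two smaller ones.

The default acquisition scheme is a single shell of 42 unique directions
at b = 1000 s/mm² plus 7 b=0 volumes, the clinical protocol the simulator
emulates. Directions are a deterministic golden-spiral hemisphere set
(full design-matrix rank, condition number ~1.4e3 including the b-scale);
any valid per-subject scheme (e.g. a single b=0 volume) is accepted.

## Halfway (midspace) registration

Interpolating one visit into the other's space biases longitudinal change
toward the resampled visit. Instead, the between-visit rigid transform is
estimated in both directions with an intensity-based registration; the
two estimates of the forward map, `A_fwd` and `A_bwd⁻¹`, are blended
through the matrix logarithm, `L = (log A_fwd + log A_bwd⁻¹)/2`, and the
halves are `H_base = exp(L/2)` and `H_follow = exp(−L/2)`. This blend is
exact for pure translations (half translation) and pure rotations (half
angle), satisfies `H_follow⁻¹ ∘ H_base = exp(L)` by construction, and —
because swapping the visits negates `L` — makes the midspace template
exactly symmetric under visit exchange. Rigid halves are re-orthonormalized
by SVD against `expm` round-off. Each visit is resampled exactly once
(transforms are composed, never cascaded; the `Image.n_interp` counter
enforces this), and the midspace FA template is the voxelwise mean of the
two half-resampled maps.

The registration itself is a deterministic multi-resolution scheme (default
pyramid factors 2, 1 with Gaussian anti-aliasing): a translation grid
search (±10 voxels, 2-voxel step) at the coarsest level, a per-axis
rotation sweep (±15°, step 2.5°·factor) at every level, and
Levenberg–Marquardt refinement of the mean-squared intensity difference at
each level. Two implementation details matter in practice and were chosen
after observing failure modes on phantoms:

- The LM Jacobian is assembled analytically from the moving image's
  spatial gradient (chain rule through the transform), not by finite
  differences of the cost. Trilinear interpolation makes the cost
  non-smooth exactly at integer-grid alignment — the point a longitudinal
  registration starts from — and finite-difference steps across that kink
  stall the optimizer.
- Residuals are evaluated on a structure mask (a dilated threshold of the
  smoothed fixed image, anchored between the background median and the
  peak). In FA maps of tube phantoms — and of brains — the structured
  voxels are a minority; the noise-only background otherwise flattens the
  cost gradient and quintuples the registration error.

A 12-dof affine parameterization (scales + shears) is available by flag;
6-dof rigid is the default for within-subject visits. A correlation-ratio
cost is available (Powell refinement) for inputs without shared intensity
units. Failure is explicit, mirroring how longitudinal studies exclude
subjects: constant images, an optimizer that ends worse than the identity,
or forward/backward estimates whose round trip moves a field-of-view
corner by more than 0.5 voxel all raise a registration error, and the
pipeline records the subject's exclusion with the reason rather than
averaging a misregistered pair. On the default noisy smoke cohort the
measured exclusion rate is a few percent, comparable to what longitudinal
DTI studies report.

## Group template, skeleton, projection

Midspace FA maps are aligned to an evolving mean (initialized at the first
subject, two refinement rounds, rigid by default) to form the group mean-FA
template; at phantom scale this stands in for the nonlinear warp to a
standard-space FA template that whole-brain TBSS would use, a documented
limitation of the desk-scale design. Subjects whose alignment fails are
dropped and logged.

The skeleton is the set of voxels with mean FA above the threshold
(default 0.2) that are local maxima of the smoothed mean FA (σ = 1 voxel)
across the local ridge. The cross-ridge direction is taken from the
center-of-gravity offset of the 3×3×3 FA neighborhood when that offset is
informative (> 0.05 voxel), and from the strongest-curvature Hessian
eigenvector at ridge centers where the offset degenerates to zero. A
Hessian-only rule was tried first and rejected: on a Gaussian tube profile
the second derivative across the tube vanishes on the inflection ring
(one cross-section radius out), where the largest-magnitude eigenvector
rotates into the tangential direction and admits a thick, cross-shaped
skeleton. The hybrid rule reproduces analytic centerlines of straight
tubes, parallel tube pairs, and arcs at Dice ≥ 0.9 with single-voxel
thickness. Voxels on the volume faces are excluded (derivatives are
unreliable there). Raising the threshold can only shrink the skeleton.

Projection fills each skeleton voxel with the maximum of the subject's FA
along the perpendicular search directions, sampled trilinearly every 0.5
voxel up to 4 voxels (configurable). Voxels whose two cross-ridge
curvatures are comparable (ratio > 0.5) are tube-like: there is no single
meaningful perpendicular, so the search fans over eight evenly spaced
directions in the plane orthogonal to the ridge tangent — the same
special-casing classic TBSS applies to tube-like skeleton voxels. Ties
prefer the smaller displacement, then the positive direction. The chosen
displacement vector is recorded per skeleton voxel and reused verbatim for
MD/AD/RD: non-FA metrics inherit FA's projection geometry and are never
re-searched. Each visit's metric maps reach the common grid through a
single composed transform (native → midspace → common grid), so projection
operates on once-interpolated data.

## Change maps and inference

Change is baseline minus final visit per skeleton voxel: FA decline over
time is a positive delta, diffusivity increase a negative delta. Results
are labeled in "carrier shows decline/increase" vocabulary so the
subtraction convention cannot be misread. Change maps are not annualized;
with a constant within-cohort interval the t statistic is scale-invariant,
so annualization would not change any inference (asserted by test).
Cohorts are analyzed separately.

Inference is a permutation GLM: per-voxel OLS with the predictor of
interest (carrier indicator, or one baseline clinical score in the
carriers-only analyses) plus nuisance covariates (age, sex, site; dummy
coding in alphabetical order, single-level factors dropped with a log
line, intercept always present). The t map's positive part is enhanced
with TFCE, `TFCE(v) = Σ_h e(h,v)^E · h^H · Δh` with H = 2, E = 1 and 100
uniform threshold steps (midpoint rule; an isolated voxel of height h
receives h^(H+1)/(H+1) to discretization accuracy), using 26-connectivity
restricted to skeleton voxels — the skeleton-optimized TFCE variant. The
TFCE core is an incremental union-find over descending thresholds
(numba-compiled), making 500-permutation runs on desk-scale skeletons a
matter of milliseconds.

The null distribution follows the Freedman–Lane scheme: the response is
residualized against the nuisance-only model, residual rows are permuted
(seeded generator; deterministic for a fixed seed), the full model is
refit, and the maximum TFCE over the skeleton is recorded. Family-wise
corrected p-values use the +1 convention,
`pfwe(v) = (1 + #{perm max ≥ TFCE(v)}) / (n_perm + 1)`, so p is never 0
and is monotone nonincreasing in the observed TFCE. Each direction of a
contrast is a separate one-sided test at α = 0.05 (recorded in the result
metadata); both directions share one permutation pass, so flipping the
contrast sign exactly exchanges the pair. With intercept-only nuisance the
scheme reduces exactly to label permutation (verified by exhaustive
enumeration at n = 6). The reference analysis used 5000 permutations;
that is the library default, with 500 used in the desk-scale suites for
p-resolution of 1/501.

## Synthetic cohorts

The generator emulates a two-group (control vs. HD-expansion-carrier),
two-visit study. White matter is a set of tube phantoms — by default a
straight association-bundle-like tube and an arc commissural-like sweep on
a 48³ grid of 2 mm voxels (24³ for smoke runs) — of prolate tensors whose
principal axis follows the local centerline tangent. The FA profile is
exactly Gaussian across the cross-section (σ = radius/2), peaking at the
nominal value (default 0.6–0.65) on the axis, with MD blending from the
tract value (0.75e-3 mm²/s) to the isotropic background (0.7e-3 mm²/s).
Longitudinal change is injected in the eigenvalues — lowering the
anisotropy split and/or raising MD — so FA decline and diffusivity
increase are mutually consistent physics rather than independent dials.
Default injected changes: −0.03 axis FA in the straight tract and
+0.04e-3 mm²/s MD in the arc over the between-visit interval, carriers
only, scaled per subject by a magnitude multiplier ~ N(1, 0.3) clipped to
[0.2, 2].

Each visit gets an independent rigid pose (uniform within ±2 voxels, ±3°;
the phantom is re-evaluated analytically in the moved frame with rotated
tensor orientation, so misalignment introduces no interpolation), forward
signals via the Stejskal–Tanner model, and Rician noise
`√((S+ε₁)² + ε₂²)` with σ = S0/20 (b0 SNR 20, typical clinical DWI).
Clinical scores are drawn around published group means of the two
reference cohorts (e.g. carrier TMS 7.4 in the low-burden preset, 18.7 in
the manifest preset) with additive Gaussian noise, and carrier scores are
coupled to the subject's change magnitude (TMS k = +6 to +10 points per
unit magnitude, SDMT/SWR/TFC negative) — strong enough to be detectable
at full preset size (67/77 and 33/49 subjects), realistic enough to be
marginal at smoke scale. CAG repeats are integer draws near 43 (floor 39
or 40 by preset); disease burden is Age × (CAG − 35.5). All latent truth
(poses, per-subject magnitudes, affected-tract masks at half-maximum
cross-section weight, couplings) is recorded, and
`truth_mask_on_grid` carries affected masks into any analysis grid by
registering the noise-free phantom FA to that grid's template.

What the generator does not emulate — and hence what green tests do not
establish about real data: brain anatomy and crossing fibers, eddy/
susceptibility distortion, multi-site intensity effects, nonlinear
anatomy-to-standard-space warps, subject dropout, and floor/ceiling
behavior of real clinical scales beyond simple clipping.

## Composite clinical scores

The composite UHDRS is the fixed linear combination
`(TFC−10.4)/1.9 − (TMS−29.7)/14.9 + (SDMT−28.4)/11.3 + (SWR−66.1)/20.1 + 10`
(higher is better on every component except TMS). Because the score is
linear, the score of group means equals the group mean score, which is
what licenses checking published group-level composites from published
subscale means; the worked examples reproduce the four published group
values within ±0.03 (the propagated rounding of two-decimal inputs; one
published carrier value sits ~0.02 from the formula applied to its printed
means, plausibly per-subject missingness, so exactness is not forced).
Subjects missing any component are dropped from composite-based analyses
and logged; nothing is imputed. The disease burden score is
Age × (CAG − 35.5), zero at the 35.5-repeat threshold by construction.

## Numerical and design choices

- Transforms act on world (mm) coordinates via the NIfTI affine; voxel
  indices are 0-based; resampling is pull-style (target voxel → source
  coordinate through the inverse map), trilinear or nearest, zero outside
  the field of view. Identity transforms on identical grids take an exact
  no-interpolation path, which is what makes identical-visit change maps
  exactly zero end to end.
- Zero residual variance at a voxel yields t = 0 (with a warning count),
  including variance indistinguishable from accumulated round-off.
- An empty skeleton is a valid (warned) outcome, not an error.
- Pipeline runs are idempotent per configuration hash; re-runs with an
  unchanged configuration are skipped unless forced. Visual-inspection QC
  of interactive pipelines is replaced by manifest numbers: per-subject
  registration diagnostics, skeleton voxel count, change-map distribution
  summaries, and a machine-readable exclusion reason per dropped subject.
- Problem sizes in the shipped suites: 24³ grids, 15–20 subjects per
  group, 100–500 permutations — sizes at which the full pipeline runs in
  about a minute while leaving the permutation p-resolution meaningful.
  The full presets (67/77 and 33/49 subjects, 48³) use the same code
  paths.

## Known limitations

Rigid (or affine) registration only — no nonlinear warps, so the
common-grid alignment relies on the subjects sharing geometry up to a
rigid pose, true for phantoms and approximately true for the within-study
brain templates the design targets. Registration of a single straight
tube is ill-posed (translation along and rotation about the axis are
unconstrained); realistic phantoms need at least two non-parallel
structures. The skeleton's perpendicular estimate assumes ridge-like
structure; junction topology (crossing skeleton sheets) is not modeled.
One-sided α = 0.05 per direction means the two directions jointly control
FWER at 0.1 for a two-sided reading.
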