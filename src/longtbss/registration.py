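"""Symmetric two-visit linear registration into a participant midspace.

Longitudinal change estimates are biased when one visit is interpolated
into the other's space but not vice versa. The halfway (midspace)
construction avoids this: the between-visit transform is estimated in both
directions, symmetrized, and split into two half-transforms so that both
visits are resampled exactly once, into the geometric midpoint of the
visit pair. The midspace FA template is the voxelwise average of the two
half-resampled maps.

Transforms operate on world (mm) coordinates via the NIfTI affine; voxel
indices are 0-based throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, ndimage, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "Image",
    "AffineTransform",
    "MidspacePair",
    "RegistrationError",
    "register_affine",
    "halfway_transforms",
    "resample",
    "build_midspace",
]


class RegistrationError(RuntimeError):
    """Between-visit registration failed (subject excluded downstream)."""


@dataclass
class Image:
    """A 3D map with its voxel-to-world affine.

    ``n_interp`` counts how many interpolation passes the data has been
    through since native space; the longitudinal pipeline asserts that it
    never exceeds 1 (transforms are composed, never cascaded).
    """

    data: np.ndarray
    affine: np.ndarray
    n_interp: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.affine = np.asarray(self.affine, float)
        if self.data.ndim != 3:
            raise ValueError(f"Image must be 3D, got ndim={self.data.ndim}")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_center(self) -> np.ndarray:
        c_vox = (np.asarray(self.data.shape) - 1) / 2.0
        return (self.affine @ np.append(c_vox, 1.0))[:3]


@dataclass(frozen=True)
class AffineTransform:
    """4x4 homogeneous world-to-world mapping with metadata."""

    matrix: np.ndarray  # maps source world coords to target world coords
    dof: int = 6  # 6 rigid | 12 affine
    source: str = ""
    target: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.shape != (4, 4):
            raise ValueError(f"transform matrix must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-9):
            raise ValueError("last row of a homogeneous transform must be (0,0,0,1)")
        if self.dof == 6:
            R = m[:3, :3]
            if not (np.allclose(R @ R.T, np.eye(3), atol=1e-6) and np.linalg.det(R) > 0):
                raise ValueError("rigid transform must have an orthonormal, det +1 rotation block")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls, dof: int = 6, source: str = "", target: str = "") -> "AffineTransform":
        return cls(np.eye(4), dof=dof, source=source, target=target)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(
            np.linalg.inv(self.matrix), dof=self.dof, source=self.target, target=self.source
        )

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return AffineTransform(
            self.matrix @ other.matrix,
            dof=max(self.dof, other.dof),
            source=other.source,
            target=self.target,
        )

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.matrix, np.eye(4), atol=1e-12)


@dataclass
class MidspacePair:
    """Both visits of one subject resampled into their halfway space."""

    half_baseline: Image
    half_followup: Image
    template: Image  # voxelwise average of the two halves
    h_base: AffineTransform  # baseline world -> midspace world
    h_follow: AffineTransform  # followup world -> midspace world


# ---------------------------------------------------------------------------
# transform parameterization


def _param_matrix(params: np.ndarray, dof: int, center: np.ndarray) -> np.ndarray:
    """Build a world transform from optimizer parameters.

    params = [tx, ty, tz (mm), rx, ry, rz (deg)] (+ [sx, sy, sz, hxy, hxz,
    hyz] for 12 dof). Rotation (and scale/shear) is applied about
    ``center`` so translation and rotation are weakly coupled.
    """
    t = params[:3]
    rx, ry, rz = np.deg2rad(params[3:6])
    cx, cy, cz = np.cos([rx, ry, rz])
    sx_, sy_, sz_ = np.sin([rx, ry, rz])
    Rx = np.array([[1, 0, 0], [0, cx, -sx_], [0, sx_, cx]])
    Ry = np.array([[cy, 0, sy_], [0, 1, 0], [-sy_, 0, cy]])
    Rz = np.array([[cz, -sz_, 0], [sz_, cz, 0], [0, 0, 1]])
    A = Rz @ Ry @ Rx
    if dof == 12:
        scales = np.diag(params[6:9])
        shear = np.eye(3)
        shear[0, 1], shear[0, 2], shear[1, 2] = params[9:12]
        A = A @ scales @ shear
    m = np.eye(4)
    m[:3, :3] = A
    m[:3, 3] = t + center - A @ center
    return m


def _matrix_params_identity(dof: int) -> np.ndarray:
    if dof == 12:
        return np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], float)
    return np.zeros(6)


# ---------------------------------------------------------------------------
# resampling


def resample(
    image: Image,
    transform: AffineTransform,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    interp: str = "trilinear",
) -> Image:
    """Pull-resample ``image`` through ``transform`` onto a target grid.

    ``transform`` maps source world coordinates to target world
    coordinates; each target voxel is filled from the source position
    found through the inverse map. Out-of-field voxels are 0. When the
    transform is the identity and the grids coincide the data is returned
    untouched (no interpolation pass is counted), which keeps
    identical-visit pipelines exactly zero-change.
    """
    order = {"trilinear": 1, "nearest": 0}.get(interp)
    if order is None:
        raise ValueError(f"interp must be 'trilinear' or 'nearest', got {interp!r}")
    target_affine = np.asarray(target_affine, float)
    det = np.linalg.det(transform.matrix[:3, :3])
    if abs(det) < 1e-12:
        raise ValueError("singular transform")
    same_grid = tuple(target_shape) == image.data.shape and np.allclose(
        target_affine, image.affine, atol=1e-12
    )
    if transform.is_identity and same_grid:
        return Image(image.data.copy(), image.affine.copy(), n_interp=image.n_interp)

    # target voxel -> target world -> source world -> source voxel
    M = np.linalg.inv(image.affine) @ np.linalg.inv(transform.matrix) @ target_affine
    out = ndimage.affine_transform(
        image.data,
        matrix=M[:3, :3],
        offset=M[:3, 3],
        output_shape=tuple(target_shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return Image(out, target_affine.copy(), n_interp=image.n_interp + 1)


# ---------------------------------------------------------------------------
# registration


def _downsample(img: Image, factor: int, smooth_sigma: float = 0.0) -> Image:
    sigma = max(factor / 2.0 if factor > 1 else 0.0, smooth_sigma)
    sm = ndimage.gaussian_filter(img.data, sigma=sigma) if sigma > 0 else img.data
    if factor == 1:
        return Image(sm, img.affine)
    scale = np.diag([factor, factor, factor, 1.0])
    return Image(sm[::factor, ::factor, ::factor], img.affine @ scale)


def _msd(moving: Image, fixed: Image, matrix: np.ndarray) -> float:
    M = np.linalg.inv(moving.affine) @ np.linalg.inv(matrix) @ fixed.affine
    warped = ndimage.affine_transform(
        moving.data,
        matrix=M[:3, :3],
        offset=M[:3, 3],
        output_shape=fixed.data.shape,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return float(np.mean((warped - fixed.data) ** 2))


def _correlation_ratio(moving: Image, fixed: Image, matrix: np.ndarray, nbins: int = 32) -> float:
    """1 - correlation ratio eta^2 of fixed intensity given binned moving
    intensity (lower is better, matching the MSD convention)."""
    M = np.linalg.inv(moving.affine) @ np.linalg.inv(matrix) @ fixed.affine
    warped = ndimage.affine_transform(
        moving.data, matrix=M[:3, :3], offset=M[:3, 3], output_shape=fixed.data.shape,
        order=1, mode="constant", cval=0.0, prefilter=False,
    ).ravel()
    f = fixed.data.ravel()
    lo, hi = warped.min(), warped.max()
    if hi <= lo:
        return 1.0
    bins = np.clip(((warped - lo) / (hi - lo) * nbins).astype(int), 0, nbins - 1)
    total_var = f.var()
    if total_var == 0:
        return 1.0
    counts = np.bincount(bins, minlength=nbins)
    sums = np.bincount(bins, weights=f, minlength=nbins)
    sqs = np.bincount(bins, weights=f**2, minlength=nbins)
    nz = counts > 0
    within = np.sum(sqs[nz] - sums[nz] ** 2 / counts[nz]) / f.size
    return float(within / total_var)


_COSTS = {"msd": _msd, "corratio": _correlation_ratio}


def _structure_mask(fix: Image) -> np.ndarray:
    """Voxels carrying registrable structure in the fixed image.

    Restricting the least-squares fit to (a dilation of) the structured
    region keeps the large noise-only background from flattening the cost
    gradient, which matters for noisy FA maps whose tracts occupy a small
    fraction of the field of view.
    """
    sm = ndimage.gaussian_filter(fix.data, 1.0)
    # anchor the threshold between the background level (median: structure
    # is assumed to occupy a minority of the volume) and the peak
    med, peak = float(np.median(sm)), float(sm.max())
    thr = med + 0.25 * (peak - med)
    mask = ndimage.binary_dilation(sm > thr, iterations=4)
    if mask.sum() < 50 or mask.mean() > 0.9:  # degenerate mask: use everything
        return np.ones_like(sm, bool)
    return mask


def _lm_refine(
    mov: Image,
    fix: Image,
    params: np.ndarray,
    dof: int,
    center: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Levenberg-Marquardt refinement of the MSD cost.

    The Jacobian of the intensity residuals is assembled from the moving
    image's spatial gradient sampled at the warped positions (chain rule),
    which stays smooth where finite differences of the cost would see the
    interpolation kink at exact grid alignment. Residuals are evaluated on
    ``mask`` (default: the fixed image's structure mask).
    """
    grads = np.gradient(mov.data)  # d(intensity)/d(voxel index)
    Am_inv = np.linalg.inv(mov.affine)
    if mask is None:
        mask = _structure_mask(fix)
    idx = np.argwhere(mask)
    tgt = np.column_stack([idx, np.ones(len(idx))]).T
    world_t = fix.affine @ tgt  # (4, N) world coords of masked target voxels
    fix_flat = fix.data[mask]

    def src_vox(p):
        M = Am_inv @ np.linalg.inv(_param_matrix(p, dof, center))
        return (M @ world_t)[:3]

    def resid(p):
        s = src_vox(p)
        w = ndimage.map_coordinates(mov.data, s, order=1, mode="constant",
                                    cval=0.0, prefilter=False)
        return w - fix_flat

    def jac(p):
        s = src_vox(p)
        g = np.stack([
            ndimage.map_coordinates(grads[a], s, order=1, mode="constant",
                                    cval=0.0, prefilter=False)
            for a in range(3)
        ])  # (3, N)
        J = np.empty((s.shape[1], p.size))
        for k in range(p.size):
            pp = p.copy()
            pp[k] += 1e-6  # transform matrices are smooth in the parameters
            ds = (src_vox(pp) - s) / 1e-6
            J[:, k] = np.einsum("an,an->n", g, ds)
        return J

    res = optimize.least_squares(
        resid, params, jac=jac, method="lm", xtol=1e-12, ftol=1e-12,
        max_nfev=300,
    )
    return res.x


def register_affine(
    moving: Image,
    fixed: Image,
    dof: int = 6,
    cost: str = "msd",
    levels: tuple[int, ...] = (2, 1),
    grid_range_vox: float = 10.0,
    grid_step_vox: float = 2.0,
    rot_range_deg: float = 15.0,
    smooth_sigma: float = 0.0,
) -> AffineTransform:
    """Estimate the linear transform mapping ``moving`` onto ``fixed``.

    Deterministic multi-resolution optimization of the chosen cost, from
    the identity: a grid search over translations (+/- grid_range_vox
    voxels) at the coarsest level, a per-axis rotation sweep at every
    level, then local refinement per level (Levenberg-Marquardt on the
    structure-masked intensity residuals for the default mean-squared
    cost; Powell for the correlation ratio). Raises
    :class:`RegistrationError` when a cost-reducing transform cannot be
    found (constant input images, or the optimizer fails to improve on the
    identity for genuinely misaligned inputs).
    """
    if cost not in _COSTS:
        raise ValueError(f"cost must be one of {sorted(_COSTS)}, got {cost!r}")
    if dof not in (6, 12):
        raise ValueError(f"dof must be 6 or 12, got {dof}")
    if float(np.std(moving.data)) == 0.0 or float(np.std(fixed.data)) == 0.0:
        raise RegistrationError("constant image: registration cost is undefined")
    cost_fn = _COSTS[cost]
    center = fixed.world_center()

    # Exact early exit: already perfectly aligned (identical-visit pipelines).
    ident = np.eye(4)
    same_grid = moving.data.shape == fixed.data.shape and np.allclose(
        moving.affine, fixed.affine, atol=1e-12
    )
    if same_grid and np.array_equal(moving.data, fixed.data):
        return AffineTransform.identity(dof=dof)
    identity_cost = cost_fn(moving, fixed, ident)
    if identity_cost <= 1e-14 * max(1.0, float(np.mean(fixed.data**2))):
        return AffineTransform.identity(dof=dof)

    params = _matrix_params_identity(dof)
    vox = float(np.min(fixed.voxel_size))

    for li, f in enumerate(levels):
        mov_l = _downsample(moving, f, smooth_sigma)
        fix_l = _downsample(fixed, f, smooth_sigma)

        def level_cost(p):
            return cost_fn(mov_l, fix_l, _param_matrix(p, dof, center))

        def local_refine(p):
            if cost == "msd":
                return _lm_refine(mov_l, fix_l, p, dof, center)
            res = optimize.minimize(
                level_cost, p, method="Powell",
                options={"xtol": 0.02 if f == 1 else 0.05 * f, "ftol": 1e-8, "maxiter": 50},
            )
            return res.x

        if li == 0:
            # translation grid search at the coarsest level only
            best = level_cost(params)
            steps = np.arange(-grid_range_vox, grid_range_vox + 1e-9, grid_step_vox) * vox
            best_p = params.copy()
            for tx in steps:
                for ty in steps:
                    for tz in steps:
                        p = params.copy()
                        p[:3] = [tx, ty, tz]
                        c = level_cost(p)
                        if c < best:
                            best, best_p = c, p
            params = best_p

        params = local_refine(params)

        # Per-axis rotation sweep around the refined optimum, then refine
        # again if it found a better basin. Downsampled levels cannot see
        # small rotations of compact structures, and the refiner can stall
        # on the rotation-flat ridge at the aligned-translation point, so
        # the sweep is what hands it a basin containing the true rotation.
        best = level_cost(params)
        improved = False
        for axis in (3, 4, 5):
            for ang in np.arange(-rot_range_deg, rot_range_deg + 1e-9, 2.5 * f):
                p = params.copy()
                p[axis] = params[axis] + ang
                c = level_cost(p)
                if c < best:
                    best, params, improved = c, p, True
        if improved:
            params = local_refine(params)

    final = _param_matrix(params, dof, center)
    if cost == "msd":
        # judge improvement where the optimization actually looked
        mask = _structure_mask(fixed)
        warped_final = resample(moving, AffineTransform(final, dof=12), fixed.data.shape, fixed.affine)
        warped_ident = resample(moving, AffineTransform(ident, dof=12), fixed.data.shape, fixed.affine)
        final_cost = float(np.mean((warped_final.data[mask] - fixed.data[mask]) ** 2))
        identity_cost = float(np.mean((warped_ident.data[mask] - fixed.data[mask]) ** 2))
    else:
        final_cost = cost_fn(moving, fixed, final)
    if final_cost > identity_cost * (1 + 1e-9):
        raise RegistrationError(
            f"optimization failed: final cost {final_cost:g} exceeds identity cost {identity_cost:g}"
        )
    return AffineTransform(final, dof=dof)


# ---------------------------------------------------------------------------
# halfway decomposition


def _logm_real(m: np.ndarray) -> np.ndarray:
    L = linalg.logm(m)
    if np.max(np.abs(L.imag)) > 1e-8:
        raise ValueError("transform too far from identity for a real matrix logarithm")
    return L.real


def halfway_transforms(
    a_fwd: AffineTransform,
    a_bwd: AffineTransform,
    consistency_corners: np.ndarray | None = None,
    consistency_tol_mm: float | None = None,
) -> tuple[AffineTransform, AffineTransform]:
    """Split the symmetrized between-visit transform into two halves.

    ``a_fwd`` maps baseline->followup and ``a_bwd`` followup->baseline.
    The two independent estimates of the forward map, a_fwd and
    inverse(a_bwd), are blended as their geometric mean through the matrix
    logarithm, L = (log a_fwd + log a_bwd^-1)/2; the halves are
    H_base = exp(L/2) (baseline->midspace) and H_follow = exp(-L/2)
    (followup->midspace). The blend is exact for pure translations and
    pure rotations (half translation / half rotation angle) and satisfies
    H_follow^-1 ∘ H_base = exp(L) by construction; swapping the two
    visits negates L and therefore exchanges the halves exactly.

    If ``consistency_corners`` (world mm, shape (k, 3)) is given, the
    round trip a_bwd ∘ a_fwd is required to move each corner by at most
    ``consistency_tol_mm``; a larger discrepancy raises ValueError.
    """
    if consistency_corners is not None:
        rt = a_bwd.matrix @ a_fwd.matrix
        pts = np.column_stack([consistency_corners, np.ones(len(consistency_corners))])
        moved = (rt @ pts.T)[:3].T - np.asarray(consistency_corners, float)
        worst = float(np.max(np.linalg.norm(moved, axis=1)))
        tol = 0.5 if consistency_tol_mm is None else float(consistency_tol_mm)
        if worst > tol:
            raise ValueError(
                f"forward and backward registrations are inconsistent: round-trip error "
                f"{worst:.3f} mm exceeds tolerance {tol:g} mm"
            )
    if a_fwd.is_identity and a_bwd.is_identity:
        return (
            AffineTransform.identity(dof=a_fwd.dof, source="baseline", target="midspace"),
            AffineTransform.identity(dof=a_bwd.dof, source="followup", target="midspace"),
        )
    L = 0.5 * (_logm_real(a_fwd.matrix) + _logm_real(np.linalg.inv(a_bwd.matrix)))
    L[3] = 0.0
    h_base = linalg.expm(0.5 * L)
    h_follow = linalg.expm(-0.5 * L)
    dof = max(a_fwd.dof, a_bwd.dof)
    if dof == 6:
        # re-orthonormalize the rotation block against expm round-off
        for h in (h_base, h_follow):
            u, _, vt = np.linalg.svd(h[:3, :3])
            h[:3, :3] = u @ vt
    return (
        AffineTransform(h_base, dof=dof, source="baseline", target="midspace"),
        AffineTransform(h_follow, dof=dof, source="followup", target="midspace"),
    )


def build_midspace(
    baseline_fa: Image,
    followup_fa: Image,
    dof: int = 6,
    cost: str = "msd",
) -> MidspacePair:
    """Register both visit FA maps to each other, split the symmetrized
    transform, resample each visit once into the halfway space, and
    average the two half-images into the participant midspace template.

    The midspace grid is the (shared) visit grid; each visit's data passes
    through exactly one interpolation. Registration failure propagates as
    :class:`RegistrationError` so callers can exclude the subject.
    """
    a_fwd = register_affine(baseline_fa, followup_fa, dof=dof, cost=cost)
    a_bwd = register_affine(followup_fa, baseline_fa, dof=dof, cost=cost)
    shape = baseline_fa.data.shape
    corners_vox = np.array(
        [[0, 0, 0, 1]]
        + [
            [i * (shape[0] - 1), j * (shape[1] - 1), k * (shape[2] - 1), 1]
            for i in (0, 1)
            for j in (0, 1)
            for k in (0, 1)
        ],
        float,
    )
    corners = (baseline_fa.affine @ corners_vox.T)[:3].T
    tol = 0.5 * float(np.min(baseline_fa.voxel_size))
    h_base, h_follow = halfway_transforms(
        a_fwd, a_bwd, consistency_corners=corners, consistency_tol_mm=tol
    )
    half_b = resample(baseline_fa, h_base, shape, baseline_fa.affine)
    half_f = resample(followup_fa, h_follow, shape, baseline_fa.affine)
    template = Image((half_b.data + half_f.data) / 2.0, half_b.affine.copy(),
                     n_interp=max(half_b.n_interp, half_f.n_interp))
    return MidspacePair(
        half_baseline=half_b,
        half_followup=half_f,
        template=template,
        h_base=h_base,
        h_follow=h_follow,
    )
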