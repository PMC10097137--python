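"""Diffusion tensor estimation and scalar maps.

The forward model is the monoexponential Stejskal-Tanner signal

    S_i = S0 * exp(-b_i * g_i^T D g_i)

with D the symmetric 3x3 diffusion tensor (mm^2/s). Fitting inverts this
per voxel by ordinary least squares on the log signal; scalar maps follow
from the tensor eigensystem: FA (normalized eigenvalue dispersion), MD
(mean eigenvalue), AD (largest eigenvalue) and RD (mean of the two
smaller eigenvalues).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from longtbss import io as ltio

logger = logging.getLogger(__name__)

__all__ = [
    "GradientScheme",
    "DWIVolume",
    "TensorField",
    "ScalarMaps",
    "ConditioningError",
    "default_scheme",
    "bmatrix",
    "predict_signal",
    "fit_tensor",
    "eigensystem",
    "scalar_maps",
]

# Order of the 6 unique tensor components throughout this module.
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


class ConditioningError(ValueError):
    """The gradient scheme cannot support a tensor fit (rank < 7)."""


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion sensitization directions and b-values, one per volume."""

    directions: np.ndarray  # (n, 3); arbitrary for b=0 rows
    bvalues: np.ndarray  # (n,) s/mm^2

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.directions, float))
        b = np.asarray(self.bvalues, float).ravel()
        if d.shape != (b.size, 3):
            raise ValueError(f"directions shape {d.shape} incompatible with {b.size} b-values")
        dw = b > 0
        norms = np.linalg.norm(d[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("nonzero-b directions must be unit vectors (|norm-1| <= 1e-6)")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "bvalues", b)

    def __len__(self) -> int:
        return self.bvalues.size

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvalues == 0))

    @property
    def n_dw(self) -> int:
        return int(np.sum(self.bvalues > 0))

    def validate_for_fit(self) -> None:
        """A tensor fit needs >= 1 b=0 volume and >= 6 unique DW directions."""
        if self.n_b0 < 1:
            raise ConditioningError("scheme has no b=0 volume")
        dw = self.directions[self.bvalues > 0]
        # Directions equal up to sign sensitize identically.
        canon = dw * np.where(dw[:, [0]] < 0, -1, 1)
        unique = np.unique(np.round(canon, 6), axis=0)
        if unique.shape[0] < 6:
            raise ConditioningError(
                f"scheme has {unique.shape[0]} unique diffusion directions; >= 6 required"
            )

    @classmethod
    def from_files(cls, bval_path, bvec_path) -> "GradientScheme":
        bvals, bvecs = ltio.read_bvals_bvecs(bval_path, bvec_path)
        return cls(directions=bvecs, bvalues=bvals)

    def to_files(self, bval_path, bvec_path) -> None:
        ltio.write_bvals_bvecs(self.bvalues, self.directions, bval_path, bvec_path)


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the upper hemisphere (golden spiral)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = (i + 0.5) / n  # upper hemisphere only: antipodal directions are redundant
    r = np.sqrt(1.0 - z**2)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def default_scheme(n_directions: int = 42, bvalue: float = 1000.0, n_b0: int = 7) -> GradientScheme:
    """Clinical single-shell scheme: quasi-uniform unique directions at the
    given b-value preceded by the b=0 reference volumes (defaults: 42
    directions at b = 1000 s/mm^2 and 7 b=0 volumes)."""
    dirs_dw = _fibonacci_hemisphere(n_directions)
    directions = np.vstack([np.zeros((n_b0, 3)), dirs_dw])
    bvalues = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bvalue))])
    return GradientScheme(directions=directions, bvalues=bvalues)


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted acquisition with its gradient scheme."""

    data: np.ndarray  # (x, y, z, n_volumes), intensities >= 0
    affine: np.ndarray  # 4x4 voxel-to-world
    scheme: GradientScheme

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.affine = np.asarray(self.affine, float)
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4D, got ndim={self.data.ndim}")
        if self.data.shape[3] != len(self.scheme):
            raise ValueError(
                f"4th dimension ({self.data.shape[3]}) must match scheme length ({len(self.scheme)})"
            )
        vs = self.voxel_size
        if np.any(vs <= 0):
            raise ValueError(f"voxel size must be positive, got {vs}")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class TensorField:
    """Per-voxel diffusion tensors (6 unique components) with S0 and mask."""

    tensors: np.ndarray  # (x, y, z, 6) ordered per TENSOR_COMPONENTS, mm^2/s
    s0: np.ndarray  # (x, y, z)
    mask: np.ndarray  # (x, y, z) bool
    affine: np.ndarray
    n_dropped: int = 0  # voxels dropped for insufficient usable volumes

    def tensor_at(self, index) -> np.ndarray:
        return components_to_matrix(self.tensors[index])


@dataclass
class ScalarMaps:
    """FA/MD/AD/RD maps on a shared grid and mask."""

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    n_clamped: int = 0  # negative eigenvalues clamped to zero

    def metric(self, name: str) -> np.ndarray:
        name = name.lower()
        if name not in ("fa", "md", "ad", "rd"):
            raise KeyError(f"unknown DTI metric {name!r}")
        return getattr(self, name)


def components_to_matrix(c: np.ndarray) -> np.ndarray:
    """(..., 6) component vectors -> (..., 3, 3) symmetric matrices."""
    c = np.asarray(c, float)
    m = np.empty(c.shape[:-1] + (3, 3), float)
    m[..., 0, 0] = c[..., 0]
    m[..., 1, 1] = c[..., 1]
    m[..., 2, 2] = c[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = c[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = c[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = c[..., 5]
    return m


def matrix_to_components(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, float)
    return np.stack(
        [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2], m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
        axis=-1,
    )


def bmatrix(scheme: GradientScheme) -> np.ndarray:
    """Log-linear tensor design matrix, one row per volume.

    Row i is [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]
    acting on [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]; b=0 rows have zeros in
    the six tensor columns. Raises ConditioningError when the direction set
    cannot determine all 7 parameters.
    """
    scheme.validate_for_fit()
    g = scheme.directions
    b = scheme.bvalues
    B = np.empty((len(scheme), 7))
    B[:, 0] = 1.0
    B[:, 1] = -b * g[:, 0] ** 2
    B[:, 2] = -b * g[:, 1] ** 2
    B[:, 3] = -b * g[:, 2] ** 2
    B[:, 4] = -2 * b * g[:, 0] * g[:, 1]
    B[:, 5] = -2 * b * g[:, 0] * g[:, 2]
    B[:, 6] = -2 * b * g[:, 1] * g[:, 2]
    if np.linalg.matrix_rank(B) < 7:
        raise ConditioningError("degenerate direction set: design matrix rank < 7")
    return B


def predict_signal(tensor: np.ndarray, s0: float, scheme: GradientScheme) -> np.ndarray:
    """Forward Stejskal-Tanner signal S_i = S0 exp(-b_i g_i^T D g_i)."""
    tensor = np.asarray(tensor, float)
    if tensor.shape == (6,):
        tensor = components_to_matrix(tensor)
    if tensor.shape != (3, 3) or not np.allclose(tensor, tensor.T, atol=1e-12):
        raise ValueError("tensor must be a symmetric 3x3 matrix (or 6 components)")
    if s0 <= 0:
        raise ValueError(f"s0 must be positive, got {s0}")
    eigvals = np.linalg.eigvalsh(tensor)
    if eigvals[0] < -1e-12 * max(1.0, abs(eigvals[-1])):
        raise ValueError(f"tensor must be positive semidefinite, min eigenvalue {eigvals[0]:g}")
    g = scheme.directions
    adc = np.einsum("ni,ij,nj->n", g, tensor, g)
    return s0 * np.exp(-scheme.bvalues * adc)


def fit_tensor(dwi: DWIVolume, mask: np.ndarray) -> TensorField:
    """Per-voxel OLS tensor fit on the log signal.

    Voxels with nonpositive intensities in some diffusion-weighted volumes
    have those volumes excluded provided >= 7 usable rows remain; otherwise
    the voxel is removed from the mask and counted in ``n_dropped``.
    Nonpositive b=0 intensity always drops the voxel (no S0 reference).
    """
    mask = np.asarray(mask, bool)
    if mask.shape != dwi.shape3d:
        raise ValueError("mask shape does not match DWI grid")
    if not mask.any():
        raise ValueError("empty mask")
    B = bmatrix(dwi.scheme)
    b0_idx = dwi.scheme.bvalues == 0

    sig = dwi.data[mask]  # (n_vox, n_vols)
    n_vox = sig.shape[0]
    ok_rows = sig > 0
    usable_vox = ok_rows[:, b0_idx].all(axis=1)

    coefs = np.zeros((n_vox, 7))
    clean = usable_vox & ok_rows.all(axis=1)

    if clean.any():
        # Fast path: shared design matrix for voxels with all-positive signal.
        logs = np.log(sig[clean])
        coefs[clean] = np.linalg.lstsq(B, logs.T, rcond=None)[0].T

    for i in np.flatnonzero(usable_vox & ~clean):
        rows = ok_rows[i]
        if rows.sum() < 7 or np.linalg.matrix_rank(B[rows]) < 7:
            usable_vox[i] = False
            continue
        coefs[i] = np.linalg.lstsq(B[rows], np.log(sig[i, rows]), rcond=None)[0]

    n_dropped = int(np.sum(~usable_vox))
    if n_dropped:
        logger.warning("fit_tensor: %d voxel(s) dropped for unusable signal", n_dropped)

    out_mask = np.zeros_like(mask)
    out_mask[mask] = usable_vox
    tensors = np.zeros(dwi.shape3d + (6,))
    s0 = np.zeros(dwi.shape3d)
    flat_t = np.zeros((n_vox, 6))
    flat_t[usable_vox] = coefs[usable_vox, 1:]
    flat_s0 = np.zeros(n_vox)
    flat_s0[usable_vox] = np.exp(coefs[usable_vox, 0])
    tensors[mask] = flat_t
    s0[mask] = flat_s0
    return TensorField(
        tensors=tensors, s0=s0, mask=out_mask, affine=dwi.affine.copy(), n_dropped=n_dropped
    )


def eigensystem(tf: TensorField) -> tuple[np.ndarray, np.ndarray, int]:
    """Sorted eigenvalues and principal direction per masked voxel.

    Returns (eigenvalues (x,y,z,3) sorted descending, principal direction
    (x,y,z,3), clamp count). Negative eigenvalues (noise) are clamped to 0
    in the returned array; the count of affected voxels is logged.
    """
    mats = components_to_matrix(tf.tensors[tf.mask])
    w, v = np.linalg.eigh(mats)  # ascending
    w = w[:, ::-1]
    principal = v[:, :, ::-1][:, :, 0]
    n_clamped = int(np.sum((w < 0).any(axis=1)))
    if n_clamped:
        logger.info("eigensystem: clamped negative eigenvalues in %d voxel(s)", n_clamped)
    w = np.clip(w, 0.0, None)
    evals = np.zeros(tf.mask.shape + (3,))
    evecs = np.zeros(tf.mask.shape + (3,))
    evals[tf.mask] = w
    evecs[tf.mask] = principal
    return evals, evecs, n_clamped


def scalar_maps(
    eigenvalues: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    n_clamped: int = 0,
) -> ScalarMaps:
    """FA/MD/AD/RD from sorted nonnegative eigenvalues.

    FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||, defined as 0 where all
    eigenvalues vanish; MD = mean; AD = lambda_1; RD = (lambda_2+lambda_3)/2.
    """
    ev = np.asarray(eigenvalues, float)
    mask = np.asarray(mask, bool)
    w = ev[mask]
    md = w.mean(axis=1)
    ad = w[:, 0]
    rd = (w[:, 1] + w[:, 2]) / 2.0
    norm2 = np.sum(w**2, axis=1)
    dev2 = np.sum((w - md[:, None]) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(dev2) / np.sqrt(norm2)
    fa = np.where(norm2 > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)

    def _embed(vals):
        out = np.zeros(mask.shape)
        out[mask] = vals
        return out

    return ScalarMaps(
        fa=_embed(fa),
        md=_embed(md),
        ad=_embed(ad),
        rd=_embed(rd),
        mask=mask.copy(),
        affine=np.asarray(affine, float),
        n_clamped=n_clamped,
    )


def maps_from_dwi(dwi: DWIVolume, mask: np.ndarray) -> tuple[ScalarMaps, TensorField]:
    """Convenience: tensor fit + eigensystem + scalar maps in one call."""
    tf = fit_tensor(dwi, mask)
    evals, _, n_clamped = eigensystem(tf)
    return scalar_maps(evals, tf.mask, tf.affine, n_clamped), tf


def prolate_eigenvalues(peak_fa: float, md: float) -> tuple[float, float, float]:
    """Eigenvalues (l1, l2, l2) of a prolate tensor with given FA and MD.

    Solves FA = 3 d / sqrt(3 MD^2 + 6 d^2) for the anisotropy split d with
    l1 = MD + 2d, l2 = l3 = MD - d. Requires FA in [0, 1); note RD >= 0
    demands FA <= 3/sqrt(6+3) ... physical inputs are the caller's concern
    only insofar as l2 >= 0, which is checked.
    """
    if not 0 <= peak_fa < 1:
        raise ValueError(f"peak FA must be in [0, 1), got {peak_fa}")
    d = peak_fa * md * np.sqrt(3.0 / (9.0 - 6.0 * peak_fa**2))
    l1 = md + 2 * d
    l2 = md - d
    if l2 < 0:
        raise ValueError(f"FA {peak_fa} with MD {md} implies negative radial eigenvalue")
    return float(l1), float(l2), float(l2)
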