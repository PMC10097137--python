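"""Mean-FA template, skeleton extraction, and perpendicular projection.

Tract-based spatial statistics restricts voxelwise analysis to a
one-voxel-thick skeleton of tract centers extracted from the group mean FA
map, then fills each skeleton voxel with the maximum FA found along the
local perpendicular direction in each subject's map. The projection
absorbs residual misalignment between subjects: a tract shifted by a voxel
or two still contributes its center value to the same skeleton voxel.

Non-FA metrics (MD/AD/RD) are sampled at the location the FA search
selected, inheriting FA's projection geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from longtbss.registration import AffineTransform, Image, RegistrationError, register_affine, resample

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTemplate",
    "Skeleton",
    "SkeletonSamples",
    "build_group_template",
    "skeletonize",
    "project_fa",
    "project_nonfa",
    "skeleton_adjacency",
]


@dataclass
class GroupTemplate:
    """Cross-subject mean FA map with per-subject alignment transforms."""

    mean_fa: Image
    subject_to_common: dict[str, AffineTransform]
    subjects: list[str]
    dropped: list[str]


@dataclass
class Skeleton:
    """Thresholded mean-FA ridge with per-voxel search geometry.

    ``perp_dir`` is the direction (voxel units) across the local ridge;
    ``tangent`` runs along it. Where the structure is tube-like (two
    comparable cross-sectional curvatures, e.g. a cylindrical tract) the
    projection search fans over the whole plane orthogonal to the tangent
    instead of the single perpendicular line, mirroring how TBSS treats
    tube-like skeleton voxels.
    """

    mask: np.ndarray  # 3D bool
    indices: np.ndarray  # (n, 3) voxel indices of skeleton voxels
    perp_dir: np.ndarray  # (n, 3) unit vectors
    tangent: np.ndarray  # (n, 3) unit vectors
    is_tube: np.ndarray  # (n,) bool
    threshold: float
    affine: np.ndarray
    token: int  # identity token tying samples to this skeleton

    @property
    def n_voxels(self) -> int:
        return int(self.indices.shape[0])


@dataclass
class SkeletonSamples:
    """Per-skeleton-voxel samples of one metric for one subject-visit."""

    values: np.ndarray  # (n_skeleton_voxels,)
    offsets: np.ndarray  # (n, 3) signed search displacement, voxel units
    metric: str
    skeleton_token: int
    subject_id: str = ""
    visit: int = 0


def build_group_template(
    midspace_fas: dict[str, Image],
    dof: int = 6,
    rounds: int = 2,
    grid_range_vox: float = 4.0,
) -> GroupTemplate:
    """Iteratively align subject midspace FA maps to an evolving mean.

    The reference starts as the first subject's map; each round registers
    every subject to the current reference, resamples, and averages. At
    phantom scale all maps live on a common grid and the transforms are
    near-identity, standing in for the nonlinear standard-space warp used
    with whole-brain data. Subjects whose alignment fails are dropped and
    reported, never silently averaged.
    """
    ids = list(midspace_fas)
    if len(ids) < 2:
        raise ValueError("a group template needs at least 2 subjects")
    ref = midspace_fas[ids[0]]
    grid_shape, grid_affine = ref.data.shape, ref.affine
    transforms: dict[str, AffineTransform] = {}
    dropped: list[str] = []
    mean = None
    for _ in range(rounds):
        target = ref if mean is None else mean
        aligned = []
        transforms = {}
        dropped = []
        for sid in ids:
            img = midspace_fas[sid]
            try:
                t = register_affine(img, target, dof=dof, grid_range_vox=grid_range_vox)
            except RegistrationError as exc:
                logger.warning("template alignment failed for subject %s: %s", sid, exc)
                dropped.append(sid)
                continue
            transforms[sid] = t
            aligned.append(resample(img, t, grid_shape, grid_affine).data)
        if not aligned:
            raise RegistrationError("no subject survived template alignment")
        mean = Image(np.mean(aligned, axis=0), np.asarray(grid_affine).copy())
    kept = [s for s in ids if s not in dropped]
    return GroupTemplate(mean_fa=mean, subject_to_common=transforms, subjects=kept, dropped=dropped)


def _hessian_eigen(smoothed: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hessian eigenvalues/vectors of a smoothed map at given voxels.

    Returns (eigvals (n,3), eigvecs (n,3,3)) ordered by descending
    |eigenvalue|; column j of eigvecs is the direction of eigvals[:, j].
    """
    grads = np.gradient(smoothed)
    hess = np.empty((3, 3) + smoothed.shape)
    for i in range(3):
        gg = np.gradient(grads[i])
        for j in range(3):
            hess[i, j] = gg[j]
    hess = 0.5 * (hess + hess.transpose(1, 0, 2, 3, 4))  # enforce symmetry
    hv = hess[:, :, idx[:, 0], idx[:, 1], idx[:, 2]].transpose(2, 0, 1)
    w, v = np.linalg.eigh(hv)
    order = np.argsort(-np.abs(w), axis=1)
    w_sorted = np.take_along_axis(w, order, axis=1)
    v_sorted = np.stack([np.take_along_axis(v[:, k, :], order, axis=1) for k in range(3)], axis=1)
    return w_sorted, v_sorted


def _cog_direction(smoothed: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Center-of-gravity offset (voxels) of the 3x3x3 neighborhood."""
    weights = []
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                offsets.append((di, dj, dk))
                pos = idx + np.array([di, dj, dk])
                weights.append(smoothed[pos[:, 0], pos[:, 1], pos[:, 2]])
    W = np.stack(weights, axis=1)  # (n, 27)
    O = np.asarray(offsets, float)  # (27, 3)
    total = W.sum(axis=1, keepdims=True)
    return (W @ O) / np.maximum(total, 1e-30)


def _sample_trilinear(volume: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinear samples of ``volume`` at fractional voxel coords (n, 3)."""
    return ndimage.map_coordinates(
        volume, coords.T, order=1, mode="constant", cval=0.0, prefilter=False
    )


def skeletonize(
    template: GroupTemplate | Image,
    threshold: float = 0.2,
    sigma: float = 1.0,
    tube_ratio: float = 0.5,
) -> Skeleton:
    """Extract the mean-FA skeleton above an FA threshold.

    A voxel belongs to the skeleton iff its mean FA exceeds ``threshold``
    and it is a local maximum of the smoothed mean FA across the local
    ridge: the ridge tangent is the smallest-|curvature| eigenvector of
    the Hessian (sigma-voxel Gaussian smoothing) and the voxel must
    dominate its +-1 voxel neighbors along both cross-ridge
    eigendirections. Voxels whose two cross-ridge curvatures are
    comparable (ratio > ``tube_ratio``) are flagged tube-like, which
    widens the projection search to the full perpendicular plane.

    An empty skeleton is a valid outcome (logged, not an error).
    """
    img = template.mean_fa if isinstance(template, GroupTemplate) else template
    fa = img.data
    smoothed = ndimage.gaussian_filter(fa, sigma=sigma)
    above = fa > threshold
    # gradient/Hessian estimates are unreliable on the volume faces
    above[[0, -1], :, :] = above[:, [0, -1], :] = above[:, :, [0, -1]] = False
    idx = np.argwhere(above)
    if idx.size == 0:
        logger.warning("skeletonize: no voxel above FA threshold %g; skeleton is empty", threshold)
        return Skeleton(
            mask=np.zeros_like(above),
            indices=idx.reshape(0, 3),
            perp_dir=np.zeros((0, 3)),
            tangent=np.zeros((0, 3)),
            is_tube=np.zeros(0, bool),
            threshold=threshold,
            affine=img.affine.copy(),
            token=_new_token(),
        )

    w, v = _hessian_eigen(smoothed, idx)
    # eigenvectors by descending |curvature|: [:, :, 0] strongest cross-ridge,
    # [:, :, 2] ridge tangent
    e1 = v[:, :, 0]
    tangent = v[:, :, 2]
    curv_ratio = np.abs(w[:, 1]) / np.maximum(np.abs(w[:, 0]), 1e-30)
    is_tube = curv_ratio > tube_ratio

    # Search direction: the local center-of-gravity offset of the 3x3x3
    # FA neighborhood where it is informative (off-center voxels), falling
    # back to the strongest Hessian curvature direction at ridge centers
    # where the CofG offset degenerates to zero.
    cog = _cog_direction(smoothed, idx)
    cog_norm = np.linalg.norm(cog, axis=1)
    use_cog = cog_norm > 0.05
    perp = np.where(use_cog[:, None], cog / np.maximum(cog_norm, 1e-30)[:, None], e1)
    # Hessian-direction voxels must sit on a concave ridge
    concave_ok = use_cog | (w[:, 0] < 0)

    center_vals = smoothed[idx[:, 0], idx[:, 1], idx[:, 2]]
    plus = _sample_trilinear(smoothed, idx + perp)
    minus = _sample_trilinear(smoothed, idx - perp)
    keep = concave_ok & (center_vals >= plus) & (center_vals >= minus)
    keep &= (center_vals > plus) | (center_vals > minus)

    e1 = perp
    idx = idx[keep]
    mask = np.zeros_like(above)
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    n = int(keep.sum())
    if n == 0:
        logger.warning("skeletonize: ridge test removed every voxel; skeleton is empty")
    return Skeleton(
        mask=mask,
        indices=idx,
        perp_dir=e1[keep],
        tangent=tangent[keep],
        is_tube=is_tube[keep],
        threshold=threshold,
        affine=img.affine.copy(),
        token=_new_token(),
    )


_TOKEN_COUNTER = [0]


def _new_token() -> int:
    _TOKEN_COUNTER[0] += 1
    return _TOKEN_COUNTER[0]


def _search_directions(skel: Skeleton, n_angles: int = 8) -> np.ndarray:
    """Unit search directions per skeleton voxel, (n, n_angles, 3).

    Sheet-like voxels search only along +-perp_dir (remaining slots repeat
    that direction); tube-like voxels fan over the plane orthogonal to the
    tangent at n_angles evenly spaced angles spanning 180 degrees.
    """
    n = skel.n_voxels
    dirs = np.empty((n, n_angles, 3))
    # orthonormal basis of the cross-section plane
    b1 = skel.perp_dir
    b2 = np.cross(skel.tangent, b1)
    b2 /= np.maximum(np.linalg.norm(b2, axis=1, keepdims=True), 1e-30)
    angles = np.arange(n_angles) * (np.pi / n_angles)
    fan = (
        b1[:, None, :] * np.cos(angles)[None, :, None]
        + b2[:, None, :] * np.sin(angles)[None, :, None]
    )
    dirs[skel.is_tube] = fan[skel.is_tube]
    dirs[~skel.is_tube] = b1[~skel.is_tube, None, :]
    return dirs


def project_fa(
    subject_fa: Image,
    skeleton: Skeleton,
    max_search: float = 4.0,
    step: float = 0.5,
    subject_id: str = "",
    visit: int = 0,
) -> SkeletonSamples:
    """Perpendicular max-FA projection of a subject map onto the skeleton.

    For every skeleton voxel the subject's FA is sampled (trilinear) along
    the +- perpendicular search directions in ``step``-voxel increments up
    to ``max_search`` voxels; the maximum value wins and its displacement
    is recorded. Ties prefer smaller |offset|, then the positive
    direction. ``max_search = 0`` reduces to sampling at the skeleton
    voxel itself.
    """
    if skeleton.n_voxels == 0:
        return SkeletonSamples(
            values=np.zeros(0), offsets=np.zeros((0, 3)), metric="fa",
            skeleton_token=skeleton.token, subject_id=subject_id, visit=visit,
        )
    dirs = _search_directions(skeleton)  # (n, a, 3)
    radii = np.arange(step, max_search + 1e-9, step) if max_search > 0 else np.zeros(0)
    # displacement candidates ordered by |offset| then +/- preference
    disp = [np.zeros((skeleton.n_voxels, 1, 3))]
    for r in radii:
        disp.append(dirs * r)  # positive fan
        disp.append(-dirs * r)  # negative fan
    cand = np.concatenate(disp, axis=1)  # (n, c, 3)
    coords = skeleton.indices[:, None, :] + cand
    n, c, _ = coords.shape
    vals = _sample_trilinear(subject_fa.data, coords.reshape(-1, 3)).reshape(n, c)
    best = np.argmax(vals, axis=1)  # first max: smaller offset, + before -
    values = vals[np.arange(n), best]
    offsets = cand[np.arange(n), best]
    return SkeletonSamples(
        values=values,
        offsets=offsets,
        metric="fa",
        skeleton_token=skeleton.token,
        subject_id=subject_id,
        visit=visit,
    )


def project_nonfa(
    metric_map: Image,
    skeleton: Skeleton,
    fa_samples: SkeletonSamples,
    metric: str,
) -> SkeletonSamples:
    """Sample a non-FA metric at the locations chosen by the FA projection.

    The FA search defines the projection geometry for all metrics of the
    same subject-visit; MD/AD/RD are read at the FA-determined source
    positions, never re-searched.
    """
    if fa_samples.offsets is None or fa_samples.metric != "fa":
        raise ValueError("project_nonfa requires offsets from a prior project_fa call")
    if fa_samples.skeleton_token != skeleton.token:
        raise ValueError("FA offsets were computed on a different skeleton")
    coords = skeleton.indices + fa_samples.offsets
    values = _sample_trilinear(metric_map.data, coords)
    return SkeletonSamples(
        values=values,
        offsets=fa_samples.offsets.copy(),
        metric=metric.lower(),
        skeleton_token=skeleton.token,
        subject_id=fa_samples.subject_id,
        visit=fa_samples.visit,
    )


def skeleton_adjacency(skeleton: Skeleton) -> tuple[np.ndarray, np.ndarray]:
    """26-connectivity neighbor graph restricted to skeleton voxels.

    Returns CSR-style (indptr, indices) arrays over skeleton voxel order
    (the order of ``skeleton.indices``), the form consumed by the TFCE
    enhancer.
    """
    idx = skeleton.indices
    n = idx.shape[0]
    lookup = -np.ones(skeleton.mask.shape, dtype=np.int64)
    lookup[idx[:, 0], idx[:, 1], idx[:, 2]] = np.arange(n)
    offsets = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    )
    indptr = np.zeros(n + 1, dtype=np.int64)
    neighbor_lists = []
    shape = skeleton.mask.shape
    for v in range(n):
        pos = idx[v] + offsets
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        nb = lookup[pos[ok, 0], pos[ok, 1], pos[ok, 2]]
        nb = nb[nb >= 0]
        neighbor_lists.append(nb)
        indptr[v + 1] = indptr[v] + nb.size
    indices = np.concatenate(neighbor_lists) if neighbor_lists else np.zeros(0, dtype=np.int64)
    return indptr, indices.astype(np.int64)
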