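"""Synthetic two-visit, two-group longitudinal DWI cohorts with ground truth.

The generator emulates the structure of a longitudinal Huntington's
disease imaging study: a control group and an HD-expansion-carrier group,
each scanned twice, with tract-localized white-matter change in the
carriers between visits. White matter is modeled as tube phantoms
(straight or arc centerlines) of prolate diffusion tensors whose FA
profile falls off as a Gaussian across the tube cross-section, embedded in
an isotropic background. Longitudinal change is injected in the tensor
eigenvalues (lowering the axial split and/or raising the mean
diffusivity), so FA decline and diffusivity increase are mutually
consistent physics. Each visit gets an independent rigid misalignment and
Rician signal noise; clinical scores are drawn around realistic group
means and statistically coupled to each carrier's injected change
magnitude. Every latent quantity is recorded so any pipeline stage can be
scored against truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from longtbss import dti
from longtbss import io as ltio
from longtbss.clinical import ClinicalRecord, ClinicalTable
from longtbss.registration import AffineTransform

logger = logging.getLogger(__name__)

__all__ = [
    "Tract",
    "PhantomSpec",
    "TractChange",
    "ScoreCoupling",
    "CohortSpec",
    "Phantom",
    "GroundTruth",
    "make_phantom",
    "add_rician_noise",
    "simulate_subject",
    "simulate_cohort",
    "trackon_preset",
    "paddington_preset",
    "smoke_preset",
]


@dataclass(frozen=True)
class Tract:
    """A tube phantom: straight segment or planar arc centerline.

    Geometry is specified in fractions of the field of view so the same
    tract definition scales from smoke grids to full phantoms. ``radius``
    (voxels) is the cross-sectional scale: the FA profile is
    peak_fa * exp(-r^2 / (2 sigma^2)) with sigma = radius / 2, so FA falls
    below ~0.14 * peak at the nominal radius.
    """

    name: str
    kind: str = "straight"  # "straight" | "arc"
    point: tuple[float, float, float] = (0.35, 0.5, 0.5)  # on-axis point (FOV fractions)
    direction: tuple[float, float, float] = (0.0, 1.0, 0.0)  # straight tracts
    arc_center: tuple[float, float, float] = (0.5, 0.5, 0.35)
    arc_radius: float = 0.28  # FOV fraction
    arc_axes: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (1.0, 0.0, 0.0),
        (0.0, 0.0, 1.0),
    )
    arc_angles: tuple[float, float] = (30.0, 150.0)  # degrees within the arc plane
    radius: float = 4.0  # tube radius, voxels
    peak_fa: float = 0.6
    md: float = 0.75e-3  # mm^2/s on the axis

    def __post_init__(self):
        if self.kind not in ("straight", "arc"):
            raise ValueError(f"tract kind must be 'straight' or 'arc', got {self.kind!r}")
        if not 0.2 < self.peak_fa < 1.0:
            raise ValueError(f"tract peak FA must be in (0.2, 1), got {self.peak_fa}")
        if self.radius < 2:
            raise ValueError(f"tube radius must be >= 2 voxels, got {self.radius}")

    @property
    def axial_diffusivity(self) -> float:
        return dti.prolate_eigenvalues(self.peak_fa, self.md)[0]

    @property
    def radial_diffusivity(self) -> float:
        return dti.prolate_eigenvalues(self.peak_fa, self.md)[1]

    def distance_tangent(self, pts_mm: np.ndarray, fov_mm: np.ndarray):
        """Distance (mm) from points to the centerline + unit tangents."""
        if self.kind == "straight":
            p0 = np.asarray(self.point) * fov_mm
            d = np.asarray(self.direction, float)
            d = d / np.linalg.norm(d)
            rel = pts_mm - p0
            proj = rel @ d
            closest = p0 + proj[:, None] * d
            dist = np.linalg.norm(pts_mm - closest, axis=1)
            tangent = np.broadcast_to(d, pts_mm.shape)
            return dist, tangent
        c = np.asarray(self.arc_center) * fov_mm
        R = self.arc_radius * float(np.mean(fov_mm))
        u = np.asarray(self.arc_axes[0], float)
        u = u / np.linalg.norm(u)
        v = np.asarray(self.arc_axes[1], float)
        v = v - (v @ u) * u
        v = v / np.linalg.norm(v)
        rel = pts_mm - c
        a = rel @ u
        b = rel @ v
        theta = np.arctan2(b, a)
        th0, th1 = np.deg2rad(self.arc_angles)
        theta = np.clip(theta, th0, th1)
        closest = c + R * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
        dist = np.linalg.norm(pts_mm - closest, axis=1)
        tangent = -np.sin(theta)[:, None] * u + np.cos(theta)[:, None] * v
        return dist, tangent


@dataclass(frozen=True)
class PhantomSpec:
    """Grid and tissue model of the white-matter phantom."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: float = 2.0  # mm, isotropic
    tracts: tuple[Tract, ...] = ()
    background_d: float = 0.7e-3  # isotropic background diffusivity mm^2/s
    s0: float = 1000.0
    allow_overlap: bool = False

    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_size] * 3 + [1.0])
        return a

    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, float) * self.voxel_size


def default_tracts(radius: float = 4.0) -> tuple[Tract, Tract]:
    """Two non-overlapping tracts: a straight association-bundle-like tube
    and an arc commissural-bundle-like sweep."""
    return (
        Tract(name="slf_like", kind="straight", point=(0.3, 0.5, 0.65),
              direction=(0.0, 1.0, 0.0), radius=radius, peak_fa=0.6, md=0.75e-3),
        Tract(name="cc_like", kind="arc", arc_center=(0.5, 0.5, 0.1),
              arc_radius=0.25, arc_axes=((1.0, 0.0, 0.0), (0.0, 0.0, 1.0)),
              arc_angles=(35.0, 145.0), radius=radius, peak_fa=0.65, md=0.75e-3),
    )


@dataclass
class Phantom:
    """Evaluated tensor field of a phantom, with per-tract geometry."""

    tensors: np.ndarray  # (x, y, z, 6)
    label: np.ndarray  # int map, 0 = background, i+1 = tracts[i]
    centerline: np.ndarray  # bool, voxels within 0.5 voxel of a centerline
    weights: np.ndarray  # (n_tracts, x, y, z) Gaussian cross-section weights
    affine: np.ndarray
    spec: PhantomSpec


def make_phantom(
    spec: PhantomSpec,
    pose: AffineTransform | None = None,
    tract_mods: dict[str, tuple[float, float]] | None = None,
) -> Phantom:
    """Evaluate the phantom tensor field on its grid.

    ``pose`` rigidly moves the whole object in world space (the geometry
    is evaluated analytically in the moved frame and the tensor
    orientation rotated accordingly — no interpolation, so posed phantoms
    are exact). ``tract_mods`` maps tract name -> (fa_delta, md_delta)
    applied on the tract axis and tapering with the cross-section weight;
    this is how longitudinal change is injected.
    """
    if not spec.tracts:
        shape = spec.grid_shape
        tensors = np.zeros(shape + (6,))
        tensors[..., :3] = spec.background_d
        return Phantom(
            tensors=tensors,
            label=np.zeros(shape, int),
            centerline=np.zeros(shape, bool),
            weights=np.zeros((0,) + shape),
            affine=spec.affine(),
            spec=spec,
        )
    tract_mods = tract_mods or {}
    shape = spec.grid_shape
    affine = spec.affine()
    fov = spec.fov_mm()
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    pts = (affine @ vox.T)[:3].T  # world mm

    if pose is not None:
        inv = np.linalg.inv(pose.matrix)
        pts_eval = (inv[:3, :3] @ pts.T).T + inv[:3, 3]
        rot = pose.matrix[:3, :3]
    else:
        pts_eval = pts
        rot = np.eye(3)

    n_vox = pts.shape[0]
    n_tr = len(spec.tracts)
    wts = np.zeros((n_tr, n_vox))
    tangents = np.zeros((n_tr, n_vox, 3))
    dists = np.zeros((n_tr, n_vox))
    for t_i, tract in enumerate(spec.tracts):
        dist_mm, tang = tract.distance_tangent(pts_eval, fov)
        r = dist_mm / spec.voxel_size  # voxels
        sigma = tract.radius / 2.0
        w = np.exp(-(r**2) / (2 * sigma**2))
        w[r > 2 * tract.radius] = 0.0
        wts[t_i] = w
        dists[t_i] = r
        tangents[t_i] = (rot @ tang.T).T

    significant = wts > 0.05
    if not spec.allow_overlap and n_tr > 1 and np.any(significant.sum(axis=0) > 1):
        raise ValueError("tracts overlap; set allow_overlap=True to permit")

    dominant = np.argmax(wts, axis=0)
    w_dom = wts[dominant, np.arange(n_vox)]
    tang_dom = tangents[dominant, np.arange(n_vox)]

    peak_fa = np.array([t.peak_fa for t in spec.tracts])
    md_axis = np.array([t.md for t in spec.tracts])
    fa_d = np.array([tract_mods.get(t.name, (0.0, 0.0))[0] for t in spec.tracts])
    md_d = np.array([tract_mods.get(t.name, (0.0, 0.0))[1] for t in spec.tracts])

    fa_vox = (peak_fa[dominant] + fa_d[dominant]) * w_dom
    md_vox = spec.background_d + ((md_axis + md_d)[dominant] - spec.background_d) * w_dom
    fa_vox = np.clip(fa_vox, 0.0, 0.95)

    # prolate eigenvalues per voxel: l1 = md + 2 delta, l2 = l3 = md - delta
    delta = fa_vox * md_vox * np.sqrt(3.0 / (9.0 - 6.0 * fa_vox**2))
    delta = np.minimum(delta, md_vox)  # keep radial eigenvalue nonnegative
    l1 = md_vox + 2 * delta
    l2 = md_vox - delta

    # D = (l1 - l2) t t' + l2 I
    tt = tang_dom[:, :, None] * tang_dom[:, None, :]
    D = (l1 - l2)[:, None, None] * tt
    D[:, 0, 0] += l2
    D[:, 1, 1] += l2
    D[:, 2, 2] += l2
    comps = dti.matrix_to_components(D).reshape(shape + (6,))

    label = np.where(w_dom > 0.05, dominant + 1, 0).reshape(shape)
    centerline = np.zeros(n_vox, bool)
    for t_i in range(n_tr):
        centerline |= (dists[t_i] <= 0.5) & (dominant == t_i)
    return Phantom(
        tensors=comps,
        label=label,
        centerline=centerline.reshape(shape),
        weights=wts.reshape((n_tr,) + shape),
        affine=affine,
        spec=spec,
    )


def phantom_scalar_maps(phantom: Phantom) -> "dti.ScalarMaps":
    """Noise-free scalar maps of a phantom's tensor field (truth maps)."""
    shape = phantom.tensors.shape[:-1]
    tf = dti.TensorField(
        tensors=phantom.tensors,
        s0=np.full(shape, phantom.spec.s0),
        mask=np.ones(shape, bool),
        affine=phantom.affine,
    )
    evals, _, n_clamped = dti.eigensystem(tf)
    return dti.scalar_maps(evals, tf.mask, phantom.affine, n_clamped)


def truth_mask_on_grid(
    truth: GroundTruth,
    tract: str,
    target,
) -> np.ndarray:
    """Carry a ground-truth affected mask into an analysis grid.

    The pipeline's common grid is anchored to one subject's midspace, not
    to the phantom frame, so truth masks must be mapped before scoring
    overlap. The phantom's noise-free FA map is registered to ``target``
    (an :class:`~longtbss.registration.Image`, e.g. the group mean FA) and
    the named affected mask is resampled through that transform; returns a
    boolean mask on the target grid.
    """
    from longtbss.registration import Image, register_affine, resample

    fa = phantom_scalar_maps(truth.phantom).fa
    est = register_affine(Image(fa, truth.phantom.affine), target)
    mask = truth.affected_masks[tract].astype(float)
    moved = resample(Image(mask, truth.phantom.affine), est, target.data.shape, target.affine)
    return moved.data > 0.5


def add_rician_noise(signal: np.ndarray, sigma: float, seed_or_rng) -> np.ndarray:
    """Rician-corrupt magnitude MR signal: sqrt((S + e1)^2 + e2^2).

    e1, e2 ~ Normal(0, sigma^2). sigma = 0 returns the input exactly;
    output is nonnegative and deterministic per seed.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    signal = np.asarray(signal, float)
    if sigma == 0:
        return signal.copy()
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    e1 = rng.normal(0.0, sigma, signal.shape)
    e2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)


def _signals_from_tensors(tensors: np.ndarray, s0: float, scheme: dti.GradientScheme) -> np.ndarray:
    """Vectorized Stejskal-Tanner forward model over a tensor grid."""
    shape = tensors.shape[:-1]
    c = tensors.reshape(-1, 6)
    g = scheme.directions
    b = scheme.bvalues
    # g' D g = gx^2 Dxx + gy^2 Dyy + gz^2 Dzz + 2 gx gy Dxy + 2 gx gz Dxz + 2 gy gz Dyz
    q = np.column_stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]]
    )  # (n_vol, 6)
    adc = c @ q.T  # (n_vox, n_vol)
    sig = s0 * np.exp(-b[None, :] * adc)
    return sig.reshape(shape + (len(scheme),))


def _random_rigid(rng: np.random.Generator, max_t_vox: float, max_r_deg: float,
                  voxel_size: float, center: np.ndarray) -> AffineTransform:
    t = rng.uniform(-max_t_vox, max_t_vox, 3) * voxel_size
    angles = np.deg2rad(rng.uniform(-max_r_deg, max_r_deg, 3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    A = Rz @ Ry @ Rx
    m = np.eye(4)
    m[:3, :3] = A
    m[:3, 3] = t + center - A @ center
    return AffineTransform(m, dof=6)


@dataclass(frozen=True)
class TractChange:
    """Annualized-equivalent longitudinal change injected in one tract.

    ``fa_delta``/``md_delta`` are the expected change at the tract axis
    over the full between-visit interval (not per year), applied to the
    affected group only.
    """

    tract: str
    fa_delta: float = 0.0
    md_delta: float = 0.0
    group: str = "carrier"


@dataclass(frozen=True)
class ScoreCoupling:
    """Clinical score model: base + k * (subject change magnitude - 1) + noise."""

    base_control: float
    base_carrier: float
    sd_control: float
    sd_carrier: float
    k: float = 0.0  # coupling to the carrier's change-magnitude multiplier
    lo: float = 0.0
    hi: float = np.inf


def _default_couplings(cohort: str) -> dict[str, ScoreCoupling]:
    # Group means/SDs chosen near published longitudinal HD cohort tables;
    # k couples carriers' scores to their injected change magnitude.
    if cohort == "paddington":
        return {
            "tms": ScoreCoupling(1.5, 18.71, 1.5, 6.0, k=10.0, lo=0.0),
            "tfc": ScoreCoupling(12.97, 12.04, 0.17, 0.5, k=-0.8, lo=0.0, hi=13.0),
            "sdmt": ScoreCoupling(54.0, 37.53, 9.0, 7.0, k=-10.0, lo=0.0),
            "swr": ScoreCoupling(109.4, 79.26, 14.0, 11.0, k=-12.0, lo=0.0),
        }
    return {
        "tms": ScoreCoupling(1.33, 7.43, 1.2, 4.0, k=6.0, lo=0.0),
        "tfc": ScoreCoupling(13.0, 12.86, 0.0, 0.3, k=-0.3, lo=0.0, hi=13.0),
        "sdmt": ScoreCoupling(56.88, 52.62, 11.0, 10.0, k=-8.0, lo=0.0),
        "swr": ScoreCoupling(107.94, 102.60, 17.0, 15.0, k=-10.0, lo=0.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Complete recipe for a reproducible two-visit synthetic cohort."""

    name: str = "smoke"
    n_control: int = 8
    n_carrier: int = 8
    interval_months: float = 24.0
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(tracts=default_tracts()))
    changes: tuple[TractChange, ...] = (
        TractChange("slf_like", fa_delta=-0.03, md_delta=0.0),
        TractChange("cc_like", fa_delta=0.0, md_delta=0.04e-3),
    )
    noise_sigma_rel: float = 0.05  # Rician sigma / s0 (b0 SNR 20)
    max_translation_vox: float = 2.0
    max_rotation_deg: float = 3.0
    subject_sd: float = 0.3  # SD of the per-carrier change magnitude multiplier
    n_directions: int = 42
    bvalue: float = 1000.0
    n_b0: int = 7
    cag_mean: float = 43.1
    cag_sd: float = 2.3
    cag_min: int = 40
    age_mean_control: float = 49.6
    age_mean_carrier: float = 44.0
    age_sd: float = 9.0
    sites: tuple[str, ...] = ("siteA",)
    couplings: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_control < 2 or self.n_carrier < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.noise_sigma_rel < 0:
            raise ValueError("noise sigma must be >= 0")

    def scheme(self) -> dti.GradientScheme:
        return dti.default_scheme(self.n_directions, self.bvalue, self.n_b0)

    def score_couplings(self) -> dict[str, ScoreCoupling]:
        if self.couplings is not None:
            return self.couplings
        return _default_couplings("paddington" if self.name.startswith("padd") else "trackon")


def trackon_preset(seed: int = 0, **overrides) -> CohortSpec:
    """Low-disease-burden cohort: 67 controls / 77 carriers, 24 months."""
    kw = dict(name="trackon", n_control=67, n_carrier=77, interval_months=24.0, seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


def paddington_preset(seed: int = 0, **overrides) -> CohortSpec:
    """Manifest-HD cohort: 33 controls / 49 carriers, 15 months."""
    kw = dict(
        name="paddington", n_control=33, n_carrier=49, interval_months=15.0,
        cag_min=39, age_mean_control=52.0, age_mean_carrier=47.8, seed=seed,
        changes=(
            TractChange("slf_like", fa_delta=-0.02, md_delta=0.03e-3),
            TractChange("cc_like", fa_delta=-0.01, md_delta=0.05e-3),
        ),
    )
    kw.update(overrides)
    return CohortSpec(**kw)


def smoke_preset(seed: int = 0, n: int = 8, grid: int = 24, **overrides) -> CohortSpec:
    """Small fast cohort for end-to-end runs: n+n subjects on a small grid."""
    kw = dict(
        name="smoke", n_control=n, n_carrier=n, interval_months=24.0,
        phantom=PhantomSpec(grid_shape=(grid, grid, grid), tracts=default_tracts(radius=3.0)),
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


@dataclass
class SubjectTruth:
    subject_id: str
    group: str
    magnitude: float  # change-magnitude multiplier (0 for controls)
    pose_visit1: np.ndarray
    pose_visit2: np.ndarray
    tract_mods: dict[str, tuple[float, float]]


@dataclass
class GroundTruth:
    """Everything needed to score any stage's recovery."""

    affected_masks: dict[str, np.ndarray]  # tract name -> bool map (w >= 0.5)
    changes: tuple[TractChange, ...]
    subjects: dict[str, SubjectTruth]
    couplings: dict[str, ScoreCoupling]
    phantom: Phantom

    def to_json_dict(self) -> dict:
        return {
            "changes": [asdict(c) for c in self.changes],
            "couplings": {k: asdict(v) for k, v in self.couplings.items()},
            "subjects": {
                sid: {
                    "group": st.group,
                    "magnitude": st.magnitude,
                    "pose_visit1": st.pose_visit1.tolist(),
                    "pose_visit2": st.pose_visit2.tolist(),
                    "tract_mods": {k: list(v) for k, v in st.tract_mods.items()},
                }
                for sid, st in self.subjects.items()
            },
        }


def simulate_subject(
    spec: CohortSpec,
    group: str,
    magnitude: float,
    rng: np.random.Generator,
    misalign: bool = True,
    noise: bool = True,
) -> tuple[dti.DWIVolume, dti.DWIVolume, SubjectTruth]:
    """Generate both visits of one subject.

    Visit 2 tensors differ from visit 1 in the affected tracts for the
    affected group, scaled by the subject's change-magnitude multiplier;
    each visit carries its own rigid pose and Rician noise draw. Truth
    (poses, applied deltas) is returned alongside.
    """
    scheme = spec.scheme()
    pspec = spec.phantom
    center = pspec.fov_mm() / 2.0

    if misalign and (spec.max_translation_vox > 0 or spec.max_rotation_deg > 0):
        pose1 = _random_rigid(rng, spec.max_translation_vox, spec.max_rotation_deg,
                              pspec.voxel_size, center)
        pose2 = _random_rigid(rng, spec.max_translation_vox, spec.max_rotation_deg,
                              pspec.voxel_size, center)
    else:
        rng.uniform(size=12)  # keep the stream aligned across configs
        pose1 = AffineTransform.identity()
        pose2 = AffineTransform.identity()

    mods: dict[str, tuple[float, float]] = {}
    if group == "carrier":
        for ch in spec.changes:
            if ch.group == "carrier":
                mods[ch.tract] = (ch.fa_delta * magnitude, ch.md_delta * magnitude)

    ph1 = make_phantom(pspec, pose=pose1)
    ph2 = make_phantom(pspec, pose=pose2, tract_mods=mods)
    sig1 = _signals_from_tensors(ph1.tensors, pspec.s0, scheme)
    sig2 = _signals_from_tensors(ph2.tensors, pspec.s0, scheme)
    sigma = spec.noise_sigma_rel * pspec.s0
    if noise and sigma > 0:
        sig1 = add_rician_noise(sig1, sigma, rng)
        sig2 = add_rician_noise(sig2, sigma, rng)
    dwi1 = dti.DWIVolume(data=sig1, affine=pspec.affine(), scheme=scheme)
    dwi2 = dti.DWIVolume(data=sig2, affine=pspec.affine(), scheme=scheme)
    truth = SubjectTruth(
        subject_id="", group=group, magnitude=magnitude if group == "carrier" else 0.0,
        pose_visit1=pose1.matrix, pose_visit2=pose2.matrix, tract_mods=mods,
    )
    return dwi1, dwi2, truth


def _draw_clinical(
    spec: CohortSpec, sid: str, group: str, magnitude: float, site: str,
    rng: np.random.Generator,
) -> ClinicalRecord:
    cp = spec.score_couplings()
    scores = {}
    for name, c in cp.items():
        if group == "carrier":
            v = c.base_carrier + c.k * (magnitude - 1.0) + rng.normal(0.0, c.sd_carrier)
        else:
            v = c.base_control + rng.normal(0.0, c.sd_control)
        scores[name] = float(np.clip(v, c.lo, c.hi))
    age_mean = spec.age_mean_carrier if group == "carrier" else spec.age_mean_control
    age = float(np.clip(rng.normal(age_mean, spec.age_sd), 20.0, 70.0))
    cag = None
    if group == "carrier":
        cag = float(np.clip(round(rng.normal(spec.cag_mean, spec.cag_sd)), spec.cag_min, 55))
    sex = "M" if rng.uniform() < 0.5 else "F"
    return ClinicalRecord(
        subject_id=sid, group=group, age=age, sex=sex, site=site, cag=cag,
        tfc=scores["tfc"], tms=scores["tms"], sdmt=scores["sdmt"], swr=scores["swr"],
    )


def simulate_cohort(
    spec: CohortSpec,
    outdir,
    misalign: bool = True,
    noise: bool = True,
) -> tuple[ClinicalTable, GroundTruth]:
    """Write a complete cohort dataset to ``outdir`` and return its truth.

    Layout: ``sub-XXX/ses-{1,2}/dwi.nii.gz`` + ``dwi.bval``/``dwi.bvec``,
    ``participants.csv``, ``truth.json`` plus per-tract
    ``truth_affected_<tract>.nii.gz`` masks. Byte-reproducible for a fixed
    spec and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    scheme = spec.scheme()

    base_phantom = make_phantom(spec.phantom)
    affected = {}
    for ch in spec.changes:
        t_i = [t.name for t in spec.phantom.tracts].index(ch.tract)
        affected[ch.tract] = base_phantom.weights[t_i] >= 0.5

    groups = ["control"] * spec.n_control + ["carrier"] * spec.n_carrier
    records = []
    subject_truths: dict[str, SubjectTruth] = {}
    for i, group in enumerate(groups):
        sid = f"sub-{i + 1:03d}"
        magnitude = float(np.clip(rng.normal(1.0, spec.subject_sd), 0.2, 2.0)) if group == "carrier" else 0.0
        dwi1, dwi2, truth = simulate_subject(spec, group, magnitude, rng,
                                             misalign=misalign, noise=noise)
        truth.subject_id = sid
        subject_truths[sid] = truth
        site = spec.sites[i % len(spec.sites)]
        records.append(_draw_clinical(spec, sid, group, magnitude, site, rng))
        for visit, dwi in ((1, dwi1), (2, dwi2)):
            ses = outdir / sid / f"ses-{visit}"
            ses.mkdir(parents=True, exist_ok=True)
            ltio.write_nifti(dwi.data.astype(np.float32), dwi.affine, ses / "dwi.nii.gz")
            scheme.to_files(ses / "dwi.bval", ses / "dwi.bvec")

    table = ClinicalTable(records)
    table.to_csv(outdir / "participants.csv")
    truth = GroundTruth(
        affected_masks=affected,
        changes=spec.changes,
        subjects=subject_truths,
        couplings=spec.score_couplings(),
        phantom=base_phantom,
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
    for name, mask in affected.items():
        ltio.write_nifti(mask.astype(np.uint8), spec.phantom.affine(),
                         outdir / f"truth_affected_{name}.nii.gz")
    logger.info("simulated cohort %r: %d subjects -> %s", spec.name, len(groups), outdir)
    return table, truth
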