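"""Longitudinal change maps and TFCE permutation inference on the skeleton.

Change is baseline minus final visit per skeleton voxel, so a decline over
time (the expected FA trajectory in carriers) produces a positive delta
and an increase over time (diffusivity) a negative delta. Group contrasts
and carrier-only clinical correlations are tested with a permutation GLM:
ordinary least squares t statistics, enhanced with threshold-free cluster
enhancement (TFCE), and family-wise error corrected against the
permutation distribution of the maximum TFCE value over the skeleton
(Freedman-Lane residual permutation under the nuisance-only model).

Each contrast direction is a separate one-sided test; results carry the
direction label so downstream reporting can speak in "carrier shows
decline/increase" vocabulary rather than raw contrast signs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from longtbss.clinical import ClinicalTable
from longtbss.skeleton import Skeleton, SkeletonSamples, skeleton_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "ChangeSamples",
    "SkeletonStatResult",
    "ContrastPair",
    "change_map",
    "glm_tstat",
    "tfce",
    "permutation_test",
    "run_group_comparison",
    "run_correlation",
    "CLINICAL_SCORES",
]

CLINICAL_SCORES = ("dbs", "sdmt", "swr", "tms", "tfc", "cuhdrs")


@dataclass
class ChangeSamples:
    """Per-subject baseline-minus-final skeleton samples for one metric."""

    values: np.ndarray  # (n_subjects, n_skeleton_voxels)
    subject_ids: list[str]
    metric: str
    skeleton_token: int
    interval_months: float = 0.0


@dataclass
class SkeletonStatResult:
    """Voxelwise statistics for one directed contrast on the skeleton."""

    tmap: np.ndarray  # signed t per skeleton voxel (observed)
    tfce_map: np.ndarray  # TFCE of the contrast-positive part of tmap
    pfwe: np.ndarray  # FWER-corrected p per voxel
    n_perm: int
    seed: int
    alpha: float
    label: str  # human-readable direction, e.g. "carrier FA decline > control"
    one_sided: bool = True

    @property
    def sig_mask(self) -> np.ndarray:
        return self.pfwe < self.alpha

    @property
    def n_significant(self) -> int:
        return int(self.sig_mask.sum())


@dataclass
class ContrastPair:
    """Both directions of one contrast, sharing a permutation null."""

    positive: SkeletonStatResult
    negative: SkeletonStatResult


def change_map(baseline: SkeletonSamples, followup: SkeletonSamples) -> np.ndarray:
    """Baseline minus final-visit skeleton samples (one subject, one metric).

    Positive values mean the metric declined over time; negative values
    mean it increased. Raises if the two sample sets do not share a
    subject, metric, and skeleton.
    """
    if baseline.skeleton_token != followup.skeleton_token:
        raise ValueError("baseline and followup samples come from different skeletons")
    if baseline.metric != followup.metric:
        raise ValueError(
            f"metric mismatch: {baseline.metric!r} vs {followup.metric!r}"
        )
    if baseline.subject_id != followup.subject_id:
        raise ValueError(
            f"subject mismatch: {baseline.subject_id!r} vs {followup.subject_id!r}"
        )
    delta = baseline.values - followup.values
    if not np.all(np.isfinite(delta)):
        raise ValueError("non-finite change values")
    return delta


def glm_tstat(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    """OLS t statistic of a contrast, per column of ``Y``.

    t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c) with residual dof
    n - rank(X). Voxels with zero residual variance get t = 0 (degenerate
    phantom voxels, warned once per call).
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    X = np.asarray(X, float)
    c = np.asarray(contrast, float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows for {p} design columns, got {n}")
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n - rank
    sigma2 = np.sum(resid**2, axis=0) / dof
    cvar = float(c @ np.linalg.inv(X.T @ X) @ c)
    num = c @ beta
    # residual variance indistinguishable from round-off is degenerate
    floor = 1e-20 * np.maximum(np.mean(Y**2, axis=0), np.finfo(float).tiny)
    sigma2 = np.where(sigma2 <= floor, 0.0, sigma2)
    denom = np.sqrt(sigma2 * cvar)
    t = np.zeros_like(num)
    ok = denom > 0
    if not ok.all():
        logger.warning("glm_tstat: %d voxel(s) with zero residual variance; t set to 0", int((~ok).sum()))
    t[ok] = num[ok] / denom[ok]
    return t


@njit(cache=True)
def _uf_find(parent, v):
    root = v
    while parent[root] != root:
        root = parent[root]
    while parent[v] != root:
        parent[v], v = root, parent[v]
    return root


@njit(cache=True)
def _tfce_core(stat, indptr, indices, H, E, n_steps):
    n = stat.shape[0]
    out = np.zeros(n)
    hmax = 0.0
    for i in range(n):
        if stat[i] > hmax:
            hmax = stat[i]
    if hmax <= 0.0:
        return out
    dh = hmax / n_steps
    order = np.argsort(-stat)
    parent = np.empty(n, np.int64)
    size = np.zeros(n, np.int64)
    active = np.zeros(n, np.bool_)
    ptr = 0
    for k in range(n_steps, 0, -1):
        h = (k - 0.5) * dh
        while ptr < n and stat[order[ptr]] > h:
            v = order[ptr]
            ptr += 1
            parent[v] = v
            size[v] = 1
            active[v] = True
            for j in range(indptr[v], indptr[v + 1]):
                u = indices[j]
                if active[u]:
                    ru = _uf_find(parent, u)
                    rv = _uf_find(parent, v)
                    if ru != rv:
                        # union by size
                        if size[ru] < size[rv]:
                            ru, rv = rv, ru
                        parent[rv] = ru
                        size[ru] += size[rv]
        inc = dh * h**H
        for i in range(ptr):
            v = order[i]
            r = _uf_find(parent, v)
            out[v] += size[r] ** E * inc
    return out


def tfce(
    stat: np.ndarray,
    adjacency: tuple[np.ndarray, np.ndarray],
    H: float = 2.0,
    E: float = 1.0,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement on the skeleton graph.

    TFCE(v) = sum_h e(h, v)^E * h^H * dh, where e(h, v) is the extent of
    the suprathreshold (stat > h) connected component containing v, using
    26-connectivity restricted to skeleton voxels. Thresholds are the
    midpoints of ``n_steps`` uniform bins of [0, max(stat)]; an isolated
    voxel of height h0 therefore receives ~ h0^(H+1)/(H+1). Negative input
    values are treated as sub-threshold everywhere (run the mirrored
    contrast separately for the other tail). An all-zero map returns an
    all-zero map.
    """
    stat = np.ascontiguousarray(np.asarray(stat, float))
    if stat.ndim != 1:
        raise ValueError("tfce expects a 1D stat vector over skeleton voxels")
    indptr, indices = adjacency
    return _tfce_core(
        stat,
        np.ascontiguousarray(indptr, dtype=np.int64),
        np.ascontiguousarray(indices, dtype=np.int64),
        float(H),
        float(E),
        int(n_steps),
    )


def _freedman_lane_null(
    Y: np.ndarray,
    x: np.ndarray,
    Z: np.ndarray,
    adjacency: tuple[np.ndarray, np.ndarray],
    n_perm: int,
    seed: int,
    H: float,
    E: float,
    n_steps: int,
    permutations: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Observed t/TFCE and the max-TFCE permutation null for both tails.

    Freedman-Lane: the response is residualized against the nuisance-only
    model, the residual rows are permuted, and the full model is refit.
    Returns (t_obs, tfce_pos, tfce_neg, maxnull_pos, maxnull_neg).
    """
    Y = np.asarray(Y, float)
    n = Y.shape[0]
    X = np.column_stack([x, Z])
    contrast = np.zeros(X.shape[1])
    contrast[0] = 1.0

    t_obs = glm_tstat(Y, X, contrast)
    tfce_pos = tfce(np.clip(t_obs, 0, None), adjacency, H, E, n_steps)
    tfce_neg = tfce(np.clip(-t_obs, 0, None), adjacency, H, E, n_steps)

    # residualize against nuisance (Freedman-Lane)
    Zp = np.linalg.pinv(Z)
    Ytilde = Y - Z @ (Zp @ Y)

    # precompute full-model quantities reused across permutations
    Xp = np.linalg.pinv(X)
    cvar = float(contrast @ np.linalg.inv(X.T @ X) @ contrast)
    dof = n - np.linalg.matrix_rank(X)
    a = (contrast @ Xp)  # (n,) row mapping Y -> c'beta

    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = np.stack([rng.permutation(n) for _ in range(n_perm)])
    else:
        permutations = np.asarray(permutations)
        n_perm = permutations.shape[0]

    maxnull_pos = np.empty(n_perm)
    maxnull_neg = np.empty(n_perm)
    for i, perm in enumerate(permutations):
        Yp = Ytilde[perm]
        beta = Xp @ Yp
        resid = Yp - X @ beta
        sigma2 = np.sum(resid**2, axis=0) / dof
        denom = np.sqrt(sigma2 * cvar)
        num = a @ Yp
        t = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
        maxnull_pos[i] = tfce(np.clip(t, 0, None), adjacency, H, E, n_steps).max(initial=0.0)
        maxnull_neg[i] = tfce(np.clip(-t, 0, None), adjacency, H, E, n_steps).max(initial=0.0)
    return t_obs, tfce_pos, tfce_neg, maxnull_pos, maxnull_neg


def _pfwe(tfce_obs: np.ndarray, maxnull: np.ndarray, n_perm: int) -> np.ndarray:
    # +1 convention: p is never 0, minimum 1/(n_perm+1)
    exceed = np.sum(maxnull[None, :] >= tfce_obs[:, None], axis=1)
    return (1.0 + exceed) / (n_perm + 1.0)


def permutation_test(
    Y: np.ndarray,
    x: np.ndarray,
    nuisance: np.ndarray | None,
    adjacency: tuple[np.ndarray, np.ndarray],
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    H: float = 2.0,
    E: float = 1.0,
    n_steps: int = 100,
    labels: tuple[str, str] = ("positive association", "negative association"),
    permutations: np.ndarray | None = None,
) -> ContrastPair:
    """Permutation GLM with TFCE and max-statistic FWER correction.

    ``Y`` is subjects x skeleton voxels, ``x`` the predictor of interest,
    ``nuisance`` the covariate block (an intercept column is appended
    automatically). Both one-sided directions are tested against the same
    seeded permutation null; exchanging the sign of ``x`` exactly swaps
    the two results. ``permutations`` overrides the seeded draw (used for
    exhaustive enumeration on small samples).

    pfwe(v) = (1 + #{perm max TFCE >= observed TFCE(v)}) / (n_perm + 1);
    deterministic for a fixed seed.
    """
    Y = np.asarray(Y, float)
    x = np.asarray(x, float).ravel()
    n = Y.shape[0]
    if x.size != n:
        raise ValueError("predictor length does not match response rows")
    if n_perm < 100:
        logger.warning("n_perm=%d gives coarse p-value resolution (min p = %.3g)", n_perm, 1 / (n_perm + 1))
    Z = np.ones((n, 1)) if nuisance is None else np.column_stack([np.ones(n), nuisance])
    t_obs, tfce_pos, tfce_neg, null_pos, null_neg = _freedman_lane_null(
        Y, x, Z, adjacency, n_perm, seed, H, E, n_steps, permutations=permutations
    )
    n_eff = null_pos.size
    pos = SkeletonStatResult(
        tmap=t_obs, tfce_map=tfce_pos, pfwe=_pfwe(tfce_pos, null_pos, n_eff),
        n_perm=n_eff, seed=seed, alpha=alpha, label=labels[0],
    )
    neg = SkeletonStatResult(
        tmap=-t_obs, tfce_map=tfce_neg, pfwe=_pfwe(tfce_neg, null_neg, n_eff),
        n_perm=n_eff, seed=seed, alpha=alpha, label=labels[1],
    )
    return ContrastPair(positive=pos, negative=neg)


def _stack_deltas(deltas: ChangeSamples, table: ClinicalTable, subject_ids: list[str]):
    order = [deltas.subject_ids.index(s) for s in subject_ids]
    return deltas.values[order]


def run_group_comparison(
    deltas: ChangeSamples,
    table: ClinicalTable,
    skeleton: Skeleton,
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    H: float = 2.0,
    E: float = 1.0,
    n_steps: int = 100,
) -> ContrastPair:
    """Carriers-vs-controls contrast on longitudinal change, both directions.

    The response is the baseline-minus-final change map; the predictor is
    the carrier indicator; age, sex, and site enter as nuisance
    covariates. Under the subtraction convention the returned
    ``positive`` result is "greater decline over time in carriers" (for
    FA this is the expected carrier effect; for diffusivities the
    expected carrier effect — greater increase — is the ``negative``
    result). Labels spell this out per metric.
    """
    if deltas.skeleton_token != skeleton.token:
        raise ValueError("change samples come from a different skeleton")
    ids = deltas.subject_ids
    groups = np.array([table.get(s).group for s in ids])
    n_car, n_con = int(np.sum(groups == "carrier")), int(np.sum(groups == "control"))
    if n_car == 0 or n_con == 0:
        raise ValueError(f"both groups required: {n_con} controls, {n_car} carriers")
    if min(n_car, n_con) < 5:
        logger.warning("small group size (%d controls, %d carriers)", n_con, n_car)
    x = (groups == "carrier").astype(float)
    nuisance, _ = table.design_columns(ids)
    m = deltas.metric.upper()
    labels = (
        f"carrier {m} decline > control",
        f"carrier {m} increase > control",
    )
    return permutation_test(
        deltas.values, x, nuisance, skeleton_adjacency(skeleton),
        n_perm=n_perm, seed=seed, alpha=alpha, H=H, E=E, n_steps=n_steps, labels=labels,
    )


def run_correlation(
    deltas: ChangeSamples,
    table: ClinicalTable,
    skeleton: Skeleton,
    score: str,
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    H: float = 2.0,
    E: float = 1.0,
    n_steps: int = 100,
) -> ContrastPair:
    """Carrier-only voxelwise correlation of change with a baseline score.

    ``score`` is one of dbs/sdmt/swr/tms/tfc/cuhdrs. Subjects missing the
    score are dropped with a log line (no imputation). Both one-sided
    directions are tested; a constant score is a rank error.
    """
    score = score.lower()
    if score not in CLINICAL_SCORES:
        raise ValueError(f"score must be one of {CLINICAL_SCORES}, got {score!r}")
    if deltas.skeleton_token != skeleton.token:
        raise ValueError("change samples come from a different skeleton")
    ids = []
    vals = []
    for s in deltas.subject_ids:
        rec = table.get(s)
        if rec.group != "carrier":
            raise ValueError(f"correlation analyses are carriers-only; {s} is {rec.group}")
        v = getattr(rec, score) if score not in ("cuhdrs", "dbs") else (
            rec.cuhdrs if score == "cuhdrs" else rec.dbs
        )
        if v is None:
            logger.info("subject %s dropped from %s correlation (missing score)", s, score)
            continue
        ids.append(s)
        vals.append(float(v))
    x = np.array(vals)
    if x.size < 3:
        raise ValueError("too few carriers with the requested score")
    if np.std(x) == 0:
        raise ValueError(f"score {score!r} is constant across carriers (rank deficient)")
    sub = table.subset(ids)
    nuisance, _ = sub.design_columns(ids)
    Y = _stack_deltas(deltas, table, ids)
    m = deltas.metric.upper()
    labels = (
        f"higher baseline {score.upper()} ~ larger {m} decline",
        f"higher baseline {score.upper()} ~ larger {m} increase",
    )
    return permutation_test(
        Y, x, nuisance, skeleton_adjacency(skeleton),
        n_perm=n_perm, seed=seed, alpha=alpha, H=H, E=E, n_steps=n_steps, labels=labels,
    )
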