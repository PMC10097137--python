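"""Change maps, GLM t statistics, TFCE, and permutation inference."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from longtbss.clinical import ClinicalRecord, ClinicalTable
from longtbss.inference import (
    ChangeSamples,
    change_map,
    glm_tstat,
    permutation_test,
    run_correlation,
    run_group_comparison,
    tfce,
)
from longtbss.skeleton import SkeletonSamples


def make_samples(values, subject="s1", visit=1, metric="fa", token=1):
    values = np.asarray(values, float)
    return SkeletonSamples(
        values=values, offsets=np.zeros((values.size, 3)), metric=metric,
        skeleton_token=token, subject_id=subject, visit=visit,
    )


def chain_adjacency(n):
    indptr = np.zeros(n + 1, np.int64)
    nb = []
    for v in range(n):
        lst = [u for u in (v - 1, v + 1) if 0 <= u < n]
        nb += lst
        indptr[v + 1] = len(nb)
    return indptr, np.asarray(nb, np.int64)


class TestChangeMap:
    def test_identical_visits_zero(self):
        a = make_samples([0.5, 0.4], visit=1)
        b = make_samples([0.5, 0.4], visit=2)
        np.testing.assert_array_equal(change_map(a, b), 0.0)

    def test_fa_decline_gives_positive_delta(self):
        assert change_map(make_samples([0.50]), make_samples([0.45], visit=2))[0] == pytest.approx(0.05)

    def test_md_increase_gives_negative_delta(self):
        d = change_map(
            make_samples([0.70e-3], metric="md"), make_samples([0.80e-3], metric="md", visit=2)
        )
        assert d[0] == pytest.approx(-0.10e-3)

    def test_mismatched_skeleton_rejected(self):
        with pytest.raises(ValueError, match="skeleton"):
            change_map(make_samples([1.0], token=1), make_samples([1.0], token=2))

    def test_mismatched_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            change_map(make_samples([1.0], metric="fa"), make_samples([1.0], metric="md"))


class TestGlmTstat:
    def test_matches_pooled_two_sample_t(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([rng.normal(0, 1, 12), rng.normal(0.7, 1, 12)])
        X = np.column_stack([np.r_[np.zeros(12), np.ones(12)], np.ones(24)])
        t = glm_tstat(y[:, None], X, [1, 0])[0]
        ref = sps.ttest_ind(y[12:], y[:12], equal_var=True).statistic
        assert t == pytest.approx(ref, abs=1e-10)

    def test_matches_correlation_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        X = np.column_stack([x, np.ones(25)])
        t = glm_tstat(y[:, None], X, [1, 0])[0]
        r = np.corrcoef(x, y)[0, 1]
        assert t**2 == pytest.approx(r**2 * 23 / (1 - r**2), rel=1e-10)

    def test_orthogonal_response_gives_zero_t(self):
        X = np.column_stack([np.r_[np.zeros(4), np.ones(4)], np.ones(8)])
        y = np.array([1.0, -1, 2, -2, 1, -1, 2, -2])  # identical group means
        assert glm_tstat(y[:, None], X, [1, 0])[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_residual_variance_yields_zero_t(self):
        # a constant response (degenerate phantom voxel): zero residual
        # variance must produce t = 0, not a division blow-up
        X = np.column_stack([np.r_[np.zeros(4), np.ones(4)], np.ones(8)])
        y = np.full((8, 1), 5.0)
        assert glm_tstat(y, X, [1, 0])[0] == 0.0

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            glm_tstat(np.random.default_rng(0).normal(size=(10, 2)), X, [1, 0])


class TestTfce:
    def test_all_zero_map_passes_through(self, isolated_voxel_adjacency):
        out = tfce(np.zeros(1), isolated_voxel_adjacency)
        np.testing.assert_array_equal(out, 0.0)

    def test_isolated_voxel_closed_form(self, isolated_voxel_adjacency):
        """Fine-step threshold integration of an isolated voxel of height
        h converges to h^(H+1)/(H+1): height 3, H=2, E=1 gives 9."""
        out = tfce(np.array([3.0]), isolated_voxel_adjacency, H=2.0, E=1.0, n_steps=100)
        assert out[0] == pytest.approx(9.0, rel=0.02)

    def test_doubling_scales_by_two_to_h_plus_one(self, isolated_voxel_adjacency):
        lo = tfce(np.array([3.0]), isolated_voxel_adjacency)[0]
        hi = tfce(np.array([6.0]), isolated_voxel_adjacency)[0]
        assert hi / lo == pytest.approx(8.0, rel=1e-6)

    def test_constant_line_extent_weighting(self):
        """Brute-force oracle: constant height h on an n-chain gives every
        voxel sum_k (n * h_k^H) dh -> n^E * h^(H+1)/(H+1)."""
        adj = chain_adjacency(5)
        out = tfce(np.full(5, 2.0), adj, H=2.0, E=1.0, n_steps=400)
        assert np.allclose(out, 5 * 2.0**3 / 3, rtol=0.01)

    def test_extent_uses_connected_components_only(self):
        # two voxels not adjacent: each enhanced as isolated voxel
        indptr = np.array([0, 0, 0], np.int64)
        out = tfce(np.array([3.0, 3.0]), (indptr, np.zeros(0, np.int64)))
        assert out[0] == pytest.approx(9.0, rel=0.02)
        # same two voxels connected: extent 2 doubles the E=1 enhancement
        adj = chain_adjacency(2)
        out2 = tfce(np.array([3.0, 3.0]), adj)
        assert out2[0] == pytest.approx(18.0, rel=0.02)


class TestPermutationTest:
    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(20, 15))
        x = np.r_[np.zeros(10), np.ones(10)]
        adj = chain_adjacency(15)
        a = permutation_test(Y, x, None, adj, n_perm=200, seed=9)
        b = permutation_test(Y, x, None, adj, n_perm=200, seed=9)
        np.testing.assert_array_equal(a.positive.pfwe, b.positive.pfwe)
        np.testing.assert_array_equal(a.negative.tmap, b.negative.tmap)

    def test_contrast_sign_swap_exchanges_pair(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(18, 10))
        x = rng.normal(size=18)
        Z = rng.normal(size=(18, 2))
        adj = chain_adjacency(10)
        pair = permutation_test(Y, x, Z, adj, n_perm=150, seed=2)
        flipped = permutation_test(Y, -x, Z, adj, n_perm=150, seed=2)
        np.testing.assert_array_equal(pair.positive.pfwe, flipped.negative.pfwe)
        np.testing.assert_array_equal(pair.positive.tfce_map, flipped.negative.tfce_map)

    def test_pfwe_bounds_and_monotonicity(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(16, 12))
        Y[8:, :4] += 1.5
        x = np.r_[np.zeros(8), np.ones(8)]
        adj = chain_adjacency(12)
        res = permutation_test(Y, x, None, adj, n_perm=200, seed=1).positive
        assert np.all(res.pfwe >= 1 / 201) and np.all(res.pfwe <= 1.0)
        order = np.argsort(res.tfce_map)
        assert np.all(np.diff(res.pfwe[order]) <= 1e-12)  # higher TFCE, lower p

    def test_freedman_lane_equals_label_permutation_exhaustively(self):
        """With intercept-only nuisance, permuting nuisance residuals is
        identical to permuting group labels: compare t statistics over
        every permutation of n = 6 subjects against the direct oracle."""
        rng = np.random.default_rng(6)
        n = 6
        Y = rng.normal(size=(n, 4))
        x = np.r_[np.zeros(3), np.ones(3)]
        Z = np.ones((n, 1))
        Ytilde = Y - Y.mean(axis=0)  # residuals of the intercept-only model
        X = np.column_stack([x, Z])
        for perm in itertools.permutations(range(n)):
            p = np.asarray(perm)
            t_fl = glm_tstat(Ytilde[p], X, [1, 0])
            # oracle: permute the response rows directly (label permutation)
            t_direct = glm_tstat(Y[p], X, [1, 0])
            np.testing.assert_allclose(t_fl, t_direct, atol=1e-10)

    def test_low_n_perm_warns(self, caplog):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(12, 5))
        x = np.r_[np.zeros(6), np.ones(6)]
        with caplog.at_level("WARNING"):
            permutation_test(Y, x, None, chain_adjacency(5), n_perm=50, seed=0)
        assert any("resolution" in r.message or "coarse" in r.message for r in caplog.records)


def make_table(n_control, n_carrier, rng, site_levels=("x",)):
    recs = []
    for i in range(n_control + n_carrier):
        grp = "control" if i < n_control else "carrier"
        recs.append(
            ClinicalRecord(
                subject_id=f"s{i}", group=grp, age=float(rng.uniform(30, 60)),
                sex="M" if rng.uniform() < 0.5 else "F",
                site=site_levels[i % len(site_levels)],
                cag=42.0 if grp == "carrier" else None,
                tfc=12.0, tms=float(rng.uniform(0, 20)),
                sdmt=float(rng.uniform(30, 60)), swr=float(rng.uniform(70, 110)),
            )
        )
    return ClinicalTable(recs)


class TestGroupAndCorrelation:
    def test_injected_group_effect_recovered(self, smoke_skeleton_adjacency):
        """A 1.5-SD FA-decline effect in connected skeleton voxels is
        detected in the carrier-decline direction, localized (Dice >= 0.5),
        with no significant control-decline voxels."""
        skel, adj = smoke_skeleton_adjacency
        rng = np.random.default_rng(11)
        n1 = n2 = 15
        nv = skel.n_voxels
        region = np.zeros(nv, bool)
        region[: max(6, nv // 3)] = True
        Y = rng.normal(0, 0.01, size=(n1 + n2, nv))
        Y[n1:, region] += 0.015  # carriers decline more
        table = make_table(n1, n2, rng)
        deltas = ChangeSamples(Y, [f"s{i}" for i in range(n1 + n2)], "fa", skel.token)
        pair = run_group_comparison(deltas, table, skel, n_perm=500, seed=3)
        sig = pair.positive.sig_mask
        d = 2 * (sig & region).sum() / max(sig.sum() + region.sum(), 1)
        assert d >= 0.5
        assert pair.negative.n_significant == 0
        assert "decline" in pair.positive.label

    def test_single_group_rejected(self, smoke_skeleton_adjacency):
        skel, _ = smoke_skeleton_adjacency
        rng = np.random.default_rng(12)
        table = make_table(0, 6, rng)
        deltas = ChangeSamples(
            rng.normal(size=(6, skel.n_voxels)), [f"s{i}" for i in range(6)], "fa", skel.token
        )
        with pytest.raises(ValueError, match="both groups"):
            run_group_comparison(deltas, table, skel, n_perm=100, seed=0)

    def test_correlation_recovers_coupled_score(self, smoke_skeleton_adjacency):
        """When baseline TMS is positively coupled to injected diffusivity
        increase, the association localizes to the affected voxels in the
        increase direction."""
        skel, _ = smoke_skeleton_adjacency
        rng = np.random.default_rng(13)
        n = 25
        nv = skel.n_voxels
        region = np.zeros(nv, bool)
        region[: max(6, nv // 3)] = True
        severity = rng.normal(1.0, 0.3, n)
        Y = rng.normal(0, 0.01, size=(n, nv))
        Y[:, region] -= 0.02 * severity[:, None]  # MD increase = negative delta
        recs = []
        for i in range(n):
            recs.append(
                ClinicalRecord(
                    subject_id=f"s{i}", group="carrier", age=float(rng.uniform(30, 60)),
                    sex="M" if rng.uniform() < 0.5 else "F", site="x", cag=42.0,
                    tfc=12.0, tms=float(10 + 8 * severity[i] + rng.normal(0, 1)),
                    sdmt=50.0, swr=90.0,
                )
            )
        table = ClinicalTable(recs)
        deltas = ChangeSamples(Y, [f"s{i}" for i in range(n)], "md", skel.token)
        pair = run_correlation(deltas, table, skel, "tms", n_perm=500, seed=4)
        sig = pair.negative.sig_mask  # higher TMS ~ larger MD increase
        d = 2 * (sig & region).sum() / max(sig.sum() + region.sum(), 1)
        assert d >= 0.5
        assert "increase" in pair.negative.label

    def test_constant_score_is_rank_error(self, smoke_skeleton_adjacency):
        skel, _ = smoke_skeleton_adjacency
        rng = np.random.default_rng(14)
        n = 8
        recs = [
            ClinicalRecord(f"s{i}", "carrier", 45.0, "F", "x", cag=42.0,
                           tfc=13.0, tms=5.0, sdmt=50.0, swr=90.0)
            for i in range(n)
        ]
        deltas = ChangeSamples(
            rng.normal(size=(n, skel.n_voxels)), [f"s{i}" for i in range(n)], "fa", skel.token
        )
        with pytest.raises(ValueError, match="constant"):
            run_correlation(deltas, ClinicalTable(recs), skel, "tfc", n_perm=100, seed=0)

    def test_control_subject_in_correlation_rejected(self, smoke_skeleton_adjacency):
        skel, _ = smoke_skeleton_adjacency
        rng = np.random.default_rng(15)
        table = make_table(1, 5, rng)
        deltas = ChangeSamples(
            rng.normal(size=(6, skel.n_voxels)), [f"s{i}" for i in range(6)], "fa", skel.token
        )
        with pytest.raises(ValueError, match="carriers-only"):
            run_correlation(deltas, table, skel, "tms", n_perm=100, seed=0)

    def test_scale_invariance_of_t_maps(self, smoke_skeleton_adjacency):
        """Annualizing constant-interval deltas rescales the response but
        leaves every t map unchanged."""
        skel, _ = smoke_skeleton_adjacency
        rng = np.random.default_rng(16)
        n1 = n2 = 10
        Y = rng.normal(size=(n1 + n2, skel.n_voxels))
        table = make_table(n1, n2, rng)
        ids = [f"s{i}" for i in range(n1 + n2)]
        raw = ChangeSamples(Y, ids, "fa", skel.token, interval_months=24.0)
        annual = ChangeSamples(Y * (12.0 / 24.0), ids, "fa", skel.token, interval_months=24.0)
        p1 = run_group_comparison(raw, table, skel, n_perm=100, seed=5)
        p2 = run_group_comparison(annual, table, skel, n_perm=100, seed=5)
        np.testing.assert_allclose(p1.positive.tmap, p2.positive.tmap, atol=1e-10)
        np.testing.assert_array_equal(p1.positive.sig_mask, p2.positive.sig_mask)
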