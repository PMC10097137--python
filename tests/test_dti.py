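"""Tensor model: design matrix, forward signal, OLS fit, scalar maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from longtbss import dti
from longtbss.simulate import add_rician_noise


def random_psd_tensor(rng, scale=1e-3):
    A = rng.normal(size=(3, 3))
    return (A @ A.T) * scale / 3.0


class TestScheme:
    def test_default_scheme_shape(self, default_scheme):
        assert len(default_scheme) == 49
        assert default_scheme.n_b0 == 7 and default_scheme.n_dw == 42
        norms = np.linalg.norm(default_scheme.directions[default_scheme.bvalues > 0], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_file_round_trip(self, default_scheme, tmp_path):
        default_scheme.to_files(tmp_path / "dwi.bval", tmp_path / "dwi.bvec")
        back = dti.GradientScheme.from_files(tmp_path / "dwi.bval", tmp_path / "dwi.bvec")
        np.testing.assert_allclose(back.bvalues, default_scheme.bvalues)
        np.testing.assert_allclose(back.directions, default_scheme.directions, atol=1e-9)


class TestBMatrix:
    def test_default_scheme_full_rank(self, default_scheme):
        B = dti.bmatrix(default_scheme)
        assert B.shape == (49, 7)
        assert np.linalg.matrix_rank(B) == 7
        # b=0 rows carry no tensor sensitivity
        np.testing.assert_allclose(B[:7, 1:], 0.0)

    def test_all_b0_scheme_rejected(self):
        s = dti.GradientScheme(np.zeros((8, 3)), np.zeros(8))
        with pytest.raises(dti.ConditioningError):
            dti.bmatrix(s)

    def test_single_repeated_direction_rejected(self):
        d = np.tile([1.0, 0, 0], (10, 1))
        s = dti.GradientScheme(np.vstack([[0, 0, 0], d]), np.r_[0, np.full(10, 1000.0)])
        with pytest.raises(dti.ConditioningError):
            dti.bmatrix(s)


class TestPredictSignal:
    def test_zero_tensor_returns_s0(self, default_scheme):
        sig = dti.predict_signal(np.zeros((3, 3)), 500.0, default_scheme)
        np.testing.assert_allclose(sig, 500.0)

    def test_isotropic_attenuation(self, default_scheme):
        d = 0.7e-3
        sig = dti.predict_signal(np.eye(3) * d, 1000.0, default_scheme)
        dw = default_scheme.bvalues > 0
        np.testing.assert_allclose(sig[dw], 1000.0 * np.exp(-0.7), rtol=1e-12)
        np.testing.assert_allclose(sig[~dw], 1000.0)

    def test_stick_perpendicular_unattenuated(self):
        scheme = dti.GradientScheme(
            np.array([[0, 0, 0], [0, 1, 0]]), np.array([0.0, 1000.0])
        )
        stick = np.diag([1.7e-3, 0, 0])  # along x, gradient along y
        sig = dti.predict_signal(stick, 800.0, scheme)
        assert sig[1] == pytest.approx(800.0)

    def test_negative_definite_rejected(self, default_scheme):
        with pytest.raises(ValueError):
            dti.predict_signal(-np.eye(3) * 1e-3, 1000.0, default_scheme)


class TestFitTensor:
    def test_noiseless_round_trip_batch(self, default_scheme):
        """OLS on noiseless log-signal inverts the forward model exactly."""
        rng = np.random.default_rng(7)
        tensors = [random_psd_tensor(rng) for _ in range(64)]
        sig = np.stack([dti.predict_signal(D, 1000.0, default_scheme) for D in tensors])
        dwi = dti.DWIVolume(sig.reshape(4, 4, 4, -1), np.eye(4), default_scheme)
        tf = dti.fit_tensor(dwi, np.ones((4, 4, 4), bool))
        fitted = tf.tensors.reshape(64, 6)
        truth = np.stack([dti.matrix_to_components(D) for D in tensors])
        assert np.max(np.abs(fitted - truth)) / np.max(np.abs(truth)) < 1e-9

    def test_constant_signal_gives_zero_tensor(self, default_scheme):
        sig = np.full((1, 1, 1, 49), 400.0)
        tf = dti.fit_tensor(dti.DWIVolume(sig, np.eye(4), default_scheme), np.ones((1, 1, 1), bool))
        np.testing.assert_allclose(tf.tensors, 0.0, atol=1e-12)
        assert tf.s0[0, 0, 0] == pytest.approx(400.0)

    def test_empty_mask_rejected(self, default_scheme):
        sig = np.full((2, 2, 2, 49), 100.0)
        dwi = dti.DWIVolume(sig, np.eye(4), default_scheme)
        with pytest.raises(ValueError, match="empty mask"):
            dti.fit_tensor(dwi, np.zeros((2, 2, 2), bool))

    def test_nonpositive_dw_volumes_excluded_per_voxel(self, default_scheme):
        D = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        sig = dti.predict_signal(D, 1000.0, default_scheme)
        vol = np.tile(sig, (1, 1, 2, 1))
        vol[0, 0, 1, 10] = 0.0  # one corrupted DW volume at one voxel
        tf = dti.fit_tensor(dti.DWIVolume(vol, np.eye(4), default_scheme), np.ones((1, 1, 2), bool))
        assert tf.mask.all()  # still fit from remaining rows
        np.testing.assert_allclose(tf.tensor_at((0, 0, 1)), D, rtol=1e-6, atol=1e-12)

    def test_fa_bias_under_rician_noise_snr20(self, default_scheme):
        """Median FA bias over replicate voxels stays below 0.02 at b0
        SNR 20 for a strongly anisotropic tensor."""
        D = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        sig = dti.predict_signal(D, 1000.0, default_scheme)
        n = 1000
        noisy = add_rician_noise(np.tile(sig, (n, 1)), 50.0, 2024)
        dwi = dti.DWIVolume(noisy.reshape(n, 1, 1, -1), np.eye(4), default_scheme)
        maps, _ = dti.maps_from_dwi(dwi, np.ones((n, 1, 1), bool))
        true_fa = np.sqrt(1.5) * np.sqrt(np.sum((np.diag(D) - D.trace() / 3) ** 2)) / np.sqrt(
            np.sum(np.diag(D) ** 2)
        )
        assert abs(np.median(maps.fa[:, 0, 0]) - true_fa) < 0.02


class TestEigensystemScalarMaps:
    def test_diagonal_tensor(self):
        comps = dti.matrix_to_components(np.diag([3e-3, 2e-3, 1e-3]))
        tf = dti.TensorField(
            tensors=comps.reshape(1, 1, 1, 6), s0=np.ones((1, 1, 1)),
            mask=np.ones((1, 1, 1), bool), affine=np.eye(4),
        )
        evals, evecs, _ = dti.eigensystem(tf)
        np.testing.assert_allclose(evals[0, 0, 0], [3e-3, 2e-3, 1e-3])
        assert abs(evecs[0, 0, 0] @ [1, 0, 0]) == pytest.approx(1.0)

    def test_rotation_invariance_of_eigenvalues_and_fa(self):
        rng = np.random.default_rng(3)
        lam = np.diag([1.7e-3, 0.5e-3, 0.2e-3])
        R = Rotation.random(random_state=5).as_matrix()
        rotated = R @ lam @ R.T
        both = np.stack([dti.matrix_to_components(lam), dti.matrix_to_components(rotated)])
        tf = dti.TensorField(
            tensors=both.reshape(2, 1, 1, 6), s0=np.ones((2, 1, 1)),
            mask=np.ones((2, 1, 1), bool), affine=np.eye(4),
        )
        evals, evecs, _ = dti.eigensystem(tf)
        np.testing.assert_allclose(evals[0, 0, 0], evals[1, 0, 0], rtol=1e-10)
        maps = dti.scalar_maps(evals, tf.mask, tf.affine)
        assert maps.fa[0, 0, 0] == pytest.approx(maps.fa[1, 0, 0], rel=1e-10)

    def test_negative_eigenvalue_clamped_and_counted(self):
        comps = dti.matrix_to_components(np.diag([1e-3, 1e-4, -1e-5]))
        tf = dti.TensorField(
            tensors=comps.reshape(1, 1, 1, 6), s0=np.ones((1, 1, 1)),
            mask=np.ones((1, 1, 1), bool), affine=np.eye(4),
        )
        evals, _, n_clamped = dti.eigensystem(tf)
        assert n_clamped == 1
        assert evals.min() == 0.0

    @pytest.mark.parametrize(
        "lam,fa,md,ad,rd",
        [
            ((5e-4, 5e-4, 5e-4), 0.0, 5e-4, 5e-4, 5e-4),
            ((1.0, 0.0, 0.0), 1.0, 1 / 3, 1.0, 0.0),
            ((1.7e-3, 0.3e-3, 0.3e-3), 0.7990222, 0.76667e-3, 1.7e-3, 0.3e-3),
        ],
    )
    def test_scalar_map_formulas(self, lam, fa, md, ad, rd):
        evals = np.array(lam).reshape(1, 1, 1, 3)
        maps = dti.scalar_maps(evals, np.ones((1, 1, 1), bool), np.eye(4))
        assert maps.fa[0, 0, 0] == pytest.approx(fa, abs=1e-6)
        assert maps.md[0, 0, 0] == pytest.approx(md, rel=1e-4)
        assert maps.ad[0, 0, 0] == pytest.approx(ad, rel=1e-9)
        assert maps.rd[0, 0, 0] == pytest.approx(rd, abs=1e-12)

    def test_md_identity_within_mask(self):
        rng = np.random.default_rng(0)
        evals = np.sort(rng.uniform(0, 3e-3, size=(4, 4, 4, 3)))[..., ::-1]
        maps = dti.scalar_maps(evals, np.ones((4, 4, 4), bool), np.eye(4))
        np.testing.assert_allclose(maps.md, (maps.ad + 2 * maps.rd) / 3, atol=1e-15)

    def test_all_zero_eigenvalues_give_zero_fa(self):
        maps = dti.scalar_maps(np.zeros((1, 1, 1, 3)), np.ones((1, 1, 1), bool), np.eye(4))
        assert maps.fa[0, 0, 0] == 0.0


@given(
    fa=st.floats(min_value=0.05, max_value=0.9),
    md=st.floats(min_value=2e-4, max_value=2e-3),
)
@settings(max_examples=40, deadline=None)
def test_prolate_eigenvalues_reproduce_requested_fa_md(fa, md):
    l1, l2, l3 = dti.prolate_eigenvalues(fa, md)
    evals = np.array([l1, l2, l3]).reshape(1, 1, 1, 3)
    maps = dti.scalar_maps(evals, np.ones((1, 1, 1), bool), np.eye(4))
    assert maps.fa[0, 0, 0] == pytest.approx(fa, rel=1e-9)
    assert maps.md[0, 0, 0] == pytest.approx(md, rel=1e-9)
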