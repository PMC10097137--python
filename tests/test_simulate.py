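"""Synthetic cohort generator: phantoms, noise, subjects, datasets."""

import json

import numpy as np
import pytest

from longtbss import dti
from longtbss.registration import AffineTransform
from longtbss.simulate import (
    CohortSpec,
    PhantomSpec,
    Tract,
    add_rician_noise,
    default_tracts,
    make_phantom,
    phantom_scalar_maps,
    simulate_cohort,
    simulate_subject,
    smoke_preset,
    trackon_preset,
)


class TestMakePhantom:
    def test_straight_tube_axis_fa_matches_spec(self, straight_tube):
        phantom, maps = straight_tube
        axis_fa = maps.fa[phantom.centerline]
        assert np.all(np.abs(axis_fa - 0.6) < 0.01)

    def test_background_only_is_isotropic(self):
        phantom = make_phantom(PhantomSpec(grid_shape=(10, 10, 10)))
        maps = phantom_scalar_maps(phantom)
        np.testing.assert_allclose(maps.fa, 0.0, atol=1e-9)
        np.testing.assert_allclose(maps.md, 0.7e-3, rtol=1e-9)

    def test_arc_principal_axis_tangent_to_arc(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48), tracts=(default_tracts()[1],))
        phantom = make_phantom(spec)
        tf = dti.TensorField(
            tensors=phantom.tensors, s0=np.full(spec.grid_shape, 1000.0),
            mask=np.ones(spec.grid_shape, bool), affine=phantom.affine,
        )
        _, evecs, _ = dti.eigensystem(tf)
        tract = spec.tracts[0]
        idx = np.argwhere(phantom.centerline)
        pts = idx * spec.voxel_size
        _, tangents = tract.distance_tangent(pts, spec.fov_mm())
        dots = np.abs(np.einsum("ij,ij->i", evecs[phantom.centerline], tangents))
        assert np.all(dots > 0.99)

    def test_overlapping_tracts_rejected(self):
        t = Tract(name="a", point=(0.5, 0.5, 0.5), direction=(0, 1, 0), radius=4.0)
        u = Tract(name="b", point=(0.52, 0.5, 0.5), direction=(0, 0, 1), radius=4.0)
        with pytest.raises(ValueError, match="overlap"):
            make_phantom(PhantomSpec(grid_shape=(32, 32, 32), tracts=(t, u)))
        make_phantom(PhantomSpec(grid_shape=(32, 32, 32), tracts=(t, u), allow_overlap=True))

    def test_posed_phantom_moves_centerline(self):
        spec = PhantomSpec(
            grid_shape=(32, 32, 32),
            tracts=(Tract(name="t", point=(0.5, 0.5, 0.5), direction=(0, 1, 0), radius=3.0),),
        )
        m = np.eye(4)
        m[0, 3] = 4.0  # 2 voxels
        moved = make_phantom(spec, pose=AffineTransform(m))
        ref = make_phantom(spec)
        np.testing.assert_array_equal(moved.centerline[2:], ref.centerline[:-2])

    def test_tract_mods_shift_axis_fa_and_md(self):
        spec = PhantomSpec(
            grid_shape=(32, 32, 32),
            tracts=(Tract(name="t", point=(0.5, 0.5, 0.5), direction=(0, 1, 0),
                          radius=3.0, peak_fa=0.6, md=0.75e-3),),
        )
        base = phantom_scalar_maps(make_phantom(spec))
        changed = phantom_scalar_maps(make_phantom(spec, tract_mods={"t": (-0.03, 0.05e-3)}))
        cl = make_phantom(spec).centerline
        assert np.median(base.fa[cl] - changed.fa[cl]) == pytest.approx(0.03, abs=0.002)
        assert np.median(changed.md[cl] - base.md[cl]) == pytest.approx(0.05e-3, rel=0.05)

    def test_invalid_tract_parameters_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            Tract(name="x", radius=1.0)
        with pytest.raises(ValueError, match="FA"):
            Tract(name="x", peak_fa=0.1)


class TestRicianNoise:
    def test_sigma_zero_is_identity(self):
        sig = np.linspace(10, 100, 7)
        out = add_rician_noise(sig, 0.0, 1)
        np.testing.assert_array_equal(out, sig)

    def test_zero_signal_rayleigh_mean(self):
        """At S = 0 the magnitude is Rayleigh with mean sigma*sqrt(pi/2)."""
        out = add_rician_noise(np.zeros(100_000), 1.0, 42)
        assert out.mean() == pytest.approx(np.sqrt(np.pi / 2), rel=0.01)
        assert np.all(out >= 0)

    def test_high_snr_limit_is_unbiased(self):
        out = add_rician_noise(np.full(100_000, 100.0), 1.0, 43)
        assert out.mean() == pytest.approx(100.0, rel=1e-3)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), -1.0, 0)

    def test_deterministic_per_seed(self):
        a = add_rician_noise(np.ones(100), 0.5, 7)
        b = add_rician_noise(np.ones(100), 0.5, 7)
        np.testing.assert_array_equal(a, b)


class TestSimulateSubject:
    def test_control_visits_identical_without_noise_or_misalignment(self):
        spec = smoke_preset(seed=0, n=2)
        rng = np.random.default_rng(0)
        d1, d2, truth = simulate_subject(spec, "control", 0.0, rng, misalign=False, noise=False)
        np.testing.assert_array_equal(d1.data, d2.data)
        np.testing.assert_array_equal(truth.pose_visit1, np.eye(4))

    def test_carrier_axis_fa_drops_by_injected_delta(self):
        """Noiseless, alignment-free carrier: fitting both visits recovers
        the injected axis FA decline through the full forward model."""
        spec = smoke_preset(seed=0, n=2, grid=32)
        rng = np.random.default_rng(1)
        d1, d2, truth = simulate_subject(spec, "carrier", 1.0, rng, misalign=False, noise=False)
        mask = np.ones(d1.shape3d, bool)
        maps1, _ = dti.maps_from_dwi(d1, mask)
        maps2, _ = dti.maps_from_dwi(d2, mask)
        phantom = make_phantom(spec.phantom)
        slf = (phantom.label == 1) & phantom.centerline
        drop = np.median(maps1.fa[slf] - maps2.fa[slf])
        expected = -truth.tract_mods["slf_like"][0]
        assert drop == pytest.approx(expected, abs=0.003)

    def test_misalignment_draw_respects_bounds(self):
        spec = smoke_preset(seed=0, n=2)
        rng = np.random.default_rng(2)
        _, _, truth = simulate_subject(spec, "control", 0.0, rng)
        t_vox = np.abs(truth.pose_visit1[:3, 3]) / spec.phantom.voxel_size
        # rotation about the FOV center adds to the translation column;
        # bound it loosely by translation + rotation lever arm
        assert np.all(t_vox < spec.max_translation_vox + 3)
        R = truth.pose_visit1[:3, :3]
        angle = np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))
        assert angle <= spec.max_rotation_deg * np.sqrt(3) + 1e-6


def tiny_spec(seed, n):
    """Small fast cohort for dataset-level tests (24^3 smoke geometry)."""
    return smoke_preset(seed=seed, n=n)


class TestSimulateCohort:
    def test_dataset_layout_and_reproducibility(self, tmp_path):
        spec = tiny_spec(seed=5, n=2)
        t1, _ = simulate_cohort(spec, tmp_path / "a")
        t2, _ = simulate_cohort(spec, tmp_path / "b")
        assert (tmp_path / "a" / "sub-001" / "ses-1" / "dwi.nii.gz").exists()
        assert (tmp_path / "a" / "sub-004" / "ses-2" / "dwi.bvec").exists()
        csv_a = (tmp_path / "a" / "participants.csv").read_bytes()
        csv_b = (tmp_path / "b" / "participants.csv").read_bytes()
        assert csv_a == csv_b
        truth_a = (tmp_path / "a" / "truth.json").read_bytes()
        truth_b = (tmp_path / "b" / "truth.json").read_bytes()
        assert truth_a == truth_b

    def test_trackon_preset_counts(self):
        spec = trackon_preset()
        assert spec.n_control + spec.n_carrier == 144
        assert spec.n_control == 67
        assert spec.interval_months == 24.0

    def test_carrier_scores_coupled_to_magnitude(self):
        """Across many carrier draws the TMS~magnitude regression slope
        recovers the configured coupling k (worse motor score with larger
        injected change) and SDMT couples negatively."""
        from longtbss.simulate import _draw_clinical

        spec = tiny_spec(seed=0, n=4)
        rng = np.random.default_rng(21)
        mags = rng.normal(1.0, spec.subject_sd, 500).clip(0.2, 2.0)
        recs = [
            _draw_clinical(spec, f"s{i}", "carrier", m, "siteA", rng)
            for i, m in enumerate(mags)
        ]
        k = spec.score_couplings()["tms"].k
        slope = np.polyfit(mags, [r.tms for r in recs], 1)[0]
        assert slope == pytest.approx(k, rel=0.25)
        assert np.polyfit(mags, [r.sdmt for r in recs], 1)[0] < 0

    def test_clinical_ranges_valid(self, tmp_path):
        spec = tiny_spec(seed=3, n=6)
        table, _ = simulate_cohort(spec, tmp_path / "d")
        for rec in table:
            assert not rec.validate()
            if rec.group == "carrier":
                assert rec.cag >= 40
            else:
                assert rec.cag is None

    def test_truth_json_readable(self, tmp_path):
        spec = tiny_spec(seed=4, n=2)
        simulate_cohort(spec, tmp_path / "e")
        blob = json.loads((tmp_path / "e" / "truth.json").read_text())
        assert set(blob) == {"changes", "couplings", "subjects"}
        assert len(blob["subjects"]) == 4
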