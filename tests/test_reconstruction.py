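"""Tensor fitting, eigenvalue maps, ROI statistics, and round-trip accuracy."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cardiodwi.phantoms import (PVP_ADC_M012, make_cardiac_phantom,
                                make_pvp_phantom, tensor_components)
from cardiodwi.reconstruct import (ScalarMap, TensorField, eigen_adc, fa_map,
                                   fit_tensor, roi_stats)
from cardiodwi.simulate import DEFAULT_DIRECTIONS, DWIDataset, simulate_dwi


def _uniform_dataset(tensor, directions=DEFAULT_DIRECTIONS, b=350.0,
                     shape=(4, 4, 1), s0=1.0):
    """Noiseless dataset with the same tensor in every voxel."""
    d = np.asarray(tensor)
    bvals = np.concatenate([[0.0], np.full(len(directions), b)])
    bvecs = np.vstack([[0, 0, 0], directions])
    vols = np.empty(shape + (len(bvals),))
    vols[..., 0] = s0
    for j, g in enumerate(directions):
        vols[..., j + 1] = s0 * np.exp(-b * g @ d @ g)
    return DWIDataset(vols, bvals, bvecs, np.ones(shape, dtype=bool))


def _field_from_eigenvalues(lam):
    tensors = np.zeros((1, 1, 1, 6))
    tensors[0, 0, 0, :3] = lam
    return TensorField(tensors, np.ones((1, 1, 1), dtype=bool))


class TestFitTensor:
    def test_noiseless_isotropic_recovered_to_float_precision(self):
        d = 1.578e-3 * np.eye(3)
        tf = fit_tensor(_uniform_dataset(d))
        assert np.allclose(tf.tensors[tf.valid],
                           tensor_components(d), atol=1e-15)

    def test_noiseless_anisotropic_recovery_and_md(self):
        d = np.diag([2.0e-3, 1.0e-3, 1.0e-3])
        tf = fit_tensor(_uniform_dataset(d))
        assert np.allclose(tf.tensors[tf.valid], tensor_components(d),
                           atol=1e-12)
        adc = eigen_adc(tf)
        assert adc.data[tf.valid] == pytest.approx(4.0e-3 / 3, rel=1e-9)

    def test_full_tensor_with_off_diagonals_recovered(self):
        rot = Rotation.from_euler("xyz", [20, -35, 50],
                                  degrees=True).as_matrix()
        d = rot @ np.diag([2.2e-3, 1.4e-3, 0.9e-3]) @ rot.T
        tf = fit_tensor(_uniform_dataset(d))
        assert np.allclose(tf.tensors[tf.valid], tensor_components(d),
                           rtol=1e-9)

    def test_duplicated_encodings_leave_fit_unchanged(self):
        d = np.diag([2.0e-3, 1.5e-3, 1.0e-3])
        ds = _uniform_dataset(d)
        doubled = DWIDataset(
            np.concatenate([ds.volumes, ds.volumes[..., 1:]], axis=-1),
            np.concatenate([ds.bvals, ds.bvals[1:]]),
            np.vstack([ds.bvecs, ds.bvecs[1:]]), ds.mask)
        assert np.allclose(fit_tensor(doubled).tensors,
                           fit_tensor(ds).tensors, atol=1e-15)

    def test_weighted_fit_matches_ols_on_noiseless_data(self):
        d = np.diag([2.0e-3, 1.5e-3, 1.0e-3])
        ds = _uniform_dataset(d)
        assert np.allclose(fit_tensor(ds, weighted=True).tensors,
                           fit_tensor(ds).tensors, atol=1e-12)

    def test_nonpositive_signal_flags_voxel_invalid(self):
        ds = _uniform_dataset(1.5e-3 * np.eye(3))
        ds.volumes[0, 0, 0, 3] = 0.0
        tf = fit_tensor(ds)
        assert not tf.valid[0, 0, 0]
        assert tf.valid[1:].all()

    def test_missing_b0_rejected(self):
        ds = _uniform_dataset(1.5e-3 * np.eye(3))
        bad = DWIDataset(ds.volumes[..., 1:], ds.bvals[1:], ds.bvecs[1:],
                         ds.mask)
        with pytest.raises(ValueError, match="b=0"):
            fit_tensor(bad)

    def test_rank_deficient_directions_rejected(self):
        g = np.array([[1.0, 0, 0]] * 6)
        ds = _uniform_dataset(1.5e-3 * np.eye(3), directions=g)
        with pytest.raises(ValueError, match="rank"):
            fit_tensor(ds)


class TestEigenMaps:
    def test_adc_is_arithmetic_eigenvalue_mean(self):
        adc = eigen_adc(_field_from_eigenvalues([2.0e-3, 1.5e-3, 1.0e-3]))
        assert adc.data[0, 0, 0] == pytest.approx(1.5e-3, rel=1e-12)

    def test_adc_rotation_invariant(self):
        lam = np.diag([2.2e-3, 1.4e-3, 0.9e-3])
        rot = Rotation.from_euler("zyx", [12, 45, -78],
                                  degrees=True).as_matrix()
        t = np.zeros((1, 1, 1, 6))
        t[0, 0, 0] = tensor_components(rot @ lam @ rot.T)
        adc = eigen_adc(TensorField(t, np.ones((1, 1, 1), bool)))
        assert adc.data[0, 0, 0] == pytest.approx(lam.trace() / 3, rel=1e-12)

    @pytest.mark.parametrize("lam,expected", [
        ([1.5e-3, 1.5e-3, 1.5e-3], 0.0),        # isotropic
        ([1.0, 0.0, 0.0], 1.0),                  # degenerate stick
        ([2.0e-3, 1.0e-3, 1.0e-3], 0.40824829),  # hand-evaluated
    ])
    def test_fa_reference_values(self, lam, expected):
        fa = fa_map(_field_from_eigenvalues(lam))
        assert fa.data[0, 0, 0] == pytest.approx(expected, abs=1e-8)

    def test_fa_bounded_and_nan_for_zero_tensor(self):
        fa = fa_map(_field_from_eigenvalues([0.0, 0.0, 0.0]))
        assert np.isnan(fa.data[0, 0, 0])
        rng = np.random.default_rng(4)
        for _ in range(50):
            lam = rng.uniform(0, 3e-3, 3)
            v = fa_map(_field_from_eigenvalues(lam)).data[0, 0, 0]
            assert 0.0 <= v <= 1.0


class TestRoundTrip:
    def test_noiseless_pvp_round_trip_is_exact(self, pvp_phantom, m012_wf):
        ds = simulate_dwi(pvp_phantom, m012_wf)
        adc = eigen_adc(fit_tensor(ds))
        stats = roi_stats(adc, pvp_phantom.region_map)
        for s in stats:
            truth = pvp_phantom.true_md[s.label]
            assert abs(s.mean - truth) / truth < 1e-9

    def test_noiseless_cardiac_round_trip_recovers_helix_tensors(
            self, cardiac_phantom, m012_wf):
        ds = simulate_dwi(cardiac_phantom, m012_wf)
        tf = fit_tensor(ds)
        sel = cardiac_phantom.region_map == 1
        assert np.allclose(tf.tensors[sel], cardiac_phantom.tensors[sel],
                           rtol=1e-9)

    def test_rotating_tensors_and_bvecs_together_preserves_maps(self):
        rot = Rotation.from_euler("xyz", [30, 10, -25],
                                  degrees=True).as_matrix()
        d = np.diag([2.0e-3, 1.2e-3, 0.8e-3])
        ds = _uniform_dataset(d)
        ds_rot = _uniform_dataset(rot @ d @ rot.T,
                                  directions=DEFAULT_DIRECTIONS @ rot.T)
        adc, adc_rot = (eigen_adc(fit_tensor(x)) for x in (ds, ds_rot))
        fa, fa_rot = (fa_map(fit_tensor(x)) for x in (ds, ds_rot))
        assert np.allclose(adc.data, adc_rot.data, rtol=1e-9)
        assert np.allclose(fa.data, fa_rot.data, rtol=1e-9)

    def test_rician_adc_bias_below_two_percent_at_snr_25(self, m012_wf):
        # Monte-Carlo over >500 myocardial voxels at snr = 25, b = 350
        ph = make_cardiac_phantom(myo_md=1.578e-3)
        sel = ph.region_map == 1
        vals = []
        for seed in range(3):
            ds = simulate_dwi(ph, m012_wf, snr=25.0, seed=seed)
            adc = eigen_adc(fit_tensor(ds))
            vals.append(adc.data[sel & adc.valid])
        vals = np.concatenate(vals)
        assert vals.size >= 500
        assert abs(vals.mean() - 1.578e-3) / 1.578e-3 < 0.02


class TestRoiStats:
    def test_constant_region_gives_mean_and_zero_sd(self):
        data = np.full((4, 4, 1), 2.5)
        labels = np.ones((4, 4, 1), dtype=int)
        (s,) = roi_stats(ScalarMap(data, "ADC"), labels)
        assert (s.mean, s.sd, s.n_voxels) == (2.5, 0.0, 16)

    def test_disjoint_labels_are_independent(self):
        data = np.zeros((4, 4, 1))
        labels = np.zeros((4, 4, 1), dtype=int)
        labels[:2], labels[2:] = 1, 2
        data[labels == 1] = 1.0
        data[labels == 2] = 3.0
        s1, s2 = roi_stats(ScalarMap(data, "ADC"), labels)
        assert (s1.mean, s2.mean) == (1.0, 3.0)

    def test_empty_label_raises(self):
        data = np.ones((2, 2, 1))
        labels = np.ones((2, 2, 1), dtype=int)
        with pytest.raises(ValueError, match="no valid voxels"):
            roi_stats(ScalarMap(data, "ADC"), labels, labels=[5])

    def test_smallest_pvp_vial_recovered_exactly(self, m012_wf):
        ph = make_pvp_phantom(PVP_ADC_M012)
        ds = simulate_dwi(ph, m012_wf)
        adc = eigen_adc(fit_tensor(ds))
        stats = {s.label: s for s in roi_stats(adc, ph.region_map)}
        assert stats[6].mean == pytest.approx(1.37e-3, rel=1e-9)
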