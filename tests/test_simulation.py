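"""Voxel signal model: attenuation, moment phase, dephasing, Rician noise."""

import numpy as np
import pytest

from cardiodwi.phantoms import make_cardiac_phantom
from cardiodwi.simulate import (MotionState, add_rician_noise,
                                dephasing_ensemble, dephasing_factor,
                                encode_voxel, simulate_dwi)
from cardiodwi.waveforms import gradient_moments

GX = np.array([1.0, 0.0, 0.0])


class TestEncodeVoxel:
    @pytest.mark.parametrize("d,expected", [
        (1.578e-3, 0.57562),  # healthy myocardium at b = 350
        (2.21e-3, 0.46138),   # 0% PVP vial
    ])
    def test_static_attenuation_matches_scalar_closed_form(self, d, expected):
        sig = encode_voxel(d, s0=1.0, b=350.0, direction=GX)
        assert sig.magnitude == pytest.approx(np.exp(-350.0 * d), rel=1e-12)
        assert sig.magnitude == pytest.approx(expected, abs=5e-5)

    def test_anisotropic_attenuation_projects_tensor(self):
        d = np.diag([2.0e-3, 1.0e-3, 1.0e-3])
        sig = encode_voxel(d, 1.0, 350.0, GX)
        assert sig.magnitude == pytest.approx(np.exp(-0.7), rel=1e-12)

    def test_m012_signal_invariant_to_arbitrary_bulk_motion(self, m012_wf, rng):
        static = encode_voxel(1.578e-3, 1.0, 350.0, GX, wf=m012_wf)
        for _ in range(10):
            motion = MotionState(r0=tuple(rng.normal(0, 1e-3, 3)),
                                 v=tuple(rng.normal(0, 0.05, 3)),
                                 a=tuple(rng.normal(0, 5.0, 3)),
                                 v_spread=float(rng.uniform(0, 0.05)))
            moved = encode_voxel(1.578e-3, 1.0, 350.0, GX, wf=m012_wf,
                                 motion=motion)
            assert moved.phase == pytest.approx(0.0, abs=1e-9)
            assert moved.magnitude == pytest.approx(static.magnitude,
                                                    rel=1e-12)

    def test_bulk_phase_matches_numerical_trajectory_integral(self, st_wf):
        # independent oracle: gamma * int G_eff(t) x(t) dt for the
        # polynomial trajectory x(t) = x0 + v t + a t^2 / 2
        gamma = 2.675221874e8
        x0, v, a = 2.1e-4, 1.3e-2, 3.7
        g_eff = st_wf.effective_samples
        t = st_wf.times
        expected = gamma * np.sum(g_eff * (x0 + v * t + 0.5 * a * t * t)) \
            * st_wf.dt
        sig = encode_voxel(1.5e-3, 1.0, 350.0, GX, wf=st_wf,
                           motion=MotionState(r0=(x0, 0, 0), v=(v, 0, 0),
                                              a=(a, 0, 0)))
        assert sig.phase == pytest.approx(expected, rel=1e-10)

    def test_phase_projects_on_encoding_axis(self, st_wf):
        # motion orthogonal to the encoding direction leaves no phase
        sig = encode_voxel(1.5e-3, 1.0, 350.0, GX, wf=st_wf,
                           motion=MotionState(v=(0.0, 0.02, 0.0)))
        assert sig.phase == 0.0

    def test_attenuation_monotone_in_b_and_projection(self):
        bs = np.linspace(0.0, 1000.0, 7)
        mags = [encode_voxel(1.5e-3, 1.0, b, GX).magnitude for b in bs]
        assert np.all(np.diff(mags) < 0)
        ds = np.linspace(0.5e-3, 3e-3, 7)
        mags_d = [encode_voxel(d, 1.0, 350.0, GX).magnitude for d in ds]
        assert np.all(np.diff(mags_d) < 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            encode_voxel(1.5e-3, 1.0, 350.0, np.array([1.0, 1.0, 0.0]))
        with pytest.raises(ValueError, match="s0"):
            encode_voxel(1.5e-3, -1.0, 350.0, GX)


class TestDephasing:
    def test_closed_form_matches_isochromat_ensemble(self, st_wf):
        m1 = gradient_moments(st_wf).m1
        v_spread = 7e-4  # small enough for a measurable factor
        analytic = dephasing_factor(m1, v_spread)
        ensemble = dephasing_ensemble(m1, v_spread, n=200_000, seed=11)
        assert 0.05 < analytic < 0.95  # informative regime
        assert abs(ensemble) == pytest.approx(analytic, abs=5e-3)

    def test_systolic_spread_destroys_m0_but_not_m012_signal(
            self, st_wf, m012_wf):
        spread = 10e-3  # 10 mm/s intravoxel systolic velocity spread
        f_m0 = dephasing_factor(gradient_moments(st_wf).m1, spread)
        f_m012 = dephasing_factor(gradient_moments(m012_wf).m1, spread)
        assert f_m0 < 0.1
        assert f_m012 > 0.99


class TestRicianNoise:
    def test_zero_signal_gives_rayleigh_mean(self):
        # |n1 + i n2| with sigma = 1 has mean sqrt(pi/2)
        out = add_rician_noise(np.zeros((100, 100, 100)), snr=1.0,
                               seed=3, reference=1.0)
        assert out.mean() == pytest.approx(np.sqrt(np.pi / 2), abs=3e-3)

    def test_infinite_snr_limit_returns_input(self):
        vol = np.full((8, 8, 1, 3), 2.0)
        out = add_rician_noise(vol, snr=1e12, seed=0, reference=1.0)
        assert np.allclose(out, vol, rtol=1e-9)

    def test_seeded_reproducibility(self):
        vol = np.ones((8, 8, 1, 3))
        a = add_rician_noise(vol, snr=10.0, seed=7, reference=1.0)
        b = add_rician_noise(vol, snr=10.0, seed=7, reference=1.0)
        assert np.array_equal(a, b)

    def test_invalid_snr_rejected(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones((2, 2, 1, 1)), snr=0.0)


class TestSimulateDWI:
    def test_dataset_layout(self, cardiac_phantom, m012_wf):
        ds = simulate_dwi(cardiac_phantom, m012_wf)
        assert ds.volumes.shape[3] == 7  # one b=0 + six directions
        assert ds.bvals[0] == 0.0
        assert np.all(ds.bvals[1:] == pytest.approx(350.0, rel=1e-6))
        assert np.allclose(np.linalg.norm(ds.bvecs[1:], axis=1), 1.0)

    def test_noiseless_simulation_is_bit_reproducible(self, cardiac_phantom,
                                                      m012_wf):
        a = simulate_dwi(cardiac_phantom, m012_wf)
        b = simulate_dwi(cardiac_phantom, m012_wf)
        assert np.array_equal(a.volumes, b.volumes)

    def test_noisy_simulation_deterministic_per_seed(self, cardiac_phantom,
                                                     m012_wf):
        a = simulate_dwi(cardiac_phantom, m012_wf, snr=25.0, seed=5)
        b = simulate_dwi(cardiac_phantom, m012_wf, snr=25.0, seed=5)
        c = simulate_dwi(cardiac_phantom, m012_wf, snr=25.0, seed=6)
        assert np.array_equal(a.volumes, b.volumes)
        assert not np.array_equal(a.volumes, c.volumes)

    def test_moving_heart_vanishes_with_m0_encoding(self, st_wf, m012_wf):
        motion = MotionState(v_spread=10e-3)
        moving = make_cardiac_phantom(motion=motion)
        myo = moving.region_map == 1
        sig_m0 = simulate_dwi(moving, st_wf).volumes[myo][:, 1:].mean()
        sig_m012 = simulate_dwi(moving, m012_wf).volumes[myo][:, 1:].mean()
        assert sig_m0 / sig_m012 < 0.1
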