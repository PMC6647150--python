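"""Normal-form transform, averaged OU approximation and radial SDEs."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import fhnlif as F
from fhnlif.normal_form import rotation

from conftest import random_excitable_params


class TestTransform:
    def test_similarity_at_reference_parameters(self, eq, nf01):
        assert np.abs(nf01.Q_inv @ eq.M @ nf01.Q - nf01.A).max() < 1e-10

    def test_similarity_for_random_excitable_sets(self):
        rng = np.random.default_rng(12)
        for p, eq_ in random_excitable_params(rng, 100):
            nf = F.build_normal_form(eq_.M, eq_.mu, eq_.nu, 0.01)
            assert np.abs(nf.Q_inv @ eq_.M @ nf.Q - nf.A).max() < 1e-10

    def test_transformed_noise_vector_components(self, params, nf01):
        h = nf01.h_e / nf01.sigma0
        assert h[0] == pytest.approx(1.27722, rel=1e-4)
        # second component is exactly 1/m21 = 1/epsilon
        assert h[1] == pytest.approx(1.0 / params.epsilon, abs=1e-12)

    def test_noise_norm_identities(self, eq, nf01):
        h2 = (nf01.h_e @ nf01.h_e) / nf01.sigma0**2
        assert h2 == pytest.approx(157.881, rel=1e-3)
        m12, m21 = eq.M[0, 1], eq.M[1, 0]
        assert h2 == pytest.approx(-m12 / (m21 * eq.nu**2), rel=1e-12)
        assert nf01.transform_factor**2 == pytest.approx(h2, rel=1e-12)
        # ||h_e||^2 = tr(C C*)
        assert nf01.h_e @ nf01.h_e == pytest.approx(
            np.trace(nf01.C @ nf01.C.T), rel=1e-12)

    def test_effective_amplitude(self, nf01):
        assert nf01.sigma_eff / nf01.sigma0 == pytest.approx(8.88486, rel=1e-5)

    def test_degenerate_m21_rejected(self):
        M = np.array([[0.0, -1.0], [0.0, -0.1]])
        with pytest.raises(ValueError):
            F.build_normal_form(M, 0.05, 0.3, 0.01)

    def test_rotation_matrix_convention(self):
        R = rotation(np.pi / 2)
        assert np.allclose(R @ [1.0, 0.0], [0.0, 1.0], atol=1e-12)


class TestAveragedOU:
    def test_noiseless_decay_is_exact(self, eq):
        nf0 = F.build_normal_form(eq.M, eq.mu, eq.nu, 0.0)
        y0 = np.array([0.3, -0.1])
        times, Y = F.averaged_ou_path(nf0, y0, F.SimConfig(dt=0.05, T=50.0,
                                                           seed=1))
        norm = np.linalg.norm(Y, axis=-1)
        expected = np.linalg.norm(y0) * np.exp(-eq.mu * times)
        assert np.allclose(norm, expected, rtol=1e-12)

    def test_stationary_component_variance(self, nf01):
        cfg = F.SimConfig(dt=0.05, T=200.0)
        _, Y = F.averaged_ou_path(nf01, (0.0, 0.0), cfg,
                                  rng=np.random.default_rng(13),
                                  n_paths=4000)
        var = Y[-1].var(axis=0)  # terminal ensemble, past the relaxation time
        target = nf01.sigma_eff**2 / (2 * nf01.mu)
        assert np.all(np.abs(var / target - 1.0) < 0.05)

    def test_psd_peaks_at_rotation_frequency(self, nf01):
        cfg = F.SimConfig(dt=0.01, T=500.0)
        _, Y = F.averaged_ou_path(nf01, (0.0, 0.0), cfg,
                                  rng=np.random.default_rng(14), n_paths=6)
        x = Y[:, :, 0].T[:, ::10]  # decimate for frequency resolution
        est = F.psd_estimate(x, 0.1, nperseg=2048)
        assert est.peak_frequency == pytest.approx(nf01.nu / (2 * np.pi),
                                                   rel=0.2)


class TestRadialOU:
    def test_noiseless_decay(self, eq):
        nf0 = F.build_normal_form(eq.M, eq.mu, eq.nu, 0.0)
        cfg = F.SimConfig(dt=0.05, T=100.0, seed=2)
        traj = F.simulate_radial_ou(nf0, R0=1.0, config=cfg, backend="norm")
        assert np.allclose(traj.R, np.exp(-eq.mu * traj.times), rtol=1e-12)

    def test_mu_recovered_from_noiseless_decay(self, eq):
        nf0 = F.build_normal_form(eq.M, eq.mu, eq.nu, 0.0)
        traj = F.simulate_radial_ou(nf0, R0=1.0,
                                    config=F.SimConfig(dt=0.05, T=100.0,
                                                       seed=3))
        slope = np.polyfit(traj.times, np.log(traj.R), 1)[0]
        assert -slope == pytest.approx(eq.mu, rel=0.01)

    def test_stationary_law_is_rayleigh(self, nf01):
        from scipy.stats import kstest, rayleigh
        rng = np.random.default_rng(15)
        R = F.RadialOUSampler(nf01, R0=0.0).sample_at([400.0], 4000, rng)[:, 0]
        scale = nf01.sigma_eff / np.sqrt(2 * nf01.mu)
        assert kstest(R, rayleigh(scale=scale).cdf).statistic < 0.05

    def test_backends_agree_in_law(self, nf01):
        cfg = F.SimConfig(dt=0.02, T=120.0, seed=4)
        eul = F.simulate_radial_ou(nf01, R0=0.35, config=cfg,
                                   backend="euler", n_paths=1500)
        rng = np.random.default_rng(16)
        ref = F.RadialOUSampler(nf01, R0=0.35).sample_at([120.0], 1500,
                                                         rng)[:, 0]
        assert ks_2samp(eul.R[-1], ref).statistic < 0.05

    def test_euler_backend_requires_positive_start(self, nf01):
        with pytest.raises(ValueError):
            F.simulate_radial_ou(nf01, R0=0.0,
                                 config=F.SimConfig(dt=0.01, T=1.0),
                                 backend="euler")


class TestPolarRadial:
    def test_diffusion_time_average_equals_sigma_eff_squared(self, nf01):
        t = np.linspace(0.0, 2 * np.pi / nf01.nu, 20001)
        d = nf01.h_e[0] * np.sin(nf01.nu * t) + nf01.h_e[1] * np.cos(nf01.nu * t)
        assert np.trapezoid(d**2, t) / t[-1] == pytest.approx(
            nf01.sigma_eff**2, rel=1e-4)

    def test_drift_numerator_vanishes_when_aligned_with_noise(self, nf01):
        h = nf01.h_e
        t_star = np.arctan2(h[0], h[1]) / nf01.nu  # theta(t*) parallel to h
        d = h[0] * np.sin(nf01.nu * t_star) + h[1] * np.cos(nf01.nu * t_star)
        assert (h @ h) - d**2 == pytest.approx(0.0, abs=1e-12)

    def test_positive_start_required(self, nf01):
        with pytest.raises(ValueError):
            F.simulate_polar_radial(nf01, R0=0.0,
                                    config=F.SimConfig(dt=0.01, T=1.0))

    def test_path_stays_positive(self, nf01):
        traj = F.simulate_polar_radial(
            nf01, R0=0.05, config=F.SimConfig(dt=0.01, T=300.0, seed=6))
        assert np.all(traj.R > 0)

    def test_spectrum_close_to_radial_ou(self, params):
        _, gaps = F.spectral.radial_psd_comparison(
            params, 0.01, n_paths=8, T=300.0, seed=17)
        assert gaps[1, 2] < 0.1  # radial OU vs polar variant
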