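"""Stratonovich integration, spike detection and first-passage sampling."""

import numpy as np
import pytest
from scipy.linalg import solve_continuous_lyapunov

import fhnlif as F
from fhnlif.sde import (
    AllCensoredError,
    NonFiniteStateError,
    draw_increments,
    integrate_stratonovich,
)


@pytest.fixture(scope="module")
def additive01():
    return F.NoiseSpec("additive", 0.01)


class TestIntegrator:
    def test_deterministic_convergence_to_fixed_point(self, params, eq):
        cfg = F.SimConfig(dt=0.01, T=1000.0, initial_state=(-1.00125, -0.45))
        traj = F.simulate_fhn(params, F.NoiseSpec("additive", 0.0), cfg)
        end = np.array([traj.v[-1], traj.w[-1]])
        assert np.linalg.norm(end - eq.state) < 1e-3

    def test_linear_system_decays_at_rate_mu(self, eq):
        cfg = F.SimConfig(dt=0.01, T=300.0, initial_state=(0.05, 0.01))
        M = eq.M
        traj = integrate_stratonovich(
            lambda X: X @ M.T, lambda X: np.zeros_like(X), cfg)
        norm = np.hypot(traj.v, traj.w)
        # fit log-decay over whole rotations to suppress phase wobble
        slope = np.polyfit(traj.times, np.log(norm), 1)[0]
        assert slope == pytest.approx(-eq.mu, rel=0.05)

    def test_euler_heun_reduces_to_euler_maruyama_for_additive(
            self, params, additive01):
        cfg = F.SimConfig(dt=0.01, T=20.0)
        inc = draw_increments(cfg, 1, np.random.default_rng(0))
        traj = F.simulate_fhn(params, additive01, cfg, increments=inc)
        # hand-rolled Euler-Maruyama on the same increments
        X = np.array(cfg.initial_state)
        for i in range(cfg.n_steps):
            f = F.fhn_model.drift_vector(X, params)
            X = X + f * cfg.dt + np.array([0.0, additive01.sigma0]) * inc[i, 0]
        assert np.allclose([traj.v[-1], traj.w[-1]], X, atol=1e-12)

    def test_common_noise_replay_is_bit_identical(self, params, additive01):
        cfg = F.SimConfig(dt=0.01, T=10.0, seed=123)
        t1 = F.simulate_fhn(params, additive01, cfg)
        t2 = F.simulate_fhn(params, additive01, cfg)
        assert np.array_equal(t1.v, t2.v) and np.array_equal(t1.w, t2.w)
        t3 = F.simulate_fhn(params, additive01, cfg,
                            increments=t1.noise_increments[:, None])
        assert np.array_equal(t1.v, t3.v)

    def test_multiplicative_noise_fixes_zero_recovery(self):
        # with the recovery drift frozen, h(0) = 0 keeps w at zero exactly
        noise = F.NoiseSpec("multiplicative", 0.5)
        cfg = F.SimConfig(dt=0.01, T=10.0, seed=5, initial_state=(0.3, 0.0))
        traj = integrate_stratonovich(
            lambda X: np.zeros_like(X), F.sde.fhn_noise_map(noise), cfg)
        assert np.all(traj.w == 0.0)

    def test_nonfinite_state_aborts_with_step_index(self):
        cfg = F.SimConfig(dt=0.5, T=50.0, initial_state=(1.0, 1.0))
        with pytest.raises(NonFiniteStateError) as err:
            integrate_stratonovich(
                lambda X: X**3, lambda X: np.zeros_like(X), cfg)
        assert err.value.step > 0

    def test_stationary_variance_of_transformed_components(self, params, eq,
                                                           nf01):
        # linear additive system: empirical stationary variance per
        # normal-form component vs the Lyapunov solution (within ~1% of the
        # isotropic OU value sigma^2/(2 mu))
        cfg = F.SimConfig(dt=0.01, T=400.0)
        M = eq.M
        sig = np.array([0.0, 0.01])
        traj = integrate_stratonovich(
            lambda X: X @ M.T, lambda X: np.broadcast_to(sig, X.shape),
            cfg, n_paths=300, rng=np.random.default_rng(11),
            initial_state=(0.0, 0.0))
        Y = np.einsum("ij,tpj->tpi", nf01.Q_inv, traj.states())
        samples = Y[10000:]  # discard 100 time units of burn-in
        emp = samples.reshape(-1, 2).var(axis=0)
        target = nf01.sigma_eff**2 / (2 * nf01.mu)
        assert np.all(np.abs(emp / target - 1.0) < 0.05)
        exact = solve_continuous_lyapunov(
            nf01.A, -np.outer(nf01.h_e, nf01.h_e)).diagonal()
        assert np.all(np.abs(emp / exact - 1.0) < 0.05)


class TestSpikeDetection:
    def test_sinusoid_has_one_spike_per_period(self):
        t = np.linspace(0, 4 * np.pi, 4000)
        rec = F.detect_spikes(np.sin(t), times=t, rearm_level=-0.5)
        assert rec.count == 2
        assert np.allclose(rec.spike_times, [0.0, 2 * np.pi], atol=0.01)

    def test_constant_subthreshold_has_no_spikes(self):
        t = np.linspace(0, 10, 100)
        assert F.detect_spikes(np.full_like(t, -1.0), times=t).count == 0

    def test_threshold_jitter_is_not_double_counted(self):
        t = np.arange(6.0)
        v = np.array([-1.5, 0.5, -0.1, 0.5, -1.5, 0.5])
        rec = F.detect_spikes(v, times=t, rearm_level=-1.0)
        assert rec.count == 2

    def test_isi_are_positive_differences(self):
        t = np.linspace(0, 6 * np.pi, 6000)
        rec = F.detect_spikes(np.sin(t), times=t, rearm_level=-0.5)
        assert np.all(rec.isi > 0)
        assert len(rec.isi) == rec.count - 1


@pytest.fixture(scope="module")
def spike_counts(params):
    """Median spike counts over 10 seeds for the reference amplitudes,
    simulated as one ensemble with a per-path amplitude."""
    sigmas = [0.005, 0.008, 0.01, 0.02]
    n_seeds = 10
    cfg = F.SimConfig(dt=0.01, T=1000.0)
    sig = np.repeat(sigmas, n_seeds)

    def H(X):
        out = np.zeros_like(X)
        out[..., 1] = sig
        return out

    traj = integrate_stratonovich(
        lambda X: F.fhn_model.drift_vector(X, params), H, cfg,
        n_paths=len(sig), rng=np.random.default_rng(100))
    counts = np.array(
        [F.detect_spikes(traj.path(k)).count for k in range(len(sig))]
    ).reshape(len(sigmas), n_seeds)
    return sigmas, counts


class TestSpikingStatistics:

    def test_spike_count_monotone_in_amplitude(self, spike_counts):
        _, counts = spike_counts
        med = np.median(counts, axis=1)
        assert np.all(np.diff(med) >= 0)
        assert med[-1] > med[0]

    def test_rare_spiking_at_small_amplitude(self, spike_counts):
        _, counts = spike_counts
        assert np.median(counts[0]) <= 2  # sigma0 = 0.005: rare, if at all

    def test_mostly_spiking_at_sigma_001(self, spike_counts):
        _, counts = spike_counts
        assert np.mean(counts[2] >= 1) > 0.5  # sigma0 = 0.01


class TestFirstPassageSampling:
    def test_no_noise_is_all_censored(self, params):
        with pytest.raises(AllCensoredError):
            F.sample_isi_fhn(params, F.NoiseSpec("additive", 0.0),
                             F.SimConfig(dt=0.01, T=5.0, seed=1), 10)

    def test_isi_sample_shape_and_skew(self, params):
        fp = F.sample_isi_fhn(params, F.NoiseSpec("additive", 0.02),
                              F.SimConfig(dt=0.01, T=500.0, seed=2), 300)
        assert fp.n_total == 300
        assert np.all(fp.times > 0)
        # unimodal right-skew: mean above median
        assert fp.times.mean() > np.median(fp.times)

    def test_firing_accelerates_with_amplitude(self, params):
        cfg = F.SimConfig(dt=0.01, T=800.0, seed=3)
        slow = F.sample_isi_fhn(params, F.NoiseSpec("additive", 0.008),
                                cfg, 150)
        fast = F.sample_isi_fhn(params, F.NoiseSpec("additive", 0.02),
                                cfg, 150)
        assert fast.times.mean() < slow.times.mean()
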