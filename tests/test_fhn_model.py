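"""Deterministic model analysis: fixed point, eigenstructure, excitability
diagnostics and the analytic constants of the stochastic theory."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fhnlif as F
from fhnlif.fhn_model import (
    NoUniqueFixedPointError,
    NonOscillatoryError,
    dissipativity_constants,
    dissipativity_gap,
    drift_field,
    drift_vector,
    gamma_bound,
    nonlinear_remainder,
)

from conftest import random_excitable_params


class TestDriftField:
    def test_vanishes_at_reference_fixed_point(self, params):
        f, g = drift_field((-1.00125, -0.401665), params)
        assert abs(f) < 1e-4 and abs(g) < 1e-4

    def test_value_at_origin(self, params):
        f, g = drift_field((0.0, 0.0), params)
        assert f == pytest.approx(0.265)
        assert g == pytest.approx(0.056)

    def test_critical_manifold_is_v_nullcline(self, params):
        v = np.linspace(-2.5, 2.5, 31)
        w = F.fhn_model.critical_manifold(v, params)
        f, _ = drift_field((v, w), params)
        assert np.abs(f).max() < 1e-12
        # at v = 0 the manifold sits at w = I
        assert F.fhn_model.critical_manifold(0.0, params) == pytest.approx(
            params.I)


class TestFixedPoint:
    def test_reference_coordinates(self, params):
        eq = F.fixed_point(params)
        assert eq.v_e == pytest.approx(-1.00125, abs=5e-6)
        assert eq.w_e == pytest.approx(-0.401665, abs=5e-7)
        assert eq.discriminant == pytest.approx(1.0420433, abs=1e-7)
        assert abs(eq.v_e**3 + eq.p * eq.v_e + eq.q) < 1e-12

    def test_constructed_parameters_give_exact_root(self):
        # alpha chosen so v = -1 lies on both nullclines
        eq = F.fixed_point(F.ModelParams(I=0.265, alpha=0.69875, beta=0.75))
        assert eq.v_e == pytest.approx(-1.0, abs=1e-12)

    def test_multiple_fixed_points_rejected(self):
        with pytest.raises(NoUniqueFixedPointError):
            F.fixed_point(F.ModelParams(I=0.0, alpha=0.0, beta=4.0))

    def test_drift_vanishes_for_random_excitable_sets(self):
        rng = np.random.default_rng(1)
        for p, eq in random_excitable_params(rng, 100):
            f, g = drift_field((eq.v_e, eq.w_e), p)
            assert abs(f) < 1e-10 and abs(g) < 1e-10


class TestEigenstructure:
    def test_reference_values(self, eq):
        assert eq.mu == pytest.approx(0.0312496, abs=2e-6)
        assert eq.nu == pytest.approx(0.281378, rel=1e-5)
        assert eq.mu_nu_ratio == pytest.approx(0.111059, rel=1e-5)

    def test_jacobian_structure(self, params, eq):
        assert eq.M[0, 1] == -1.0
        assert eq.M[1, 0] == params.epsilon
        assert eq.M[1, 1] == -params.epsilon * params.beta

    def test_closed_form_matches_numeric_eigendecomposition(self):
        rng = np.random.default_rng(2)
        for p, eq_ in random_excitable_params(rng, 50):
            ev = np.linalg.eigvals(eq_.M)
            lam = ev[np.argmax(ev.imag)]
            assert lam.real == pytest.approx(-eq_.mu, abs=1e-10)
            assert lam.imag == pytest.approx(eq_.nu, abs=1e-10)

    def test_hypothetical_unit_v_gives_mu_half_eps_beta(self, params):
        # v_e^2 = 1 collapses mu to eps*beta/2
        M, mu, nu = F.jacobian_and_eigen(params, 1.0)
        assert mu == pytest.approx(params.epsilon * params.beta / 2.0)

    def test_real_eigenvalues_rejected(self):
        # large |v_e| makes the radicand negative
        with pytest.raises(NonOscillatoryError):
            F.jacobian_and_eigen(F.ModelParams(), 2.0)


class TestExcitabilityReport:
    def test_reference_regime_is_excitable(self, params):
        rep = F.excitability_report(params)
        assert rep.excitable
        assert rep.mu_nu_ratio == pytest.approx(0.111059, rel=1e-5)
        assert rep.mu_nu_ratio < 0.2

    def test_multi_equilibrium_regime_flagged(self):
        rep = F.excitability_report(F.ModelParams(I=0.0, alpha=0.0, beta=4.0))
        assert not rep.excitable
        assert not rep.delta_positive

    def test_threshold_is_configurable(self, params):
        assert not F.excitability_report(params, ratio_threshold=0.1).excitable


class TestGammaBound:
    def test_values_and_domain(self, eq):
        assert gamma_bound(0.0, eq.v_e) == 0.0
        assert gamma_bound(0.1, eq.v_e) == pytest.approx(0.1034583, abs=1e-6)
        with pytest.raises(ValueError):
            gamma_bound(-0.1, eq.v_e)

    @given(r=st.floats(min_value=1e-6, max_value=10.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_superadditive_doubling(self, r):
        v_e = -1.00125
        assert gamma_bound(2 * r, v_e) >= 2 * gamma_bound(r, v_e)

    @pytest.mark.parametrize("r", [0.05, 0.1, 0.5])
    def test_bounds_nonlinear_remainder(self, params, eq, r):
        rng = np.random.default_rng(3)
        # random states uniformly in the radius-r ball around the equilibrium
        u = rng.normal(size=(10000, 2))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        rad = r * np.sqrt(rng.random(10000))[:, None]
        X = eq.state + rad * u
        rem = np.linalg.norm(nonlinear_remainder(X, params, eq), axis=-1)
        dev = np.linalg.norm(X - eq.state, axis=-1)
        assert np.all(rem <= gamma_bound(r, eq.v_e) * dev + 1e-12)


class TestDissipativity:
    def test_reference_constants(self, params):
        c = dissipativity_constants(params)
        assert c.b_diss == pytest.approx(0.03)
        assert c.a_diss == pytest.approx(196.020833, abs=1e-5)

    def test_degenerate_eps_one(self):
        with pytest.warns(UserWarning):
            p = F.ModelParams(I=0.0, alpha=0.0, beta=2.0, epsilon=1.0)
        c = dissipativity_constants(p)
        assert (c.a_diss, c.b_diss) == (12.0, 1.0)

    def test_inequality_on_random_pairs(self, params):
        rng = np.random.default_rng(4)
        X1 = rng.uniform(-10, 10, size=(10000, 2))
        X2 = rng.uniform(-10, 10, size=(10000, 2))
        assert np.all(dissipativity_gap(X1, X2, params) <= 1e-9)


class TestParamValidation:
    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            F.ModelParams(beta=0.0)
        with pytest.raises(ValueError):
            F.ModelParams(epsilon=-0.1)
        with pytest.raises(ValueError):
            F.NoiseSpec(kind="pink", sigma0=0.1)
        with pytest.raises(ValueError):
            F.NoiseSpec(sigma0=-1.0)

    def test_no_timescale_separation_warns(self):
        with pytest.warns(UserWarning):
            F.ModelParams(epsilon=1.5)
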