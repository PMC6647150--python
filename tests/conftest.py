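import numpy as np
import pytest

import fhnlif as F


@pytest.fixture(scope="session")
def params():
    return F.REFERENCE_PARAMS


@pytest.fixture(scope="session")
def eq(params):
    return F.analyze_equilibrium(params)


@pytest.fixture(scope="session")
def nf01(eq):
    """Normal-form transform at sigma0 = 0.01."""
    return F.build_normal_form(eq.M, eq.mu, eq.nu, 0.01)


@pytest.fixture(scope="session")
def table1_fits(params):
    """Firing-probability calibrations at the reference amplitudes, at the
    original scale (35 grid points, 1000 trials per point).

    Session-scoped: this is the expensive Monte-Carlo stage shared by the
    calibration-accuracy, trend and ISI-comparison tests.
    """
    _, fits = F.calibrate_firing_table(
        params, [0.003, 0.005, 0.01], n_trials=1000, seed=20240301,
    )
    return fits


def random_excitable_params(rng, n):
    """Draw n parameter sets in the excitable regime (positive cubic
    discriminant and complex stable eigenvalues)."""
    out = []
    while len(out) < n:
        p = F.ModelParams(
            I=rng.uniform(0.0, 0.6),
            alpha=rng.uniform(0.3, 1.0),
            beta=rng.uniform(0.4, 0.95),
            epsilon=rng.uniform(0.02, 0.2),
        )
        try:
            eq_ = F.analyze_equilibrium(p)
        except (F.fhn_model.NoUniqueFixedPointError,
                F.fhn_model.NonOscillatoryError):
            continue
        if eq_.mu > 0:
            out.append((p, eq_))
    return out
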