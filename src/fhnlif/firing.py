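"""Monte-Carlo firing mechanism: conditional firing probability on the
line below the equilibrium, sigmoid regression, and the conversion to
normal-form coordinates.

A trial starts the full stochastic model at a point ``L_i = (v_e, w_e -
l_i)`` on the vertical line through the equilibrium and asks whether the
membrane variable crosses ``v = 0`` during the *first cycle* of the path
around the fixed point.  The cycle is clocked by the unwrapped angle of
the normal-form coordinates ``Y = Q^{-1}(X - X_e)`` reaching ``2*pi`` in
magnitude (the transformed dynamics rotates nearly uniformly at rate
``nu``), with a hard time cap of ``3 * (2*pi/nu)`` for paths stalled
near the origin; capped trials count as non-spikes and their frequency
is reported.  The estimated probabilities follow a logistic law ``p(l) =
1/(1 + exp((a - l)/b))`` whose location ``a`` tracks the distance from
the rest point to the separatrix along the line and whose width ``b``
grows with the noise amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

from .fhn_model import (
    EquilibriumAnalysis,
    ModelParams,
    NoiseSpec,
    analyze_equilibrium,
    drift_vector,
)
from .normal_form import NormalFormTransform, build_normal_form
from .sde import fhn_noise_map, heun_step

__all__ = [
    "FiringGrid",
    "FiringProbabilityFit",
    "SigmoidFitError",
    "build_firing_grid",
    "estimate_firing_probability",
    "estimate_grid_probabilities",
    "fit_sigmoid",
    "transform_fit",
    "calibrate_firing",
    "calibrate_firing_table",
]

#: w-coordinate of the separatrix reference point used to size the grid;
#: specific to the reference parameter set.
SEPARATRIX_W = -0.453

N_GRID = 35


class SigmoidFitError(RuntimeError):
    """The logistic regression failed to converge; carries diagnostics."""


@dataclass(frozen=True)
class FiringGrid:
    """35 starting points ``L_i = (v_e, w_e - i*delta)``, ``i = 0..34``,
    with spacing ``delta = |w_e - w_sep| / 20`` so the separatrix sits at
    ``i = 20``."""

    delta: float
    l_values: np.ndarray
    points: np.ndarray  # (35, 2)
    separatrix_distance: float


@dataclass
class FiringProbabilityFit:
    """Result of one calibration at a fixed noise amplitude."""

    sigma0: float
    l_values: np.ndarray
    p_hat: np.ndarray
    n_trials: int
    a: float
    b: float
    a_star: float | None = None
    b_star: float | None = None
    rss: float = np.nan
    converged: bool = False
    stalled_fraction: float = 0.0


def build_firing_grid(eq: EquilibriumAnalysis,
                      separatrix_w: float = SEPARATRIX_W) -> FiringGrid:
    """Grid of starting points on the line ``L = {(v_e, w): w <= w_e}``."""
    dist = abs(eq.w_e - separatrix_w)
    delta = dist / 20.0
    l_values = delta * np.arange(N_GRID)
    points = np.column_stack(
        [np.full(N_GRID, eq.v_e), eq.w_e - l_values]
    )
    return FiringGrid(delta=delta, l_values=l_values, points=points,
                      separatrix_distance=dist)


def _first_cycle_spike_counts(
    params: ModelParams,
    noise: NoiseSpec,
    starts: np.ndarray,
    n_trials: int,
    rng: np.random.Generator,
    transform: NormalFormTransform,
    eq: EquilibriumAnalysis,
    dt: float = 0.01,
    threshold: float = 0.0,
    cycle_cap_factor: float = 3.0,
):
    """Vectorized first-cycle simulation for a batch of starting points.

    Returns ``(spike_counts, stalled_counts)`` per starting point.  A
    trial ends when it spikes (upward crossing of ``v = threshold``),
    completes one cycle (unwrapped normal-form angle reaches 2*pi in
    magnitude), or hits the time cap (counted as stalled non-spike).
    """
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    P = starts.shape[0]
    n = P * n_trials
    X = np.repeat(starts, n_trials, axis=0)
    Xe = eq.state
    Qinv = transform.Q_inv
    drift = lambda Z: drift_vector(Z, params)
    H = fhn_noise_map(noise)
    Y = (X - Xe) @ Qinv.T
    ang = np.arctan2(Y[:, 1], Y[:, 0])
    cum = np.zeros(n)
    fired = np.zeros(n, dtype=bool)
    stalled = np.zeros(n, dtype=bool)
    alive = np.arange(n)
    cap_steps = int(np.ceil(cycle_cap_factor * (2.0 * np.pi / transform.nu) / dt))
    sqdt = np.sqrt(dt)
    for i in range(cap_steps):
        dW = rng.normal(0.0, sqdt, alive.size)
        v_prev = X[:, 0].copy()
        X = heun_step(X, dt, dW, drift, H)
        crossed = (v_prev <= threshold) & (X[:, 0] > threshold)
        Y = (X - Xe) @ Qinv.T
        new_ang = np.arctan2(Y[:, 1], Y[:, 0])
        d = new_ang - ang
        d = (d + np.pi) % (2.0 * np.pi) - np.pi
        cum = cum + d
        ang = new_ang
        done_cycle = np.abs(cum) >= 2.0 * np.pi
        if crossed.any():
            fired[alive[crossed]] = True
        done = crossed | done_cycle
        if done.any():
            keep = ~done
            X, Y, ang, cum, alive = X[keep], Y[keep], ang[keep], cum[keep], alive[keep]
            if alive.size == 0:
                break
    if alive.size:
        stalled[alive] = True
    fired = fired.reshape(P, n_trials)
    stalled = stalled.reshape(P, n_trials)
    return fired.sum(axis=1), stalled.sum(axis=1)


def estimate_firing_probability(
    params: ModelParams,
    noise: NoiseSpec,
    point,
    n_trials: int = 1000,
    rng: np.random.Generator | None = None,
    dt: float = 0.01,
    transform: NormalFormTransform | None = None,
    seed: int | None = None,
):
    """Monte-Carlo estimate of the conditional firing probability from a
    single starting point.  Returns ``(p_hat, n_spikes)``."""
    if n_trials < 1:
        raise ValueError("n_trials >= 1 required")
    eq = analyze_equilibrium(params)
    if transform is None:
        transform = build_normal_form(eq.M, eq.mu, eq.nu, noise.sigma0)
    if rng is None:
        rng = np.random.default_rng(seed)
    counts, _ = _first_cycle_spike_counts(
        params, noise, np.asarray(point, dtype=float)[None, :], n_trials,
        rng, transform, eq, dt=dt,
    )
    return counts[0] / n_trials, int(counts[0])


def estimate_grid_probabilities(
    params: ModelParams,
    noise: NoiseSpec,
    grid: FiringGrid,
    n_trials: int = 1000,
    rng: np.random.Generator | None = None,
    dt: float = 0.01,
    seed: int | None = None,
):
    """Estimated firing probabilities at every grid point (one vectorized
    sweep over all ``35 * n_trials`` trials).  Returns
    ``(p_hat, stalled_fraction)``."""
    eq = analyze_equilibrium(params)
    transform = build_normal_form(eq.M, eq.mu, eq.nu, noise.sigma0)
    if rng is None:
        rng = np.random.default_rng(seed)
    counts, stalls = _first_cycle_spike_counts(
        params, noise, grid.points, n_trials, rng, transform, eq, dt=dt,
    )
    return counts / n_trials, float(stalls.sum()) / (len(grid.points) * n_trials)


def _logistic(l, a, b):
    return expit((l - a) / b)


def fit_sigmoid(l_values, p_hat_values, sigma0: float | None = None,
                weights=None):
    """Least-squares logistic fit ``p(l) = 1/(1 + exp((a - l)/b))``.

    Initial values: ``a0`` is the first grid distance at which the
    estimate exceeds 1/2 (the location where firing becomes more likely
    than not), ``b0 = 5*sigma0`` when the amplitude is known.  The fit is
    unweighted by default; pass binomial ``weights`` (standard
    deviations) to weight it.  Returns ``(a, b, rss)``.
    """
    l = np.asarray(l_values, dtype=float)
    p = np.asarray(p_hat_values, dtype=float)
    if l.size < 4 or np.ptp(l) == 0:
        raise ValueError("need >= 4 grid points with nondegenerate spread")
    above = np.flatnonzero(p > 0.5)
    a0 = l[above[0]] if above.size else float(np.median(l))
    b0 = 5.0 * sigma0 if sigma0 else max(np.ptp(l) / 10.0, 1e-6)
    try:
        popt, _ = curve_fit(
            _logistic, l, p, p0=(a0, b0),
            sigma=weights, bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise SigmoidFitError(f"logistic regression failed: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    rss = float(np.sum((_logistic(l, a, b) - p) ** 2))
    return a, b, rss


def transform_fit(fit: FiringProbabilityFit,
                  transform: NormalFormTransform):
    """Convert the sigmoid parameters to normal-form radii:
    ``a* = transform_factor * a``, ``b* = transform_factor * b``.
    The ratio ``a/b`` (hence the logistic shape) is unchanged.
    Fills the fit in place and returns ``(a_star, b_star)``."""
    fit.a_star = transform.transform_factor * fit.a
    fit.b_star = transform.transform_factor * fit.b
    return fit.a_star, fit.b_star


def calibrate_firing(
    params: ModelParams,
    noise: NoiseSpec,
    n_trials: int = 1000,
    rng: np.random.Generator | None = None,
    dt: float = 0.01,
    seed: int | None = None,
    separatrix_w: float = SEPARATRIX_W,
) -> FiringProbabilityFit:
    """Full calibration at one noise amplitude: grid, Monte-Carlo
    probabilities, sigmoid fit and normal-form conversion."""
    eq = analyze_equilibrium(params)
    transform = build_normal_form(eq.M, eq.mu, eq.nu, noise.sigma0)
    grid = build_firing_grid(eq, separatrix_w=separatrix_w)
    if rng is None:
        rng = np.random.default_rng(seed)
    p_hat, stalled = estimate_grid_probabilities(
        params, noise, grid, n_trials=n_trials, rng=rng, dt=dt,
    )
    a, b, rss = fit_sigmoid(grid.l_values, p_hat, sigma0=noise.sigma0)
    fit = FiringProbabilityFit(
        sigma0=noise.sigma0, l_values=grid.l_values, p_hat=p_hat,
        n_trials=n_trials, a=a, b=b, rss=rss, converged=True,
        stalled_fraction=stalled,
    )
    transform_fit(fit, transform)
    return fit


def calibrate_firing_table(
    params: ModelParams,
    sigma0_list,
    n_trials: int = 1000,
    rng: np.random.Generator | None = None,
    dt: float = 0.01,
    seed: int | None = None,
    kind: str = "additive",
) -> tuple[pd.DataFrame, dict[float, FiringProbabilityFit]]:
    """Calibrate over a list of amplitudes; returns a table with columns
    ``sigma0, a, b, a_star, b_star`` plus the per-amplitude fits."""
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    fits: dict[float, FiringProbabilityFit] = {}
    for s0 in sigma0_list:
        fit = calibrate_firing(params, NoiseSpec(kind=kind, sigma0=s0),
                               n_trials=n_trials, rng=rng, dt=dt)
        fits[s0] = fit
        rows.append({"sigma0": s0, "a": fit.a, "b": fit.b,
                     "a_star": fit.a_star, "b_star": fit.b_star})
    return pd.DataFrame(rows), fits
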