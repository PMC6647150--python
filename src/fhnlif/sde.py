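"""Stratonovich SDE integration, spike detection and ISI sampling.

The workhorse is a vectorized Euler-Heun predictor-corrector scheme for
systems driven by a single scalar Brownian motion,

    dX_t = F(X_t) dt + H(X_t) o dB_t,

where the Heun midpoint of the diffusion makes the path consistent with
the Stratonovich interpretation; for additive noise the scheme coincides
exactly with Euler-Maruyama.  All drivers accept a pre-drawn increment
array so that different systems can be integrated on the *same* Brownian
path (common-noise coupling, needed by the pathwise linearization error
bounds), and they record the increments they used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fhn_model import ModelParams, NoiseSpec, drift_vector, fixed_point

__all__ = [
    "SimConfig",
    "Trajectory",
    "SpikeRecord",
    "FirstPassageResult",
    "NonFiniteStateError",
    "AllCensoredError",
    "integrate_stratonovich",
    "simulate_fhn",
    "detect_spikes",
    "sample_isi_fhn",
    "fhn_noise_map",
    "heun_step",
]


class NonFiniteStateError(RuntimeError):
    """Integration produced a non-finite state; carries the step index."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite state first reached at step {step}")


class AllCensoredError(RuntimeError):
    """No run fired before the horizon at this noise amplitude."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    dt : step size (time units), default 0.01.
    T : horizon (time units).
    seed : root RNG seed (``None`` draws from OS entropy).
    initial_state : default start ``(v0, w0)``; the reference phase-portrait
        start ``(-1.00125, -0.4)`` sits just above the fixed point.
    scheme : ``euler_heun`` (Heun midpoint on the diffusion only, the
        default) or ``stochastic_rk`` (Heun on drift and diffusion).
    """

    dt: float = 0.01
    T: float = 1000.0
    seed: int | None = None
    initial_state: tuple[float, float] = (-1.00125, -0.4)
    scheme: str = "euler_heun"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.T <= 0 or self.dt > self.T:
            raise ValueError("need 0 < dt <= T")
        if self.scheme not in ("euler_heun", "stochastic_rk"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))


@dataclass
class Trajectory:
    """Sample path(s) on a uniform grid.

    ``v`` and ``w`` have shape ``(n_steps + 1,)`` for a single path or
    ``(n_steps + 1, n_paths)`` for an ensemble; ``noise_increments`` holds
    the Brownian increments actually consumed (one fewer row), retained so
    a second system can be integrated on the same noise.
    """

    times: np.ndarray
    v: np.ndarray
    w: np.ndarray
    noise_increments: np.ndarray | None = None

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_paths(self) -> int:
        return 1 if self.v.ndim == 1 else self.v.shape[1]

    def states(self) -> np.ndarray:
        """Stacked states, shape ``(n_steps + 1, [n_paths,] 2)``."""
        return np.stack([self.v, self.w], axis=-1)

    def path(self, i: int) -> "Trajectory":
        """Extract a single path from an ensemble."""
        if self.v.ndim == 1:
            return self
        inc = None if self.noise_increments is None else self.noise_increments[:, i]
        return Trajectory(self.times, self.v[:, i], self.w[:, i], inc)


@dataclass
class SpikeRecord:
    """Ordered spike (threshold-crossing) times and the interspike intervals."""

    spike_times: np.ndarray

    @property
    def isi(self) -> np.ndarray:
        return np.diff(self.spike_times)

    @property
    def count(self) -> int:
        return len(self.spike_times)


@dataclass
class FirstPassageResult:
    """First-firing times from repeated reset trials; censored runs (no
    spike before the horizon) are counted, not silently discarded."""

    times: np.ndarray
    n_censored: int
    horizon: float

    @property
    def n_total(self) -> int:
        return len(self.times) + self.n_censored


def heun_step(X, dt, dW, drift, diffusion, scheme="euler_heun"):
    """One predictor-corrector step on stacked states ``(n, d)``.

    ``drift``/``diffusion`` map ``(n, d)`` states to ``(n, d)`` fields;
    ``dW`` is the scalar Brownian increment per path, shape ``(n,)``.
    """
    f0 = drift(X)
    H0 = diffusion(X)
    dWc = dW[..., None]
    if scheme == "euler_heun":
        Xp = X + H0 * dWc
        return X + f0 * dt + 0.5 * (H0 + diffusion(Xp)) * dWc
    # stochastic_rk: Heun average on drift and diffusion
    Xp = X + f0 * dt + H0 * dWc
    return X + 0.5 * (f0 + drift(Xp)) * dt + 0.5 * (H0 + diffusion(Xp)) * dWc


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def draw_increments(config: SimConfig, n_paths: int = 1,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Brownian increments of shape ``(n_steps, n_paths)`` for ``config``."""
    rng = _as_rng(config.seed if rng is None else rng)
    return rng.normal(0.0, np.sqrt(config.dt), size=(config.n_steps, n_paths))


def integrate_stratonovich(
    drift,
    diffusion,
    config: SimConfig,
    n_paths: int = 1,
    increments: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    initial_state=None,
) -> Trajectory:
    """Integrate ``dX = F(X) dt + H(X) o dB`` and keep the full path.

    ``increments`` (shape ``(n_steps, n_paths)``) replays a given Brownian
    path; otherwise increments are drawn from ``rng`` (or ``config.seed``)
    and stored on the returned :class:`Trajectory`.  Identical seeds and
    increments produce bit-identical paths.

    Raises :class:`NonFiniteStateError` at the first non-finite step.
    """
    n_steps = config.n_steps
    if increments is None:
        increments = draw_increments(config, n_paths, rng)
    else:
        increments = np.asarray(increments, dtype=float)
        if increments.ndim == 1:
            increments = increments[:, None]
        if increments.shape != (n_steps, n_paths):
            raise ValueError(
                f"increments shape {increments.shape} != {(n_steps, n_paths)}"
            )
    x0 = config.initial_state if initial_state is None else initial_state
    X = np.tile(np.asarray(x0, dtype=float), (n_paths, 1))
    out = np.empty((n_steps + 1, n_paths, 2))
    out[0] = X
    dt = config.dt
    for i in range(n_steps):
        X = heun_step(X, dt, increments[i], drift, diffusion, config.scheme)
        if not np.all(np.isfinite(X)):
            raise NonFiniteStateError(i + 1)
        out[i + 1] = X
    times = np.arange(n_steps + 1) * dt
    if n_paths == 1:
        return Trajectory(times, out[:, 0, 0], out[:, 0, 1], increments[:, 0])
    return Trajectory(times, out[..., 0], out[..., 1], increments)


def fhn_noise_map(noise: NoiseSpec):
    """Diffusion field ``H(X)`` of the stochastic model: ``(0, sigma0)`` for
    additive channel noise, ``(0, sigma0 * w)`` for multiplicative."""
    if noise.kind == "additive":
        def H(X):
            out = np.zeros_like(X)
            out[..., 1] = noise.sigma0
            return out
    else:
        def H(X):
            out = np.zeros_like(X)
            out[..., 1] = noise.sigma0 * X[..., 1]
            return out
    return H


def simulate_fhn(
    params: ModelParams,
    noise: NoiseSpec,
    config: SimConfig,
    n_paths: int = 1,
    increments: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    initial_state=None,
) -> Trajectory:
    """Simulate the stochastic FitzHugh-Nagumo system (noise on the
    recovery equation only)."""
    drift = lambda X: drift_vector(X, params)
    return integrate_stratonovich(
        drift, fhn_noise_map(noise), config, n_paths=n_paths,
        increments=increments, rng=rng, initial_state=initial_state,
    )


def detect_spikes(
    traj: Trajectory | np.ndarray,
    threshold: float = 0.0,
    rearm_level: float = -1.0,
    times: np.ndarray | None = None,
) -> SpikeRecord:
    """Upward crossings of ``v = threshold`` with refractory re-arming.

    A crossing is counted only if ``v`` has dipped below ``rearm_level``
    (by default near the resting potential) since the previous spike, so a
    single excursion jittering around the threshold yields one spike.
    Crossing times are linearly interpolated between bracketing samples.
    """
    if isinstance(traj, Trajectory):
        v = traj.v
        t = traj.times
    else:
        v = np.asarray(traj, dtype=float)
        if times is None:
            raise ValueError("times required when passing a bare array")
        t = np.asarray(times, dtype=float)
    if v.ndim != 1:
        raise ValueError("detect_spikes expects a single path")
    up = np.flatnonzero((v[:-1] <= threshold) & (v[1:] > threshold))
    spike_times = []
    armed_from = 0
    for i in up:
        if spike_times and not np.any(v[armed_from : i + 1] < rearm_level):
            continue
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        spike_times.append(t[i] + frac * (t[i + 1] - t[i]))
        armed_from = i + 1
    return SpikeRecord(np.asarray(spike_times))


def sample_isi_fhn(
    params: ModelParams,
    noise: NoiseSpec,
    config: SimConfig,
    n_samples: int,
    rng: np.random.Generator | None = None,
    threshold: float = 0.0,
    start=None,
) -> FirstPassageResult:
    """First-firing times of the full model under the reset rule.

    Each of ``n_samples`` trials starts a fresh path at the fixed point
    (or ``start``) and records the first upward crossing of
    ``v = threshold``; runs with no spike before ``config.T`` are
    censored.  Trials are integrated in a single vectorized sweep with an
    active-set that shrinks as trials fire.

    Raises :class:`AllCensoredError` if no trial fires at all.
    """
    if n_samples < 1:
        raise ValueError("n_samples >= 1 required")
    rng = _as_rng(config.seed if rng is None else rng)
    if start is None:
        eq = fixed_point(params)
        start = (eq.v_e, eq.w_e)
    drift = lambda X: drift_vector(X, params)
    H = fhn_noise_map(noise)
    dt = config.dt
    n_steps = config.n_steps
    X = np.tile(np.asarray(start, dtype=float), (n_samples, 1))
    alive = np.arange(n_samples)
    out = np.full(n_samples, np.nan)
    for i in range(n_steps):
        dW = rng.normal(0.0, np.sqrt(dt), alive.size)
        v_prev = X[:, 0].copy()
        X = heun_step(X, dt, dW, drift, H, config.scheme)
        crossed = (v_prev <= threshold) & (X[:, 0] > threshold)
        if crossed.any():
            frac = (threshold - v_prev[crossed]) / (X[crossed, 0] - v_prev[crossed])
            out[alive[crossed]] = i * dt + frac * dt
            keep = ~crossed
            X = X[keep]
            alive = alive[keep]
            if alive.size == 0:
                break
    fired = out[~np.isnan(out)]
    if fired.size == 0:
        raise AllCensoredError(
            "no firing at this amplitude/horizon "
            f"(sigma0={noise.sigma0}, T={config.T})"
        )
    return FirstPassageResult(times=fired, n_censored=int(np.isnan(out).sum()),
                              horizon=config.T)
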