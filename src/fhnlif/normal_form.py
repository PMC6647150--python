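"""Rotation normal form and the radial Ornstein-Uhlenbeck reduction.

Around the stable focus the linearized dynamics is ``dXb = M Xb dt +
(0, sigma0) dB``.  The change of basis ``Yb = Q^{-1} Xb`` with
``Q = [[-nu, m11 + mu], [0, m21]]`` turns the drift into the
rotation-contraction matrix ``A = [[-mu, nu], [-nu, -mu]]`` (the
similarity ``Q^{-1} M Q = A`` is exact and verified on construction).
Because ``mu << nu``, time-averaging over the fast rotation approximates
``Yb`` by a slowly contracting 2-D Ornstein-Uhlenbeck process seen
through a rotating frame; its Euclidean norm ``R_t`` obeys the radial OU
SDE ``dR = [sigma^2/(2R) - mu R] dt + sigma dBtilde``, the membrane
variable of the embedded leaky integrate-and-fire model.  A second,
polar-coordinate route keeps the time-dependent projection of the
transformed noise vector ``h_e = Q^{-1}(0, sigma0)`` onto the rotating
unit vector.

All printed constants of the reference parameter set (the sine/cosine
noise coefficients, their squared norm, the effective amplitude) are
*computed* from ``M`` here, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fhn_model import ModelParams, analyze_equilibrium
from .sde import SimConfig

__all__ = [
    "NormalFormTransform",
    "RadialTrajectory",
    "build_normal_form",
    "normal_form_from_params",
    "rotation",
    "averaged_ou_path",
    "ou_exact_step",
    "simulate_radial_ou",
    "simulate_polar_radial",
]


@dataclass(frozen=True)
class NormalFormTransform:
    """Change of basis to the rotation normal form, and the noise data.

    Attributes
    ----------
    Q, Q_inv : the change-of-basis matrix and its inverse.
    A : rotation-contraction drift ``[[-mu, nu], [-nu, -mu]]``.
    C : transformed diffusion matrix ``Q^{-1} diag(0, sigma0)``.
    h_e : transformed noise vector ``Q^{-1} (0, sigma0)``; its components
        are the sine/cosine coefficients of the polar radial SDE.
    sigma_eff : effective scalar amplitude ``sqrt(tr(C C^T)/2)``.
    transform_factor : ``sqrt(-m12/(m21 nu^2)) = ||h_e||/sigma0``, the
        conversion between distances on the firing line and radii in
        normal-form coordinates.
    """

    Q: np.ndarray
    Q_inv: np.ndarray
    A: np.ndarray
    C: np.ndarray
    h_e: np.ndarray
    sigma0: float
    sigma_eff: float
    transform_factor: float
    mu: float
    nu: float


@dataclass
class RadialTrajectory:
    """Radial path ``R_t >= 0`` on a uniform grid, with the (unwrapped)
    angle where the polar construction provides one."""

    times: np.ndarray
    R: np.ndarray
    theta: np.ndarray | None = None


def build_normal_form(M: np.ndarray, mu: float, nu: float,
                      sigma0: float) -> NormalFormTransform:
    """Build the normal-form transform from the Jacobian and eigen data.

    Raises ``ValueError`` if ``m21 = 0`` (transform undefined) and
    ``AssertionError`` if the exact similarity ``Q^{-1} M Q = A`` fails
    beyond 1e-10 (it holds to machine precision for genuine complex pairs).
    """
    M = np.asarray(M, dtype=float)
    m11, m12 = M[0, 0], M[0, 1]
    m21 = M[1, 0]
    if m21 == 0:
        raise ValueError("m21 = 0: normal-form transform undefined")
    Q = np.array([[-nu, m11 + mu], [0.0, m21]])
    Q_inv = np.linalg.inv(Q)
    A = np.array([[-mu, nu], [-nu, -mu]])
    sim_err = np.abs(Q_inv @ M @ Q - A).max()
    if sim_err > 1e-10:
        raise AssertionError(f"similarity Q^-1 M Q = A fails by {sim_err:.2e}")
    C = Q_inv @ np.diag([0.0, sigma0])
    h_e = Q_inv @ np.array([0.0, sigma0])
    sigma_eff = float(np.sqrt(0.5 * np.trace(C @ C.T)))
    tf = float(np.sqrt(-m12 / (m21 * nu**2)))
    return NormalFormTransform(
        Q=Q, Q_inv=Q_inv, A=A, C=C, h_e=h_e, sigma0=sigma0,
        sigma_eff=sigma_eff, transform_factor=tf, mu=mu, nu=nu,
    )


def normal_form_from_params(params: ModelParams, sigma0: float) -> NormalFormTransform:
    """Convenience: equilibrium analysis + :func:`build_normal_form`."""
    eq = analyze_equilibrium(params)
    return build_normal_form(eq.M, eq.mu, eq.nu, sigma0)


def rotation(s):
    """Rotation matrix ``Rot_s = [[cos s, -sin s], [sin s, cos s]]``;
    vectorized over ``s`` (returns shape ``(..., 2, 2)``)."""
    s = np.asarray(s, dtype=float)
    c, sn = np.cos(s), np.sin(s)
    out = np.empty(s.shape + (2, 2))
    out[..., 0, 0] = c
    out[..., 0, 1] = -sn
    out[..., 1, 0] = sn
    out[..., 1, 1] = c
    return out


def ou_exact_step(S: np.ndarray, delta: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Exact Gaussian transition of the standard OU ``dS = -S dt + dB``
    over a (scaled) time increment ``delta``."""
    if delta == 0:
        return S
    decay = np.exp(-delta)
    sd = np.sqrt((1.0 - np.exp(-2.0 * delta)) / 2.0)
    return S * decay + sd * rng.standard_normal(S.shape)


def averaged_ou_path(
    transform: NormalFormTransform,
    y0,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_paths: int = 1,
):
    """Averaged approximation ``Yb_app(t) = (sigma/sqrt(mu)) Rot_{-nu t}
    Sb_{mu t}`` of the normal-form process.

    The standard 2-D OU ``Sb`` is advanced with its exact Gaussian
    transition at scaled steps ``mu * dt`` from ``Sb_0 =
    (sqrt(mu)/sigma) Yb_0``; with ``sigma0 = 0`` the path decays exactly
    like ``e^{-mu t}``.

    Returns ``(times, Y)`` with ``Y`` of shape ``(n_steps + 1, 2)`` or
    ``(n_steps + 1, n_paths, 2)``.
    """
    mu, nu, sigma = transform.mu, transform.nu, transform.sigma_eff
    if mu <= 0:
        raise ValueError("mu > 0 required")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_steps
    times = np.arange(n + 1) * config.dt
    y0 = np.asarray(y0, dtype=float)
    scale = sigma / np.sqrt(mu) if sigma > 0 else 1.0
    S = np.tile(y0 / scale, (n_paths, 1))
    paths = np.empty((n + 1, n_paths, 2))
    paths[0] = S
    h = mu * config.dt
    if sigma > 0:
        for i in range(n):
            S = ou_exact_step(S, h, rng)
            paths[i + 1] = S
    else:
        decay = np.exp(-h * np.arange(n + 1))
        paths = S[None, :, :] * decay[:, None, None]
    rot = rotation(-nu * times)  # (n+1, 2, 2)
    Y = scale * np.einsum("tij,tpj->tpi", rot, paths)
    if n_paths == 1:
        return times, Y[:, 0, :]
    return times, Y


def simulate_radial_ou(
    transform: NormalFormTransform,
    R0: float,
    config: SimConfig,
    backend: str = "norm",
    rng: np.random.Generator | None = None,
    n_paths: int = 1,
) -> RadialTrajectory:
    """Radial OU path ``dR = [sigma^2/(2R) - mu R] dt + sigma dBtilde``.

    Backends:

    * ``"norm"`` (default, reference): ``R_t = (sigma/sqrt(mu))
      ||Sb_{mu t}||`` with exact OU transitions — the construction the
      radial SDE is derived from, free of the ``1/R`` singularity and
      valid from ``R0 = 0``.
    * ``"euler"``: direct Euler-Maruyama on the 1-D SDE with a
      positivity guard — a step driving ``R`` to ``<= 0`` is rejected and
      retried on two conditioned half-steps (Brownian-bridge split), up
      to 20 halvings.
    """
    mu, sigma = transform.mu, transform.sigma_eff
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_steps
    times = np.arange(n + 1) * config.dt
    if backend == "norm":
        if sigma == 0:
            # noiseless limit: pure exponential contraction at rate mu
            R = R0 * np.exp(-mu * times)
            R = R if n_paths == 1 else np.tile(R[:, None], (1, n_paths))
            return RadialTrajectory(times, R)
        scale = sigma / np.sqrt(mu)
        S = np.zeros((n_paths, 2))
        S[:, 0] = R0 / scale
        R = np.empty((n + 1, n_paths))
        R[0] = scale * np.hypot(S[:, 0], S[:, 1])
        h = mu * config.dt
        for i in range(n):
            S = ou_exact_step(S, h, rng)
            R[i + 1] = scale * np.hypot(S[:, 0], S[:, 1])
        return RadialTrajectory(times, R[:, 0] if n_paths == 1 else R)
    if backend != "euler":
        raise ValueError(f"unknown backend {backend!r}")
    if R0 <= 0:
        raise ValueError("direct Euler backend requires R0 > 0")
    drift = lambda R, t: (sigma**2 / (2.0 * R) - mu * R)
    diff = lambda t: sigma
    R = np.empty((n + 1, n_paths))
    R[0] = R0
    dt = config.dt
    state = np.full(n_paths, float(R0))
    for i in range(n):
        dW = rng.normal(0.0, np.sqrt(dt), n_paths)
        state = _guarded_em_step(state, times[i], dt, dW, drift, diff, rng)
        R[i + 1] = state
    return RadialTrajectory(times, R[:, 0] if n_paths == 1 else R)


def _guarded_em_step(R, t, dt, dW, drift, diff, rng, depth=0):
    """Euler-Maruyama step on a scalar SDE (vectorized over paths) with a
    positivity guard: a step driving a path non-positive is rejected and
    redone as two half-steps with fresh increments (the exploding
    restoring drift near the origin then resolves it), recursively up to
    20 halvings."""
    R = np.asarray(R, dtype=float)
    dW = np.asarray(dW, dtype=float)
    Rn = R + drift(R, t) * dt + diff(t) * dW
    bad = Rn <= 0
    if np.any(bad):
        if depth >= 20:
            raise RuntimeError(
                "radial path hit the origin; step-halving exhausted")
        nb = int(bad.sum()) if bad.shape else 1
        dW1 = rng.normal(0.0, np.sqrt(dt / 2.0), nb)
        dW2 = rng.normal(0.0, np.sqrt(dt / 2.0), nb)
        Rh = _guarded_em_step(R[bad], t, dt / 2.0, dW1, drift, diff, rng,
                              depth + 1)
        Rn[bad] = _guarded_em_step(Rh, t + dt / 2.0, dt / 2.0, dW2,
                                   drift, diff, rng, depth + 1)
    return Rn


def simulate_polar_radial(
    transform: NormalFormTransform,
    R0: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> RadialTrajectory:
    """Polar-coordinate radial SDE with the rotating noise projection.

    With ``theta_t = (sin(nu t), cos(nu t))`` and ``h_e`` from the
    transform (never the printed constants), integrates

        dRb = [ (||h_e||^2 - <h_e, theta_t>^2) / (2 Rb) - mu Rb ] dt
              + <theta_t, h_e> dB_t

    by guarded Euler-Maruyama.  The time-average of the squared diffusion
    coefficient over one rotation period is ``||h_e||^2 / 2 =
    sigma_eff^2``.
    """
    if R0 <= 0:
        raise ValueError("polar radial SDE requires R0 > 0")
    mu, nu = transform.mu, transform.nu
    h = transform.h_e
    hsq = float(h @ h)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_steps
    times = np.arange(n + 1) * config.dt
    dot = h[0] * np.sin(nu * times) + h[1] * np.cos(nu * times)

    def drift(R, t):
        d = h[0] * np.sin(nu * t) + h[1] * np.cos(nu * t)
        return (hsq - d * d) / (2.0 * R) - mu * R

    diff = lambda t: h[0] * np.sin(nu * t) + h[1] * np.cos(nu * t)
    R = np.empty(n + 1)
    R[0] = R0
    dt = config.dt
    state = np.array([float(R0)])
    for i in range(n):
        dW = rng.normal(0.0, np.sqrt(dt), 1)
        state = _guarded_em_step(state, times[i], dt, dW, drift, diff, rng)
        R[i + 1] = state[0]
    theta = np.unwrap(np.arctan2(np.sin(nu * times), np.cos(nu * times)))
    return RadialTrajectory(times, R, theta=theta)
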