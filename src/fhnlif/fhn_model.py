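"""Deterministic FitzHugh-Nagumo model in the excitable regime.

The model is the planar slow-fast system

    dv/dt = v - v^3/3 - w + I
    dw/dt = eps * (v + alpha - beta * w)

where ``v`` is the (fast) membrane potential, ``w`` the (slow) recovery
current, ``I`` a constant bias current and ``eps`` the time-scale
separation.  The excitable regime is the parameter region with a unique,
stable fixed point (positive cubic discriminant, complex eigenvalue pair
``-mu +/- i nu`` with ``mu > 0``) whose basin covers the phase plane:
perturbations trigger at most one spike before the trajectory returns to
rest.  This module provides the closed-form equilibrium (Cardano root),
the Jacobian eigenstructure, excitability diagnostics, and the analytic
constants (dissipativity, nonlinear-remainder bound) used by the
stochastic reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "NoiseSpec",
    "EquilibriumAnalysis",
    "ExcitabilityReport",
    "DissipativityConstants",
    "NoUniqueFixedPointError",
    "NonOscillatoryError",
    "REFERENCE_PARAMS",
    "drift_field",
    "drift_vector",
    "critical_manifold",
    "fixed_point",
    "jacobian_and_eigen",
    "analyze_equilibrium",
    "excitability_report",
    "gamma_bound",
    "nonlinear_remainder",
    "dissipativity_constants",
    "dissipativity_gap",
]


class NoUniqueFixedPointError(ValueError):
    """Raised when the cubic discriminant is not positive: the nullclines
    intersect in more than one point and the excitable-regime analysis is
    unavailable."""


class NonOscillatoryError(ValueError):
    """Raised when the Jacobian eigenvalues are real: the equilibrium is
    not a focus and the averaging reduction is invalid."""


@dataclass(frozen=True)
class ModelParams:
    """FitzHugh-Nagumo parameter set.

    Parameters
    ----------
    I : float
        Constant bias current (dimensionless).
    alpha, beta : float
        Recovery-nullcline offset and slope; ``beta > 0`` is required for
        a well-defined recovery nullcline ``w = (v + alpha)/beta``.
    epsilon : float
        Fast/slow time-scale ratio, ``0 < epsilon``; values ``>= 1`` are
        allowed but warn, since there is then no slow-fast separation.
    """

    I: float = 0.265
    alpha: float = 0.7
    beta: float = 0.75
    epsilon: float = 0.08

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.epsilon >= 1:
            warnings.warn(
                "epsilon >= 1: no fast/slow time-scale separation; "
                "excitable-regime diagnostics may be meaningless",
                stacklevel=2,
            )


#: The reference excitable-regime parameter set used throughout the package.
REFERENCE_PARAMS = ModelParams(I=0.265, alpha=0.7, beta=0.75, epsilon=0.08)


@dataclass(frozen=True)
class NoiseSpec:
    """Channel-noise specification: ``h(w) = sigma0`` (additive) or
    ``h(w) = sigma0 * w`` (multiplicative), entering the recovery equation
    as a Stratonovich integral."""

    kind: str = "additive"
    sigma0: float = 0.01

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be non-negative")


def drift_field(state, params: ModelParams):
    """Evaluate the deterministic vector field ``(f, g)`` at ``state = (v, w)``.

    Accepts scalars or arrays (broadcast), returns ``(f, g)``.
    """
    v = np.asarray(state[0], dtype=float)
    w = np.asarray(state[1], dtype=float)
    f = v - v**3 / 3.0 - w + params.I
    g = params.epsilon * (v + params.alpha - params.beta * w)
    return f, g


def drift_vector(X: np.ndarray, params: ModelParams) -> np.ndarray:
    """Vectorized drift on stacked states of shape ``(..., 2)``."""
    X = np.asarray(X, dtype=float)
    f, g = drift_field((X[..., 0], X[..., 1]), params)
    return np.stack([f, g], axis=-1)


def critical_manifold(v, params: ModelParams):
    """The v-nullcline ``w = v - v^3/3 + I`` (critical manifold of the
    layer problem in the singular limit ``epsilon -> 0``)."""
    v = np.asarray(v, dtype=float)
    return v - v**3 / 3.0 + params.I


@dataclass
class EquilibriumAnalysis:
    """Fixed point of the model plus (optionally) its linearization.

    ``p, q`` are the reduced-cubic coefficients of ``v^3 + p v + q = 0``,
    ``discriminant`` is ``(p/3)^3 + (q/2)^2`` written directly as
    ``(1/beta - 1)^3 + (9/4)(alpha/beta - I)^2``.  The linear fields
    (``M``, ``mu``, ``nu``...) are filled by :func:`analyze_equilibrium`.
    """

    p: float
    q: float
    discriminant: float
    v_e: float
    w_e: float
    M: np.ndarray | None = None
    mu: float | None = None
    nu: float | None = None
    mu_nu_ratio: float | None = None
    excitable: bool | None = None
    gamma_fn_coefficients: tuple[float, float] = field(default=(1.0 / 3.0, 0.0))

    def __post_init__(self) -> None:
        self.gamma_fn_coefficients = (1.0 / 3.0, abs(self.v_e))

    @property
    def state(self) -> np.ndarray:
        return np.array([self.v_e, self.w_e])


def fixed_point(params: ModelParams) -> EquilibriumAnalysis:
    """Unique fixed point of the excitable regime via the Cardano root.

    Evaluates ``v_e = cbrt(-q/2 - sqrt(D)) + cbrt(-q/2 + sqrt(D))`` with
    real (sign-handled) cube roots, then applies one safeguarded Newton
    polish on ``v^3 + p v + q`` to suppress floating cancellation near
    ``D -> 0``.  ``w_e = (v_e + alpha)/beta``.

    Raises
    ------
    NoUniqueFixedPointError
        If the discriminant is not positive (one/three-fixed-point
        boundary or multi-equilibrium regime).
    """
    I, alpha, beta = params.I, params.alpha, params.beta
    p = 3.0 * (1.0 / beta - 1.0)
    q = 3.0 * (alpha / beta - I)
    disc = (1.0 / beta - 1.0) ** 3 + 2.25 * (alpha / beta - I) ** 2
    if disc <= 0:
        raise NoUniqueFixedPointError(
            "discriminant <= 0: not a unique fixed point; "
            "excitable-regime analysis unavailable"
        )
    s = np.sqrt(disc)
    v_e = float(np.cbrt(-q / 2.0 - s) + np.cbrt(-q / 2.0 + s))
    # one safeguarded Newton step: only accept it if it reduces the residual
    res = v_e**3 + p * v_e + q
    deriv = 3.0 * v_e**2 + p
    if deriv != 0.0:
        cand = v_e - res / deriv
        if abs(cand**3 + p * cand + q) < abs(res):
            v_e = cand
    w_e = (v_e + alpha) / beta
    return EquilibriumAnalysis(p=p, q=q, discriminant=disc, v_e=v_e, w_e=w_e)


def jacobian_and_eigen(params: ModelParams, v_e: float):
    """Jacobian ``M = [[1 - v_e^2, -1], [eps, -eps*beta]]`` at the fixed
    point and its complex eigenvalue pair ``-mu +/- i nu`` from the closed
    forms; cross-checked against a numeric eigendecomposition.

    Returns ``(M, mu, nu)``.

    Raises
    ------
    NonOscillatoryError
        If ``4*eps <= (1 - v_e^2 + eps*beta)^2`` (real eigenvalues).
    """
    eps, beta = params.epsilon, params.beta
    M = np.array([[1.0 - v_e**2, -1.0], [eps, -eps * beta]])
    rad = 4.0 * eps - (1.0 - v_e**2 + eps * beta) ** 2
    if rad <= 0:
        raise NonOscillatoryError(
            "non-oscillatory equilibrium (real eigenvalues); "
            "averaging reduction invalid"
        )
    mu = -0.5 * (1.0 - v_e**2 - eps * beta)
    nu = 0.5 * np.sqrt(rad)
    ev = np.linalg.eigvals(M)
    err = min(abs(ev[0] - (-mu + 1j * nu)), abs(ev[0] - (-mu - 1j * nu)))
    if err > 1e-10:
        raise AssertionError(
            f"closed-form eigenvalues disagree with numeric ones by {err:.2e}"
        )
    return M, float(mu), float(nu)


def analyze_equilibrium(
    params: ModelParams, ratio_threshold: float = 0.2
) -> EquilibriumAnalysis:
    """Full equilibrium analysis: fixed point + Jacobian/eigenstructure +
    excitability verdict (see :func:`excitability_report` for the criteria).
    """
    eq = fixed_point(params)
    M, mu, nu = jacobian_and_eigen(params, eq.v_e)
    eq.M = M
    eq.mu = mu
    eq.nu = nu
    eq.mu_nu_ratio = mu / nu
    eq.excitable = mu > 0 and mu / nu < ratio_threshold
    return eq


@dataclass
class ExcitabilityReport:
    """Diagnostic flags for the excitable regime and averaging validity."""

    delta_positive: bool
    complex_eigenvalues: bool
    stable_focus: bool
    mu: float | None
    nu: float | None
    mu_nu_ratio: float | None
    ratio_threshold: float
    excitable: bool


def excitability_report(
    params: ModelParams, ratio_threshold: float = 0.2
) -> ExcitabilityReport:
    """Report whether the parameter set is in the excitable regime.

    Verdict is true iff the discriminant is positive (unique fixed point),
    the eigenvalues are complex with ``mu > 0`` (stable focus), and
    ``mu/nu`` is below ``ratio_threshold``, which operationalizes the
    ``mu/nu << 1`` requirement of the averaging reduction.  The report
    never raises: failing regimes come back as flags.
    """
    try:
        eq = fixed_point(params)
    except NoUniqueFixedPointError:
        return ExcitabilityReport(
            delta_positive=False,
            complex_eigenvalues=False,
            stable_focus=False,
            mu=None,
            nu=None,
            mu_nu_ratio=None,
            ratio_threshold=ratio_threshold,
            excitable=False,
        )
    try:
        _, mu, nu = jacobian_and_eigen(params, eq.v_e)
    except NonOscillatoryError:
        return ExcitabilityReport(
            delta_positive=True,
            complex_eigenvalues=False,
            stable_focus=False,
            mu=None,
            nu=None,
            mu_nu_ratio=None,
            ratio_threshold=ratio_threshold,
            excitable=False,
        )
    ratio = mu / nu
    excitable = mu > 0 and ratio < ratio_threshold
    return ExcitabilityReport(
        delta_positive=True,
        complex_eigenvalues=True,
        stable_focus=mu > 0,
        mu=mu,
        nu=nu,
        mu_nu_ratio=ratio,
        ratio_threshold=ratio_threshold,
        excitable=excitable,
    )


def gamma_bound(r, v_e: float):
    """Nonlinear-remainder bound ``gamma(r) = r^2/3 + |v_e| r``.

    ``||F(X) - F(X_e) - M (X - X_e)|| <= gamma(r) ||X - X_e||`` whenever
    ``||X - X_e|| <= r``; increasing in ``r`` with ``gamma(0) = 0``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    return r**2 / 3.0 + abs(v_e) * r


def nonlinear_remainder(X, params: ModelParams, eq: EquilibriumAnalysis) -> np.ndarray:
    """Remainder ``F(X) - F(X_e) - M (X - X_e)`` of the linearization,
    for states ``X`` of shape ``(..., 2)``.  Only the first (fast)
    component is nonzero: ``-(v - v_e)^2 (v + 2 v_e) / 3``.
    """
    if eq.M is None:
        eq = analyze_equilibrium(params)
    X = np.asarray(X, dtype=float)
    dX = X - eq.state
    F = drift_vector(X, params)
    Fe = drift_vector(eq.state, params)
    return F - Fe - dX @ eq.M.T


@dataclass(frozen=True)
class DissipativityConstants:
    """Constants of the one-sided (weak) dissipativity inequality
    ``<X1 - X2, F(X1) - F(X2)> <= a_diss - b_diss ||X1 - X2||^2``."""

    a_diss: float
    b_diss: float


def dissipativity_constants(params: ModelParams) -> DissipativityConstants:
    """Closed-form dissipativity constants
    ``a = 3 (1 + eps*beta/2 + (1-eps)^2/(2 eps beta))^2`` and
    ``b = eps*beta/2``."""
    eps, beta = params.epsilon, params.beta
    a = 3.0 * (1.0 + eps * beta / 2.0 + (1.0 - eps) ** 2 / (2.0 * eps * beta)) ** 2
    b = eps * beta / 2.0
    return DissipativityConstants(a_diss=a, b_diss=b)


def dissipativity_gap(X1, X2, params: ModelParams,
                      consts: DissipativityConstants | None = None):
    """Sampler-side check of the dissipativity inequality.

    Returns ``<X1-X2, F(X1)-F(X2)> - (a - b ||X1-X2||^2)`` for stacked
    state pairs of shape ``(..., 2)``; non-positive values mean the
    inequality holds at those points.
    """
    if consts is None:
        consts = dissipativity_constants(params)
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    dX = X1 - X2
    dF = drift_vector(X1, params) - drift_vector(X2, params)
    lhs = np.sum(dX * dF, axis=-1)
    rhs = consts.a_diss - consts.b_diss * np.sum(dX * dX, axis=-1)
    return lhs - rhs
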