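"""Steady, spatially uniform solutions of the VWF model in canonical flows.

In a homogeneous flow the configuration-tensor evolution reduces to an
algebraic system.  For simple shear ``u = gd*y*x_hat`` (with ``s = gd*tau``):

    2*s*A_xy = f(A)*A_xx - a,   s*A_yy = f(A)*A_xy,   f(A)*A_yy = a,

and for planar pure elongation the printed system

    -2*s*A_xx = f(A)*A_xx - a,  2*s*A_yy = f(A)*A_yy - a,  A_xy = 0,

where the component with coefficient ``+2*s`` is the growing one (the
labelling of axes is immaterial to the length; solutions are returned with
the growing component first).  Both systems collapse to a single scalar
root-finding problem in the trace ``T = Tr(A)``, which is solved with a
bracketed Brent iteration — naive fixed-point iteration on these systems
oscillates.  A time-marching integrator of the full evolution equation is
provided as an independent cross-check and for arbitrary (e.g. rotational)
gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core import (
    TR_I,
    ConfTensor2D,
    FlowGradient2D,
    VWFParams,
    natural_constant,
    relaxation_time,
    scalar_rates,
    vwf_extension,
    vwf_length,
)

__all__ = [
    "SolverError",
    "UnfoldingCurve",
    "steady_pure_shear",
    "steady_pure_elongation",
    "steady_general",
    "unfolding_curve",
    "half_unfolding_threshold",
    "shear_residual",
    "elongation_residual",
    "shear_trace_from_weissenberg",
    "elongation_trace_from_weissenberg",
    "shear_components_from_weissenberg",
]

_TRACE_RTOL = 1e-14


class SolverError(RuntimeError):
    """Raised when a steady solve fails; carries the last state if any."""

    def __init__(self, message: str, last_state=None, residual=None):
        super().__init__(message)
        self.last_state = last_state
        self.residual = residual


# ----------------------------------------------------------------------
# scalar reductions in the Weissenberg number s = gamma_dot * tau
# ----------------------------------------------------------------------

def _shear_trace_ld(s: float, L_max: float) -> np.longdouble:
    """Trace of the steady shear solution, in extended precision.

    Double-precision root-finding alone leaves trace errors that the FENE
    factor amplifies near saturation, so the bracketed Brent root is
    polished with Newton steps in long-double arithmetic.
    """
    a = natural_constant(L_max)
    L2 = L_max**2
    ld = np.longdouble
    if s == 0.0:
        return ld(TR_I)

    def resid(T):
        f = L2 / (L2 - T)
        return 2 * a / f + 2 * s**2 * a / f**3 - T

    T = brentq(resid, 1e-12, L2 * (1 - 1e-13), xtol=1e-300, rtol=_TRACE_RTOL)
    # the polished trace must be consistent with the *extended-precision*
    # L^2 and a used downstream: an eps-level mismatch here is amplified
    # by f^2/L^2 in the components near saturation
    L2l = ld(L_max) ** 2
    al = L2l / (L2l - ld(TR_I))
    Tl, sl = ld(T), ld(s)
    for _ in range(3):
        f = L2l / (L2l - Tl)
        h = 2 * al / f + 2 * sl**2 * al / f**3 - Tl
        hp = -2 * al / L2l - 6 * sl**2 * al / (f**2 * L2l) - 1.0
        step = h / hp
        Tl = Tl - step
        if abs(step) < ld(1e-22) * Tl:
            break
    return Tl


def shear_trace_from_weissenberg(s: float, L_max: float) -> float:
    """Trace of the steady shear solution at Weissenberg number ``s``.

    From the algebraic system: A_yy = a/f, A_xy = s*a/f^2,
    A_xx = a/f + 2*s^2*a/f^3, so the trace satisfies
    ``T = 2a/f(T) + 2 s^2 a / f(T)^3`` — monotone bracketed root in
    ``(0, L^2)``.
    """
    return float(_shear_trace_ld(s, L_max))


def shear_components_from_weissenberg(s: float, L_max: float) -> ConfTensor2D:
    """Steady shear tensor (A_xx, A_xy, A_yy) at Weissenberg number ``s``.

    Components are formed in extended precision and rounded once, so they
    are mutually consistent to the representation limit.
    """
    ld = np.longdouble
    al = ld(L_max) ** 2 / (ld(L_max) ** 2 - ld(TR_I))
    Tl = _shear_trace_ld(abs(s), L_max)
    fl = ld(L_max) ** 2 / (ld(L_max) ** 2 - Tl)
    sl = ld(abs(s))
    a_yy = al / fl
    a_xy = np.sign(s) * sl * al / fl**2
    a_xx = al / fl + 2 * sl**2 * al / fl**3
    return ConfTensor2D(float(a_xx), float(a_xy), float(a_yy))


def _elongation_components(s: float, L_max: float) -> tuple[float, float]:
    """Steady pure-elongation components (growing, shrinking) at ``s``.

    The growing component is ``a/(f - 2s)``, so near saturation ``f - 2s``
    is a tiny difference of huge numbers; solving in the trace is
    catastrophically ill-conditioned there.  Instead the gap
    ``u = f - 2s`` is the root variable (bracketed in log space):

        L^2 (1 - 1/f) (f - 2s)(f + 2s) - 2 a f = 0,   f = 2s + u,

    which is monotone in ``u`` with a sign change between the pole and
    infinite stretch, and gives the growing component as ``a/u`` without
    cancellation.
    """
    a = natural_constant(L_max)
    L2 = L_max**2
    if s == 0.0:
        return 1.0, 1.0

    def phi(log_u):
        u = np.exp(log_u)
        f = 2.0 * s + u
        return L2 * (1.0 - 1.0 / f) * u * (f + 2.0 * s) - 2.0 * a * f

    log_u = brentq(phi, -720.0, 40.0, xtol=1e-14, rtol=8.9e-16)
    # extended-precision Newton polish in u for a certifiable residual;
    # constants formed in extended precision to stay consistent with the
    # residual evaluation
    ld = np.longdouble
    L2l = ld(L_max) ** 2
    al = L2l / (L2l - ld(TR_I))
    u, sl = ld(np.exp(log_u)), ld(s)
    for _ in range(3):
        f = 2 * sl + u
        g = L2l * (1.0 - 1.0 / f) * u * (f + 2 * sl) - 2 * al * f
        dg = (
            L2l * (1.0 - 1.0 / f) * (2 * f)  # d/du of u*(f+2s) with df/du=1
            + L2l * (u * (f + 2 * sl)) / f**2
            - 2 * al
        )
        step = g / dg
        u = u - step
        if abs(step) < ld(1e-22) * u:
            break
    f = 2 * sl + u
    return float(al / u), float(al / (f + 2 * sl))


def elongation_trace_from_weissenberg(s: float, L_max: float) -> float:
    """Trace of the steady pure-elongation solution at ``s = gd*tau``.

    Components a/(f - 2s) (growing) and a/(f + 2s) (shrinking); the FENE
    factor keeps ``f > 2s`` so the solution exists for every rate.
    """
    if s == 0.0:
        return TR_I
    grow, shrink = _elongation_components(s, L_max)
    return grow + shrink


# ----------------------------------------------------------------------
# dimensional interfaces
# ----------------------------------------------------------------------

def steady_pure_shear(gamma_dot: float, params: VWFParams) -> ConfTensor2D:
    """Steady configuration tensor in simple shear at rate ``gamma_dot`` (1/s)."""
    if gamma_dot < 0:
        raise ValueError("shear rate must be non-negative")
    if gamma_dot == 0.0:
        return ConfTensor2D.identity()
    s = gamma_dot * relaxation_time(gamma_dot, params)
    A = shear_components_from_weissenberg(s, params.L_max)
    _check_residual(*shear_residual(A, gamma_dot, params, with_scale=True), A=A, L_max=params.L_max)
    return A


def steady_pure_elongation(gamma_dot: float, params: VWFParams) -> ConfTensor2D:
    """Steady (diagonal) configuration tensor in planar pure elongation."""
    if gamma_dot < 0:
        raise ValueError("shear rate must be non-negative")
    if gamma_dot == 0.0:
        return ConfTensor2D.identity()
    s = gamma_dot * relaxation_time(gamma_dot, params)
    grow, shrink = _elongation_components(s, params.L_max)
    A = ConfTensor2D(grow, 0.0, shrink)
    _check_residual(*elongation_residual(A, gamma_dot, params, with_scale=True), A=A, L_max=params.L_max)
    return A


def _check_residual(res: np.ndarray, scale: np.ndarray, A: ConfTensor2D, L_max: float = None, tol: float = 1e-10) -> None:
    # backward-error criterion: each residual small relative to the
    # magnitude of the terms that form it.  Near extreme saturation the
    # FENE factor f amplifies the rounding of the stored components by a
    # factor ~f, so the attainable relative residual floor is ~eps*f.
    if L_max is not None:
        f = L_max**2 / (L_max**2 - A.trace)
        tol = max(tol, 16.0 * np.finfo(float).eps * f)
    if np.any(np.abs(res) > tol * scale):
        raise SolverError(
            f"steady solve residual too large: {np.max(np.abs(res) / scale):g} (relative)",
            last_state=A,
            residual=res,
        )


def shear_residual(A: ConfTensor2D, gamma_dot: float, params: VWFParams, with_scale=False):
    """Residuals of the three steady-shear equations (zero at a solution).

    With ``with_scale=True`` also returns per-equation term magnitudes for
    a backward-error test; residuals are evaluated in extended precision
    because the FENE factor is delicate near saturation.
    """
    ld = np.longdouble
    s = ld(gamma_dot) * ld(relaxation_time(gamma_dot, params))
    a = ld(params.L_max) ** 2 / (ld(params.L_max) ** 2 - ld(TR_I))
    a11, a12, a22 = ld(A.a_11), ld(A.a_12), ld(A.a_22)
    f = ld(params.L_max) ** 2 / (ld(params.L_max) ** 2 - (a11 + a22))
    res = np.array(
        [
            float(2 * s * a12 - (f * a11 - a)),
            float(s * a22 - f * a12),
            float(f * a22 - a),
        ]
    )
    if not with_scale:
        return res
    scale = np.array(
        [
            float(max(ld(1), abs(2 * s * a12), abs(f * a11), a)),
            float(max(ld(1), abs(s * a22), abs(f * a12))),
            float(max(ld(1), abs(f * a22), a)),
        ]
    )
    return res, scale


def elongation_residual(A: ConfTensor2D, gamma_dot: float, params: VWFParams, with_scale=False):
    """Residuals of the pure-elongation system (growing component first)."""
    ld = np.longdouble
    s = ld(gamma_dot) * ld(relaxation_time(gamma_dot, params))
    a = ld(params.L_max) ** 2 / (ld(params.L_max) ** 2 - ld(TR_I))
    a11, a12, a22 = ld(A.a_11), ld(A.a_12), ld(A.a_22)
    f = ld(params.L_max) ** 2 / (ld(params.L_max) ** 2 - (a11 + a22))
    res = np.array(
        [
            float(f * a11 - a - 2 * s * a11),
            float(f * a22 - a + 2 * s * a22),
            float(a12),
        ]
    )
    if not with_scale:
        return res
    scale = np.array(
        [
            float(max(ld(1), abs(f * a11), a, abs(2 * s * a11))),
            float(max(ld(1), abs(f * a22), a, abs(2 * s * a22))),
            1.0,
        ]
    )
    return res, scale


# ----------------------------------------------------------------------
# time-marching oracle for arbitrary constant gradients
# ----------------------------------------------------------------------

def steady_general(
    G: FlowGradient2D,
    params: VWFParams,
    t_max: float | None = None,
    tol: float = 1e-10,
) -> ConfTensor2D:
    """March ``dA/dt = G.A + A.G^T - (f(A)A - aI)/tau`` to steady state.

    Independent of the algebraic solvers: used as a cross-check and for
    gradients (e.g. rigid rotation) they do not cover.  Raises
    :class:`SolverError` with the last state if ``||dA/dt||`` has not
    dropped below ``tol`` (relative to ``||A||``) by ``t_max`` — e.g. for
    genuinely unsteady tumbling regimes.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    gamma_dot, _ = scalar_rates(G)
    tau = relaxation_time(gamma_dot, params)
    a = natural_constant(params.L_max)
    L2 = params.L_max**2
    g = G.as_matrix()

    def rhs(_t, y):
        A = np.array([[y[0], y[1]], [y[1], y[2]]])
        f = L2 / (L2 - (y[0] + y[2]))
        dA = g @ A + A @ g.T - (f * A - a * np.eye(2)) / tau
        return [dA[0, 0], dA[0, 1], dA[1, 1]]

    # steady state is approached on the slower of the relaxation and
    # stretching timescales; march in windows and test the residual
    t_scale = max(tau, 1.0 / gamma_dot if gamma_dot > 0 else tau)
    if t_max is None:
        t_max = 5e3 * t_scale
    y = np.array([1.0, 0.0, 1.0])
    t = 0.0
    window = 20.0 * t_scale
    while t < t_max:
        sol = solve_ivp(
            rhs,
            (t, min(t + window, t_max)),
            y,
            method="Radau",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise SolverError("time march failed: " + sol.message,
                              last_state=ConfTensor2D(*y))
        y = sol.y[:, -1]
        t = sol.t[-1]
        res = np.asarray(rhs(t, y))
        if np.max(np.abs(res)) <= tol * max(1.0, np.max(np.abs(y))):
            A = ConfTensor2D(*y)
            A.require_spd()
            return A
        window *= 2.0
    raise SolverError(
        f"no steady state within t_max={t_max:g} (residual {np.max(np.abs(res)):g})",
        last_state=ConfTensor2D(*y),
        residual=res,
    )


# ----------------------------------------------------------------------
# unfolding curves and thresholds
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class UnfoldingCurve:
    """Tabulated VWF unfolding response over a grid of shear rates.

    ``normalized_extension`` is the extension divided by the analytic
    saturation value ``L/sqrt(2) - 1``, so it tends to 1 at large rates.
    """

    gamma_dot_grid: np.ndarray
    length_values: np.ndarray
    extension_values: np.ndarray
    normalized_extension: np.ndarray
    flow_type: str = "shear"
    L_max: float = field(default=22.6)

    def __post_init__(self):
        g = np.asarray(self.gamma_dot_grid, dtype=float)
        if g.ndim != 1 or len(g) == 0 or np.any(np.diff(g) <= 0) or np.any(g < 0):
            raise ValueError("gamma_dot_grid must be non-negative, strictly increasing")
        for name in ("length_values", "extension_values", "normalized_extension"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != g.shape or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be finite and match the grid")


_STEADY = {
    "shear": steady_pure_shear,
    "elongation": steady_pure_elongation,
}


def unfolding_curve(flow_type: str, grid, params: VWFParams) -> UnfoldingCurve:
    """Sweep the steady solver over a strictly increasing grid of shear rates."""
    if flow_type not in _STEADY:
        raise ValueError(f"flow_type must be one of {sorted(_STEADY)}")
    grid = np.asarray(grid, dtype=float)
    lengths = np.empty_like(grid)
    for i, gd in enumerate(grid):
        lengths[i] = vwf_length(_STEADY[flow_type](gd, params))
    ext = lengths - 1.0
    e_max = params.L_max / np.sqrt(2.0) - 1.0
    return UnfoldingCurve(grid, lengths, ext, ext / e_max, flow_type, params.L_max)


def half_unfolding_threshold(
    flow_type: str,
    params: VWFParams,
    bracket: tuple[float, float] = (1e2, 1e5),
) -> float:
    """Shear rate at which the VWF length reaches half its saturation value.

    Solves ``L(gd) = L_max / (2*sqrt(2))`` with Brent's method to relative
    tolerance 1e-6; the root is unique because the length is monotone in
    the rate for shear and elongation.  Rotation never extends the tensor,
    so no threshold exists for it.
    """
    if flow_type == "rotation":
        raise ValueError("threshold undefined for rotational flow: length is 1")
    if flow_type not in _STEADY:
        raise ValueError(f"flow_type must be one of {sorted(_STEADY)}")
    target = params.L_max / (2.0 * np.sqrt(2.0))
    solver = _STEADY[flow_type]

    def shortfall(gd):
        return vwf_length(solver(gd, params)) - target

    lo, hi = bracket
    f_lo, f_hi = shortfall(lo), shortfall(hi)
    if not (f_lo < 0 < f_hi):
        raise SolverError(
            f"bracket ({lo:g}, {hi:g}) does not straddle the half-unfolding length "
            f"(shortfalls {f_lo:g}, {f_hi:g})"
        )
    return brentq(shortfall, lo, hi, rtol=1e-7, xtol=1e-12)
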