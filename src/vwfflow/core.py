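"""Constitutive building blocks of the continuum VWF model.

Von Willebrand factor (VWF) is represented by a symmetric, positive-definite
configuration tensor ``A`` whose components are second moments of the
protein's end-to-end vector, ``A_ij = <r_i r_j>``.  The model is a FENE-P
(finitely extensible nonlinear elastic, Peterlin closure) fluid whose
relaxation time is not constant but a saturating function of the scalar
shear rate: at low shear the relaxation time is tiny and the protein stays
globular, above a threshold shear rate it grows by three orders of magnitude
and the protein can unfold.

Two conventions fixed here and used consistently across the package:

* tensors are 2-D with ``Tr(I) = 2`` — both for the planar homogeneous
  flows and for the (r, z) plane of the axisymmetric pipe (no hoop
  component).  With maximum-length parameter ``L`` the saturated
  normalised length is ``L/sqrt(2)``;
* the velocity gradient is stored as ``G_ij = du_i/dx_j`` so that the
  stretching terms of the evolution equation read ``G.A + A.G^T``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TR_I",
    "VWFParams",
    "ConfTensor2D",
    "FlowGradient2D",
    "DimensionlessGroups",
    "relaxation_time",
    "natural_constant",
    "fene_factor",
    "vwf_length",
    "vwf_extension",
    "scalar_rates",
    "shear_gradient",
    "elongation_gradient",
    "rotation_gradient",
    "nondimensionalize",
    "redimensionalize",
]

#: trace of the identity in the 2-D tensor convention
TR_I = 2.0

# fraction of L^2 beyond which a trace is treated as outside the FENE bound
_FENE_GUARD = 1.0 - 1e-10


@dataclass(frozen=True)
class VWFParams:
    """Dimensional parameters of the VWF constitutive model.

    Parameters
    ----------
    alpha : float
        Relaxation-time scale in seconds.  The relaxation time saturates at
        ``alpha * (1 + delta)`` for large shear rates.
    beta : float
        Sharpness of the unfolding transition, in seconds.  Larger values
        switch the relaxation time on over a narrower band of shear rates.
    delta : float
        Dimensionless floor of the relaxation law; the low-shear relaxation
        time is ``alpha * delta``.
    gamma_star : float
        Shear rate (1/s) at which the relaxation time is halfway between
        its floor and its plateau.
    L_max : float
        Dimensionless maximum-length parameter ``L`` of the FENE spring.
        Must satisfy ``L**2 > Tr(I) = 2``.
    """

    alpha: float = 0.069
    beta: float = 3.44e-4
    delta: float = 9.70e-4
    gamma_star: float = 1.0e4
    L_max: float = 22.6

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "delta", "gamma_star"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.L_max**2 > TR_I:
            raise ValueError("L_max**2 must exceed Tr(I) = 2")

    def with_L(self, L_max: float) -> "VWFParams":
        """Return a copy with a different maximum-length parameter."""
        return replace(self, L_max=L_max)


@dataclass(frozen=True)
class ConfTensor2D:
    """Symmetric 2x2 configuration tensor (a_11, a_12, a_22).

    In Cartesian homogeneous flows the components are (A_xx, A_xy, A_yy);
    in the axisymmetric (r, z) plane they are read as (A_rr, A_rz, A_zz).
    """

    a_11: float
    a_12: float
    a_22: float

    @classmethod
    def identity(cls) -> "ConfTensor2D":
        return cls(1.0, 0.0, 1.0)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "ConfTensor2D":
        m = np.asarray(m, dtype=float)
        if m.shape != (2, 2) or abs(m[0, 1] - m[1, 0]) > 1e-12 * (1 + abs(m[0, 1])):
            raise ValueError("expected a symmetric 2x2 matrix")
        return cls(float(m[0, 0]), float(m[0, 1]), float(m[1, 1]))

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.a_11, self.a_12], [self.a_12, self.a_22]])

    @property
    def trace(self) -> float:
        return self.a_11 + self.a_22

    @property
    def det(self) -> float:
        return self.a_11 * self.a_22 - self.a_12**2

    def is_spd(self) -> bool:
        return self.a_11 > 0 and self.a_22 > 0 and self.det > 0

    def require_spd(self) -> None:
        if not self.is_spd():
            raise ValueError(
                "configuration tensor is not positive definite: "
                f"a_11={self.a_11:g}, a_22={self.a_22:g}, det={self.det:g}"
            )


@dataclass(frozen=True)
class FlowGradient2D:
    """Velocity gradient ``G_ij = du_i/dx_j`` of a planar flow.

    ``dimensionless`` flags whether entries are in units of 1/s (False)
    or have been scaled by the flow timescale d/U (True); mixing the two
    in one computation is a detectable error.
    """

    g_11: float
    g_12: float
    g_21: float
    g_22: float
    dimensionless: bool = False

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.g_11, self.g_12], [self.g_21, self.g_22]])


def shear_gradient(gamma_dot: float) -> FlowGradient2D:
    """Gradient of the simple shear flow ``u = gamma_dot * y * x_hat``."""
    return FlowGradient2D(0.0, gamma_dot, 0.0, 0.0)


def elongation_gradient(gamma_dot: float) -> FlowGradient2D:
    """Gradient of planar pure elongation ``u = gamma_dot/2 * (x, -y)``."""
    return FlowGradient2D(gamma_dot / 2.0, 0.0, 0.0, -gamma_dot / 2.0)


def rotation_gradient(omega: float) -> FlowGradient2D:
    """Gradient of the rigid rotation ``u = omega * (y, -x)``."""
    return FlowGradient2D(0.0, omega, -omega, 0.0)


def relaxation_time(gamma_dot, params: VWFParams):
    """Shear-rate-dependent VWF relaxation time, in seconds.

    ``tau(gd) = alpha * (0.5 * (tanh(beta*(gd - gamma_star)) + 1) + delta)``.

    Strictly increasing in the shear rate and bounded between
    ``alpha*delta`` (globular regime) and ``alpha*(1+delta)`` (unfolded
    regime).  Accepts scalars or arrays; negative shear rates are rejected.
    """
    gd = np.asarray(gamma_dot, dtype=float)
    if np.any(gd < 0):
        raise ValueError("shear rate must be non-negative")
    tau = params.alpha * (
        0.5 * (np.tanh(params.beta * (gd - params.gamma_star)) + 1.0) + params.delta
    )
    return float(tau) if np.isscalar(gamma_dot) else tau


def natural_constant(L_max: float) -> float:
    """FENE constant ``a = L^2 / (L^2 - Tr(I))`` (2-D convention).

    Chosen so that A = I is the flow-free equilibrium: f(I) = a exactly.
    """
    L2 = L_max**2
    if not L2 > TR_I:
        raise ValueError("L_max**2 must exceed Tr(I) = 2")
    return L2 / (L2 - TR_I)


def fene_factor(A, L_max: float):
    """Peterlin spring factor ``f(A) = L^2 / (L^2 - Tr(A))``.

    ``A`` may be a :class:`ConfTensor2D` or a trace value / array of trace
    values.  Raises for traces at or beyond the finite-extensibility bound.
    """
    if isinstance(A, ConfTensor2D):
        tr = A.trace
    else:
        tr = np.asarray(A, dtype=float)
    L2 = L_max**2
    if np.any(np.asarray(tr) >= _FENE_GUARD * L2):
        raise ValueError("tensor at/beyond finite extensibility: Tr(A) >= L^2")
    f = L2 / (L2 - tr)
    return float(f) if np.isscalar(tr) or isinstance(A, ConfTensor2D) else f


def vwf_length(A) -> float:
    """Normalised VWF length ``sqrt(Tr(A) / Tr(I))``.

    Equals 1 for the globular equilibrium A = I and saturates at
    ``L/sqrt(2)`` as the tensor approaches the FENE bound.
    """
    if isinstance(A, ConfTensor2D):
        A.require_spd()
        tr = A.trace
    else:
        tr = np.asarray(A, dtype=float)
        if np.any(tr <= 0):
            raise ValueError("trace must be positive")
    out = np.sqrt(tr / TR_I)
    return float(out) if isinstance(A, ConfTensor2D) or np.isscalar(tr) else out


def vwf_extension(A) -> float:
    """VWF extension ``E = L - 1`` (zero at the natural length)."""
    out = vwf_length(A) - 1.0
    return out


def scalar_rates(G: FlowGradient2D | np.ndarray) -> tuple[float, float]:
    """Scalar shear and rotation rates of a planar velocity gradient.

    ``gamma_dot = sqrt(2 D:D)`` and ``omega_dot = sqrt(2 W:W)`` where D and
    W are the symmetric and antisymmetric parts of the gradient.  Simple
    shear gives (g, g), planar pure strain (g, 0), rigid rotation (0, >0).
    """
    m = G.as_matrix() if isinstance(G, FlowGradient2D) else np.asarray(G, dtype=float)
    D = 0.5 * (m + m.T)
    W = 0.5 * (m - m.T)
    gamma_dot = float(np.sqrt(2.0 * np.sum(D * D)))
    omega_dot = float(np.sqrt(2.0 * np.sum(W * W)))
    return gamma_dot, omega_dot


@dataclass(frozen=True)
class DimensionlessGroups:
    """Dimensionless groups of the arterial-flow problem plus their scales.

    ``Re = rho*U*d/mu`` is the Reynolds number, ``xi = alpha*mu/(d^2*rho)``
    is defined so that ``xi*Re`` is the Deborah number (protein relaxation
    over flow timescale).  ``beta_hat`` and ``gamma_star_hat`` are the
    scaled parameters of the relaxation law; ``delta`` and ``L_max`` pass
    through unchanged.
    """

    Re: float
    xi: float
    beta_hat: float
    gamma_star_hat: float
    delta: float
    L_max: float
    # reference scales
    d: float
    U: float
    rho: float
    mu: float
    p_a: float = 0.0

    @property
    def deborah(self) -> float:
        return self.xi * self.Re

    def tau_hat(self, gamma_dot_hat):
        """Dimensionless relaxation time evaluated at dimensionless shear rate.

        ``tau_hat = 0.5*(tanh(beta_hat*Re*(gd - gamma_star_hat/Re)) + 1) + delta``;
        the dimensional time is ``alpha * tau_hat``.
        """
        gd = np.asarray(gamma_dot_hat, dtype=float)
        t = (
            0.5
            * (np.tanh(self.beta_hat * self.Re * (gd - self.gamma_star_hat / self.Re)) + 1.0)
            + self.delta
        )
        return float(t) if np.isscalar(gamma_dot_hat) else t


def nondimensionalize(
    params: VWFParams,
    *,
    d: float,
    U: float,
    rho: float = 1050.0,
    mu: float = 0.0025,
    p_a: float = 0.0,
) -> DimensionlessGroups:
    """Scale the dimensional model onto the pipe scales (d, U).

    Lengths scale with the maximum pipe radius ``d``, velocities with the
    maximum inlet velocity ``U``, shear rates with ``U/d`` and pressure
    with ``rho*U**2`` relative to the outlet gauge ``p_a``.
    """
    if not (d > 0 and U > 0 and rho > 0 and mu > 0):
        raise ValueError("scales d, U, rho, mu must be positive")
    t_flow = rho * d**2 / mu  # viscous diffusion time used by the scalings
    return DimensionlessGroups(
        Re=rho * U * d / mu,
        xi=params.alpha / t_flow,
        beta_hat=params.beta / t_flow,
        gamma_star_hat=params.gamma_star * t_flow,
        delta=params.delta,
        L_max=params.L_max,
        d=d,
        U=U,
        rho=rho,
        mu=mu,
        p_a=p_a,
    )


def redimensionalize(groups: DimensionlessGroups) -> VWFParams:
    """Invert :func:`nondimensionalize`; round-trips to machine precision."""
    t_flow = groups.rho * groups.d**2 / groups.mu
    return VWFParams(
        alpha=groups.xi * t_flow,
        beta=groups.beta_hat * t_flow,
        delta=groups.delta,
        gamma_star=groups.gamma_star_hat / t_flow,
        L_max=groups.L_max,
    )
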