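"""Steady transport of the VWF configuration tensor on a computed flow.

Solves the dimensionless configuration-tensor balance on the frozen flow
field (one-way coupling: the protein does not feed back on the momentum
balance):

    xi*Re*(u.grad(A) - G.A - A.G^T) = -(1/tau_hat)(f(A) A - a I)
                                      + (xi*Re/Pe) lap(A),

for the 2-D tensor (A_rr, A_rz, A_zz) in the (r, z) plane, with
``G = [[u_r, u_z], [w_r, w_z]]`` the in-plane velocity gradient and
``tau_hat`` the dimensionless relaxation law evaluated on the local scalar
shear rate.  The Laplacian term is the artificial diffusion used to
regularise the otherwise hyperbolic equation; its strength is the inverse
Peclet number ``1/Pe`` relative to the advective scale, applied
component-wise with the axisymmetric scalar Laplacian.

Boundary conditions: the inlet profile is the homogeneous steady-shear
solution at the local inlet shear rate (Dirichlet); the axis carries the
symmetry conditions (even diagonal components, vanishing off-diagonal);
the wall and outlet carry no normal diffusive flux.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fd import MappedOps, NewtonError, newton_solve
from .core import TR_I, DimensionlessGroups, VWFParams, natural_constant
from .flow import FlowField, rate_fields
from .geometry import StretchedGrid
from .homogeneous import shear_components_from_weissenberg

__all__ = ["TensorField", "inlet_profile", "solve_vwf_field", "groups_for_flow"]


@dataclass
class TensorField:
    """Discrete steady configuration-tensor field tied to a flow solution."""

    grid: StretchedGrid
    flow: FlowField
    groups: DimensionlessGroups
    Pe: float
    a_rr: np.ndarray
    a_rz: np.ndarray
    a_zz: np.ndarray
    residual_norm: float = 0.0

    @property
    def trace(self) -> np.ndarray:
        return self.a_rr + self.a_zz

    @property
    def length(self) -> np.ndarray:
        """Normalised VWF length field ``sqrt(Tr(A)/2)``."""
        return np.sqrt(self.trace / TR_I)

    @property
    def extension(self) -> np.ndarray:
        return self.length - 1.0

    @property
    def extension_fraction(self) -> np.ndarray:
        """Extension as a fraction of the achievable maximum ``L/sqrt(2)-1``."""
        e_max = self.groups.L_max / np.sqrt(2.0) - 1.0
        return self.extension / e_max

    def is_admissible(self) -> bool:
        tr = self.trace
        spd = (self.a_rr > 0) & (self.a_zz > 0) & (self.a_rr * self.a_zz > self.a_rz**2)
        return bool(np.all(spd) and np.all(tr < self.groups.L_max**2))


def groups_for_flow(
    params: VWFParams,
    Re: float,
    xi: float = 0.043,
    rho: float = 1050.0,
    mu: float = 0.0025,
) -> DimensionlessGroups:
    """Dimensionless groups for a pipe flow at Reynolds number ``Re``.

    The pipe radius is derived from the Deborah-number parameter ``xi``
    (``d = sqrt(alpha*mu/(xi*rho))``, about 1.95 mm for the default blood
    and VWF values) and the velocity scale from ``Re``.
    """
    from .core import nondimensionalize

    d = float(np.sqrt(params.alpha * mu / (xi * rho)))
    U = Re * mu / (rho * d)
    return nondimensionalize(params, d=d, U=U, rho=rho, mu=mu)


def inlet_profile(r, groups: DimensionlessGroups, params: VWFParams | None = None):
    """Inlet configuration tensor for the parabolic profile ``w = 1 - r^2``.

    Per radius this is the homogeneous steady-shear solution at the local
    dimensionless shear rate ``2r``, expressed in (r, z) components: the
    streamwise component is A_zz and the off-diagonal sign follows
    ``sign(dw/dr) = -1``.  Returns arrays (a_rr, a_rz, a_zz).
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any((r < 0) | (r > 1)):
        raise ValueError("inlet radii must lie in [0, 1]")
    L = groups.L_max
    a_rr = np.empty_like(r)
    a_rz = np.empty_like(r)
    a_zz = np.empty_like(r)
    for i, ri in enumerate(r):
        gd_hat = 2.0 * ri
        s = groups.deborah * groups.tau_hat(gd_hat) * gd_hat
        c = shear_components_from_weissenberg(s, L)  # (A_xx, A_xy, A_yy)
        a_zz[i] = c.a_11
        a_rz[i] = -c.a_12  # dw/dr = -2r < 0
        a_rr[i] = c.a_22
    return a_rr, a_rz, a_zz


def _transport_residual(x, ops, grid, groups, Pe, gamma, grad, a_in, scale):
    A = x  # (3, ny, nz): a_rr, a_rz, a_zz
    Arr, Arz, Azz = A[0], A[1], A[2]
    L2 = groups.L_max**2
    a_const = natural_constant(groups.L_max)
    xiRe = groups.deborah
    u_r, u_z, w_r, w_z = grad
    u, w = ops._u, ops._w

    tr = Arr + Azz
    f = L2 / (L2 - tr)
    inv_tau = 1.0 / groups.tau_hat(gamma)

    # stretching G.A + A.G^T
    S_rr = 2.0 * (u_r * Arr + u_z * Arz)
    S_rz = w_r * Arr + (u_r + w_z) * Arz + u_z * Azz
    S_zz = 2.0 * (w_r * Arz + w_z * Azz)

    r = grid.r
    R2 = (grid.R**2)[None, :]

    def lap(F, Fy, Fyy):
        F_r = Fy / np.sqrt(R2)
        out = Fyy / R2 + ops.d_zz(F, Fy, Fyy)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[1:] += F_r[1:] / r[1:]
        out[0] = out[1]  # axis row is overwritten by its BC below
        return out

    res = np.empty_like(A)
    comps = ((Arr, S_rr, 1.0), (Arz, S_rz, 0.0), (Azz, S_zz, 1.0))
    for k, (F, S, iden) in enumerate(comps):
        Fy, Fyy = ops.dy(F), ops.dyy(F)
        adv = ops.advect(F, u, w)
        res[k] = (
            xiRe * (adv - S)
            + inv_tau * (f * F - a_const * iden)
            - (xiRe / Pe) * lap(F, Fy, Fyy)
        )

    # ---- boundary rows -------------------------------------------------
    oy, oz = ops.oy, ops.oz
    Rp = grid.Rp[None, :]
    for k in range(3):
        F = A[k]
        # axis: diagonal components even in r, off-diagonal vanishes
        if k == 1:
            res[k][0, :] = F[0, :]
        else:
            res[k][0, :] = oy.lo[0] * F[0] + oy.lo[1] * F[1] + oy.lo[2] * F[2]
        # wall: no normal diffusive flux, (1 + R'^2) F_y = R R' F_xi
        Fy_wall = oy.hi[0] * F[-1] + oy.hi[1] * F[-2] + oy.hi[2] * F[-3]
        Fxi_wall = np.empty_like(F[-1])
        Fxi_wall[1:-1] = (
            oz.c1_m * F[-1, :-2] + oz.c1_0 * F[-1, 1:-1] + oz.c1_p * F[-1, 2:]
        )
        Fxi_wall[0] = Fxi_wall[1]
        Fxi_wall[-1] = Fxi_wall[-2]
        res[k][-1, :] = (1.0 + Rp[0] ** 2) * Fy_wall - (grid.R * Rp[0]) * Fxi_wall
        # outlet: no axial gradient
        res[k][:, -1] = oz.hi[0] * F[:, -1] + oz.hi[1] * F[:, -2] + oz.hi[2] * F[:, -3]
        # inlet: Dirichlet
        res[k][:, 0] = F[:, 0] - a_in[k]

    return res / scale


def solve_vwf_field(
    flow: FlowField,
    params: VWFParams | DimensionlessGroups,
    Pe: float = 1.0e3,
    tol: float = 1e-8,
    max_newton: int = 40,
    pe_start: float = 1.0e2,
    verbose: bool = False,
) -> TensorField:
    """Solve the steady configuration-tensor field on a frozen flow.

    ``params`` may be dimensional :class:`VWFParams` (groups derived for
    the flow's Re) or ready-made :class:`DimensionlessGroups`.  Newton
    iteration with continuation in the artificial-diffusion Peclet number
    from ``pe_start`` up to ``Pe``; the line search rejects any state
    violating positive diagonals or the finite-extensibility bound.
    Failures raise with a suggestion to lower Pe or refine the mesh — the
    solver never silently changes the requested Pe.
    """
    if Pe <= 0:
        raise ValueError("Pe must be positive")
    grid = flow.grid
    groups = (
        params
        if isinstance(params, DimensionlessGroups)
        else groups_for_flow(params, flow.Re)
    )
    if abs(groups.Re - flow.Re) > 1e-9 * max(1.0, flow.Re):
        raise ValueError("dimensionless groups do not match the flow's Re")

    ops = MappedOps(grid)
    gamma, _ = rate_fields(flow)
    u, w = flow.u, flow.w
    u_y, w_y = ops.dy(u), ops.dy(w)
    grad = (ops.d_r(u, u_y), ops.d_z(u, u_y), ops.d_r(w, w_y), ops.d_z(w, w_y))
    ops._u, ops._w = u, w  # frozen velocities for the advection operator

    a_in = np.stack(inlet_profile(grid.y, groups))
    x = np.repeat(a_in[:, :, None], grid.nz, axis=2)
    L2 = groups.L_max**2
    scale = groups.deborah * (1.0 + natural_constant(groups.L_max))

    def admissible(v):
        return bool(
            np.all(v[0] > 0)
            and np.all(v[2] > 0)
            and np.all(v[0] + v[2] < 0.999 * L2)
        )

    pe_levels = []
    p = min(pe_start, Pe)
    while p < Pe:
        pe_levels.append(p)
        p *= np.sqrt(10.0)
    pe_levels.append(Pe)

    last_exc = None
    for pe_now in pe_levels:
        try:
            x = newton_solve(
                lambda v: _transport_residual(
                    v, ops, grid, groups, pe_now, gamma, grad, a_in, scale
                ),
                x,
                nvar=3,
                ny=grid.ny,
                nz=grid.nz,
                tol=tol,
                max_iter=max_newton,
                state_ok=admissible,
                verbose=verbose,
            )
        except NewtonError as exc:
            last_exc = exc
            raise NewtonError(
                f"tensor transport failed at Pe={pe_now:g}: {exc}; "
                "consider a lower Pe or a finer mesh",
                exc.last_state,
                exc.residual_norm,
            ) from exc

    F = _transport_residual(x, ops, grid, groups, Pe, gamma, grad, a_in, scale)
    field = TensorField(
        grid=grid,
        flow=flow,
        groups=groups,
        Pe=Pe,
        a_rr=x[0],
        a_rz=x[1],
        a_zz=x[2],
        residual_norm=float(np.max(np.abs(F))),
    )
    return field
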