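"""Finite-difference machinery on nonuniform, body-fitted structured grids.

Second-order 3-point formulas on nonuniform spacings, second-order-upwind
(SOU) convective derivatives, chain-rule composition for the stenosis
mapping y = r / R(z), a coloured finite-difference sparse Jacobian and a
damped Newton driver.  Fields are (ny, nz) arrays; axis 0 is the mapped
radial direction, axis 1 the axial direction.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu


# ----------------------------------------------------------------------
# 1-D nonuniform difference coefficients
# ----------------------------------------------------------------------

class Ops1D:
    """Difference coefficient tables for one nonuniform coordinate."""

    def __init__(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        n = len(x)
        if n < 5 or np.any(np.diff(x) <= 0):
            raise ValueError("coordinate must be strictly increasing, n >= 5")
        self.x = x
        self.n = n
        hm = x[1:-1] - x[:-2]   # x_i - x_{i-1}
        hp = x[2:] - x[1:-1]    # x_{i+1} - x_i

        # centred first derivative (exact for quadratics)
        self.c1_m = -hp / (hm * (hm + hp))
        self.c1_0 = (hp - hm) / (hm * hp)
        self.c1_p = hm / (hp * (hm + hp))
        # centred second derivative
        self.c2_m = 2.0 / (hm * (hm + hp))
        self.c2_0 = -2.0 / (hm * hp)
        self.c2_p = 2.0 / (hp * (hm + hp))

        # one-sided 3-point first derivatives at the two ends
        h1, h2 = x[1] - x[0], x[2] - x[1]
        self.lo = np.array(
            [-(2 * h1 + h2) / (h1 * (h1 + h2)),
             (h1 + h2) / (h1 * h2),
             -h1 / (h2 * (h1 + h2))]
        )
        g1, g2 = x[-1] - x[-2], x[-2] - x[-3]
        self.hi = np.array(
            [(2 * g1 + g2) / (g1 * (g1 + g2)),
             -(g1 + g2) / (g1 * g2),
             g1 / (g2 * (g1 + g2))]
        )

        # SOU (backward- and forward-biased) first derivatives, valid on
        # interior ranges [2, n) and [0, n-2) respectively
        b1 = x[2:] - x[1:-1]    # x_i - x_{i-1} for i >= 2
        b2 = x[1:-1] - x[:-2]   # x_{i-1} - x_{i-2}
        self.bw_0 = (2 * b1 + b2) / (b1 * (b1 + b2))
        self.bw_1 = -(b1 + b2) / (b1 * b2)
        self.bw_2 = b1 / (b2 * (b1 + b2))
        # forward-biased: at node i (0 <= i <= n-3), uses i, i+1, i+2
        s1 = x[1:-1] - x[:-2]
        s2 = x[2:] - x[1:-1]
        self.fw_0 = -(2 * s1 + s2) / (s1 * (s1 + s2))
        self.fw_1 = (s1 + s2) / (s1 * s2)
        self.fw_2 = -s1 / (s2 * (s1 + s2))


def d1(F: np.ndarray, ops: Ops1D, axis: int) -> np.ndarray:
    """Centred first derivative along ``axis``; one-sided at both ends."""
    F = np.moveaxis(F, axis, 0)
    out = np.empty_like(F)
    c = ops
    shape = (-1,) + (1,) * (F.ndim - 1)
    out[1:-1] = (
        c.c1_m.reshape(shape) * F[:-2]
        + c.c1_0.reshape(shape) * F[1:-1]
        + c.c1_p.reshape(shape) * F[2:]
    )
    out[0] = c.lo[0] * F[0] + c.lo[1] * F[1] + c.lo[2] * F[2]
    out[-1] = c.hi[0] * F[-1] + c.hi[1] * F[-2] + c.hi[2] * F[-3]
    return np.moveaxis(out, 0, axis)


def d2(F: np.ndarray, ops: Ops1D, axis: int) -> np.ndarray:
    """Centred second derivative along ``axis``; ends copy the neighbour."""
    F = np.moveaxis(F, axis, 0)
    out = np.empty_like(F)
    c = ops
    shape = (-1,) + (1,) * (F.ndim - 1)
    out[1:-1] = (
        c.c2_m.reshape(shape) * F[:-2]
        + c.c2_0.reshape(shape) * F[1:-1]
        + c.c2_p.reshape(shape) * F[2:]
    )
    out[0] = out[1]
    out[-1] = out[-2]
    return np.moveaxis(out, 0, axis)


def d1_upwind(F: np.ndarray, V: np.ndarray, ops: Ops1D, axis: int) -> np.ndarray:
    """Second-order-upwind first derivative along ``axis`` with wind ``V``.

    Falls back to first-order upwind (and finally to the one-sided centred
    value) on the two lines nearest each boundary where the 3-point biased
    stencil does not fit.
    """
    Fm = np.moveaxis(F, axis, 0)
    Vm = np.moveaxis(V, axis, 0)
    n = Fm.shape[0]
    shape = (-1,) + (1,) * (Fm.ndim - 1)

    bw = (
        ops.bw_0.reshape(shape) * Fm[2:]
        + ops.bw_1.reshape(shape) * Fm[1:-1]
        + ops.bw_2.reshape(shape) * Fm[:-2]
    )  # valid at nodes 2..n-1
    fw = (
        ops.fw_0.reshape(shape) * Fm[:-2]
        + ops.fw_1.reshape(shape) * Fm[1:-1]
        + ops.fw_2.reshape(shape) * Fm[2:]
    )  # valid at nodes 0..n-3

    x = ops.x
    dxm = (x[1:] - x[:-1]).reshape((-1,) + (1,) * (Fm.ndim - 1))
    fo_b = (Fm[1:] - Fm[:-1]) / dxm  # backward at nodes 1..n-1
    fo_f = fo_b                       # forward at nodes 0..n-2

    out = np.empty_like(Fm)
    # interior nodes 2..n-3: full SOU either direction
    out[2 : n - 2] = np.where(Vm[2 : n - 2] >= 0, bw[: n - 4], fw[2:])
    # node 1: backward is first-order, forward SOU available
    out[1] = np.where(Vm[1] >= 0, fo_b[0], fw[1])
    # node n-2: backward SOU available, forward first-order
    out[n - 2] = np.where(Vm[n - 2] >= 0, bw[n - 4], fo_f[n - 2])
    # boundary nodes: one-sided into the domain
    out[0] = fo_f[0]
    out[n - 1] = fo_b[n - 2]
    return np.moveaxis(out, 0, axis)


# ----------------------------------------------------------------------
# mapped derivatives on the body-fitted grid
# ----------------------------------------------------------------------

class MappedOps:
    """Physical-space derivatives for fields on a :class:`StretchedGrid`.

    The mapping is y = r/R(z), xi = z, giving
      F_r  = F_y / R,
      F_z  = F_xi + y_z F_y            with y_z  = -y R'/R,
      F_rr = F_yy / R^2,
      F_zz = F_xixi + 2 y_z F_yxi + y_z^2 F_yy + y_zz F_y,
    where y_zz = y (2 R'^2/R^2 - R''/R).
    """

    def __init__(self, grid):
        self.grid = grid
        self.oy = Ops1D(grid.y)
        self.oz = Ops1D(grid.z)
        R, Rp, Rpp = grid.R, grid.Rp, grid.Rpp
        y = grid.y[:, None]
        self.R = R[None, :]
        self.y_z = -y * (Rp / R)[None, :]
        self.y_zz = y * (2.0 * Rp**2 / R**2 - Rpp / R)[None, :]
        self.r = grid.r

    def dy(self, F):
        return d1(F, self.oy, 0)

    def dz(self, F):
        return d1(F, self.oz, 1)

    def dyy(self, F):
        return d2(F, self.oy, 0)

    def dzz(self, F):
        return d2(F, self.oz, 1)

    def d_r(self, F, Fy=None):
        Fy = self.dy(F) if Fy is None else Fy
        return Fy / self.R

    def d_z(self, F, Fy=None, Fz=None):
        Fy = self.dy(F) if Fy is None else Fy
        Fz = self.dz(F) if Fz is None else Fz
        return Fz + self.y_z * Fy

    def d_rr(self, F, Fyy=None):
        Fyy = self.dyy(F) if Fyy is None else Fyy
        return Fyy / self.R**2

    def d_zz(self, F, Fy=None, Fyy=None):
        Fy = self.dy(F) if Fy is None else Fy
        Fyy = self.dyy(F) if Fyy is None else Fyy
        Fyx = self.dy(self.dz(F))
        return self.dzz(F) + 2.0 * self.y_z * Fyx + self.y_z**2 * Fyy + self.y_zz * Fy

    def advect(self, F, u, w):
        """Upwinded ``u F_r + w F_z`` using contravariant winds.

        ``u`` and ``w`` are the physical radial and axial velocities.
        """
        Vy = u / self.R + w * self.y_z
        Fy = d1_upwind(F, Vy, self.oy, 0)
        Fz = d1_upwind(F, w, self.oz, 1)
        return Vy * Fy + w * Fz


# ----------------------------------------------------------------------
# coloured sparse Jacobian + damped Newton
# ----------------------------------------------------------------------

def colored_jacobian(residual, x0, nvar, ny, nz, stencil=2, eps=1e-7):
    """Sparse Jacobian of ``residual`` by simultaneous perturbations.

    The residual is assumed local: row (v', i, j) depends only on unknowns
    within ``stencil`` nodes in each grid direction (any variable).
    Unknowns are coloured modulo (2*stencil+1) in both directions so that
    perturbed footprints never overlap; one residual evaluation per colour
    and variable.
    """
    m = 2 * stencil + 1
    F0 = residual(x0)
    N = nvar * ny * nz
    x0 = x0.ravel()
    I, J, V = [], [], []
    di = np.arange(-stencil, stencil + 1)
    offsets = np.stack(np.meshgrid(np.arange(nvar), di, di, indexing="ij"), -1).reshape(-1, 3)

    idx_i, idx_j = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    for v in range(nvar):
        for ci in range(m):
            for cj in range(m):
                mask = (idx_i % m == ci) & (idx_j % m == cj)
                mi, mj = idx_i[mask], idx_j[mask]
                cols = (v * ny + mi) * nz + mj
                h = eps * (1.0 + np.abs(x0[cols]))
                xp = x0.copy()
                xp[cols] += h
                dF = (residual(xp.reshape(nvar, ny, nz)) - F0).ravel()
                # rows affected by each perturbed column
                ri = mi[:, None] + offsets[None, :, 1]
                rj = mj[:, None] + offsets[None, :, 2]
                rv = np.broadcast_to(offsets[None, :, 0], ri.shape)
                ok = (ri >= 0) & (ri < ny) & (rj >= 0) & (rj < nz)
                rows = (rv * ny + np.clip(ri, 0, ny - 1)) * nz + np.clip(rj, 0, nz - 1)
                vals = dF[rows] / h[:, None]
                keep = ok & (vals != 0.0)
                I.append(rows[keep])
                J.append(np.broadcast_to(cols[:, None], rows.shape)[keep])
                V.append(vals[keep])
    Jac = csc_matrix(
        (np.concatenate(V), (np.concatenate(I), np.concatenate(J))), shape=(N, N)
    )
    return Jac, F0


class NewtonError(RuntimeError):
    def __init__(self, message, last_state=None, residual_norm=None):
        super().__init__(message)
        self.last_state = last_state
        self.residual_norm = residual_norm


def newton_solve(
    residual,
    x0,
    nvar,
    ny,
    nz,
    tol=1e-9,
    max_iter=25,
    stencil=2,
    state_ok=None,
    verbose=False,
    log=None,
):
    """Damped Newton iteration with a coloured-FD Jacobian and direct solve.

    ``state_ok(x)`` may veto a trial state (e.g. FENE bound violation),
    forcing a shorter step.  Returns the converged state; raises
    :class:`NewtonError` with the last iterate otherwise.
    """
    x = np.array(x0, dtype=float)
    norm0 = np.max(np.abs(residual(x)))
    if log is not None:
        log.append(norm0)
    if norm0 <= tol:
        return x
    for it in range(max_iter):
        Jac, F = colored_jacobian(residual, x, nvar, ny, nz, stencil=stencil)
        norm = np.max(np.abs(F))
        try:
            lu = splu(Jac.tocsc())
        except RuntimeError as exc:
            raise NewtonError(f"Jacobian factorisation failed: {exc}", x, norm)
        step = lu.solve(-F.ravel()).reshape(x.shape)
        lam, accepted = 1.0, False
        for _ in range(12):
            xt = x + lam * step
            if state_ok is not None and not state_ok(xt):
                lam *= 0.5
                continue
            nt = np.max(np.abs(residual(xt)))
            if nt < norm * (1.0 - 1e-4 * lam) or nt <= tol:
                x, norm, accepted = xt, nt, True
                break
            lam *= 0.5
        if not accepted:
            raise NewtonError(
                f"line search stalled at iteration {it} (|F|={norm:.3e})", x, norm
            )
        if verbose:
            print(f"  newton it={it} |F|={norm:.3e} lam={lam:g}")
        if log is not None:
            log.append(norm)
        if norm <= tol:
            return x
    raise NewtonError(f"no convergence in {max_iter} iterations (|F|={norm:.3e})", x, norm)
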