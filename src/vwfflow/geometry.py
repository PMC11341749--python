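"""Axisymmetric stenosis geometry and body-fitted structured grids.

The vessel is a pipe of unit dimensionless radius with a smooth,
flat-topped axisymmetric constriction centred at z = 0:

    r_wall(z) = 1 - h * B(|z|),
    B = 1                                   for |z| <= l1,
    B = (1 + cos(pi*(|z| - l1)/l2)) / 2     for l1 < |z| <= l1 + l2,
    B = 0                                   beyond,

a C^1 cosine-ramp bump of height ``h``, half-length ``l1`` and steepness
proportional to ``h/l2`` (max wall slope ``pi*h/(2*l2)``).

The computational mesh is a structured body-fitted grid: the radial
coordinate is mapped as ``y = r / r_wall(z)`` onto the unit square strip,
with hyperbolic-sine clustering of the y-lines toward the wall and an
axially graded spacing that refines around the stenosis.  Boundary tags
{inlet, outlet, wall, axis} are the four edges of the structured grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StenosisGeometry", "MeshSpec", "StretchedGrid", "wall_profile", "build_mesh"]


@dataclass(frozen=True)
class StenosisGeometry:
    """Dimensionless stenosis description (lengths scaled by pipe radius)."""

    h: float = 0.5
    l1: float = 1.5
    l2: float = 2.0
    z_i: float = -10.0
    z_o: float | None = None  # defaults to 30 + l1 + l2

    def __post_init__(self):
        if not (0.0 <= self.h < 1.0):
            raise ValueError("height h must lie in [0, 1)")
        if self.l1 <= 0 or self.l2 <= 0:
            raise ValueError("l1 and l2 must be positive")
        if self.z_o is None:
            object.__setattr__(self, "z_o", 30.0 + self.l1 + self.l2)
        if not self.z_i < -(self.l1 + self.l2):
            raise ValueError("inlet must sit upstream of the stenosis ramp")
        if not self.z_o > self.l1 + self.l2:
            raise ValueError("outlet must sit downstream of the stenosis ramp")

    # -- wall shape and its first two derivatives ----------------------

    def wall(self, z):
        z = np.asarray(z, dtype=float)
        az = np.abs(z)
        ramp = (az > self.l1) & (az <= self.l1 + self.l2)
        B = np.where(az <= self.l1, 1.0, 0.0)
        B = np.where(ramp, 0.5 * (1.0 + np.cos(np.pi * (az - self.l1) / self.l2)), B)
        return 1.0 - self.h * B

    def wall_slope(self, z):
        z = np.asarray(z, dtype=float)
        az = np.abs(z)
        ramp = (az > self.l1) & (az <= self.l1 + self.l2)
        dB = np.where(
            ramp, -0.5 * (np.pi / self.l2) * np.sin(np.pi * (az - self.l1) / self.l2), 0.0
        )
        return -self.h * dB * np.sign(z)

    def wall_curvature(self, z):
        """Second z-derivative of the wall radius (piecewise continuous)."""
        z = np.asarray(z, dtype=float)
        az = np.abs(z)
        ramp = (az > self.l1) & (az <= self.l1 + self.l2)
        d2B = np.where(
            ramp, -0.5 * (np.pi / self.l2) ** 2 * np.cos(np.pi * (az - self.l1) / self.l2), 0.0
        )
        return -self.h * d2B


def wall_profile(z, geom: StenosisGeometry):
    """Wall radius ``r_wall(z)``; rejects coordinates outside [z_i, z_o]."""
    z = np.asarray(z, dtype=float)
    if np.any(z < geom.z_i) or np.any(z > geom.z_o):
        raise ValueError(f"z outside domain [{geom.z_i}, {geom.z_o}]")
    out = geom.wall(z)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MeshSpec:
    """Grid-resolution controls.

    ``dz_fine`` is the axial target cell size over the stenosis,
    ``dz_far`` the far-field cap, ``n_radial`` the number of radial lines
    and ``wall_cluster`` the sinh-stretching strength toward the wall
    (larger -> thinner wall cells; ~5x finer at the wall for the default).
    """

    dz_fine: float = 0.06
    dz_far: float = 0.45
    n_radial: int = 65
    wall_cluster: float = 3.2
    growth: float = 1.10

    def __post_init__(self):
        if self.dz_fine <= 0 or self.dz_far < self.dz_fine:
            raise ValueError("need 0 < dz_fine <= dz_far")
        if self.n_radial < 8:
            raise ValueError("n_radial too small")
        if not (1.0 < self.growth < 1.5):
            raise ValueError("growth must be a mild geometric ratio")


@dataclass(frozen=True)
class StretchedGrid:
    """Body-fitted structured grid over the mapped strip [0,1] x [z_i, z_o]."""

    y: np.ndarray  # (ny,) mapped radial lines, 0 = axis, 1 = wall
    z: np.ndarray  # (nz,) axial stations
    geometry: StenosisGeometry

    @property
    def ny(self) -> int:
        return len(self.y)

    @property
    def nz(self) -> int:
        return len(self.z)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nz)

    @property
    def R(self) -> np.ndarray:
        return self.geometry.wall(self.z)

    @property
    def Rp(self) -> np.ndarray:
        return self.geometry.wall_slope(self.z)

    @property
    def Rpp(self) -> np.ndarray:
        return self.geometry.wall_curvature(self.z)

    @property
    def r(self) -> np.ndarray:
        """Physical radii, shape (ny, nz)."""
        return self.y[:, None] * self.R[None, :]

    @property
    def zz(self) -> np.ndarray:
        """Axial coordinate broadcast to (ny, nz)."""
        return np.broadcast_to(self.z[None, :], self.shape)

    #: edge names -> (axis, index): axis 0 is radial, axis 1 is axial
    @property
    def boundary_tags(self) -> dict[str, tuple[int, int]]:
        return {
            "axis": (0, 0),
            "wall": (0, self.ny - 1),
            "inlet": (1, 0),
            "outlet": (1, self.nz - 1),
        }

    def quality(self) -> dict[str, float]:
        """Simple grid-quality metrics (spacing ratios, wall cell size)."""
        dy = np.diff(self.y)
        dz = np.diff(self.z)
        return {
            "n_cells": float((self.ny - 1) * (self.nz - 1)),
            "dy_wall": float(dy[-1]),
            "dy_axis": float(dy[0]),
            "dz_min": float(dz.min()),
            "dz_max": float(dz.max()),
            "max_dz_ratio": float(np.max(dz[1:] / dz[:-1])),
        }


def _radial_lines(n: int, cluster: float) -> np.ndarray:
    s = np.linspace(0.0, 1.0, n)
    if cluster <= 0:
        return s
    y = 1.0 - np.sinh(cluster * (1.0 - s)) / np.sinh(cluster)
    y[0], y[-1] = 0.0, 1.0
    return y


def _axial_stations(geom: StenosisGeometry, spec: MeshSpec) -> np.ndarray:
    """Fine uniform spacing over the stenosis, geometric grading outside."""
    z_lo = -(geom.l1 + geom.l2) - 1.5
    z_hi = (geom.l1 + geom.l2) + 5.0
    z_lo = max(z_lo, geom.z_i)
    z_hi = min(z_hi, geom.z_o)

    core = np.arange(z_lo, z_hi + 0.5 * spec.dz_fine, spec.dz_fine)

    def grade(start, stop, direction):
        pts = []
        dz = spec.dz_fine
        zc = start
        while (stop - zc) * direction > 1e-12:
            dz = min(dz * spec.growth, spec.dz_far, abs(stop - zc))
            zc = zc + direction * dz
            pts.append(zc)
        if pts:
            pts[-1] = stop
        return np.asarray(pts)

    left = grade(z_lo, geom.z_i, -1.0)[::-1]
    right = grade(core[-1], geom.z_o, +1.0)
    return np.concatenate([left, core, right])


def build_mesh(geom: StenosisGeometry, spec: MeshSpec | None = None) -> StretchedGrid:
    """Build the body-fitted grid for a stenosis geometry.

    All nodes satisfy ``0 <= r <= r_wall(z)`` by construction of the
    mapping; boundary tags are the four structured edges.
    """
    spec = spec or MeshSpec()
    y = _radial_lines(spec.n_radial, spec.wall_cluster)
    z = _axial_stations(geom, spec)
    if len(z) < 8:
        raise ValueError("axial grid degenerate; check geometry/spec")
    return StretchedGrid(y=y, z=z, geometry=geom)
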