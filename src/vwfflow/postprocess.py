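"""Wall series and elongational-flow-region extraction.

Two reductions of a solved case are of clinical interest: the state of VWF
along the stenosis wall, where extended proteins can capture platelets,
and the elongation-dominated region in the core of the vessel near the
stenosis entrance, where ``gamma_dot`` appreciably exceeds ``omega_dot``
and proteins unfold without the relief of rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .flow import FlowField, rate_fields
from .transport import TensorField

__all__ = ["RegionReport", "wall_series", "elongational_region", "high_extension_arclength"]


def _check_matching(flow: FlowField, field: TensorField | None):
    if field is not None and field.grid is not flow.grid:
        if (
            field.grid.shape != flow.grid.shape
            or not np.allclose(field.grid.y, flow.grid.y)
            or not np.allclose(field.grid.z, flow.grid.z)
        ):
            raise ValueError("flow and tensor field live on different meshes")


def wall_series(flow: FlowField, field: TensorField) -> pd.DataFrame:
    """Sampled quantities along the stenosis wall, ordered by z.

    Columns: ``z``, ``r_wall``, ``gamma_dot`` (dimensionless), ``WSR``
    (scaled wall shear rate, ``Re * gamma_dot``), ``E`` (VWF extension)
    and ``E_pct`` (extension as % of the achievable maximum
    ``L/sqrt(2) - 1``).
    """
    _check_matching(flow, field)
    gamma, _ = rate_fields(flow)
    z = flow.grid.z
    df = pd.DataFrame(
        {
            "z": z,
            "r_wall": flow.grid.R,
            "gamma_dot": gamma[-1, :],
            "WSR": flow.Re * gamma[-1, :],
            "E": field.extension[-1, :],
            "E_pct": 100.0 * field.extension_fraction[-1, :],
        }
    )
    return df


def high_extension_arclength(series: pd.DataFrame, fraction: float = 0.5) -> float:
    """Wall arclength over which the extension exceeds ``fraction*max(E)``.

    Steeper stenoses confine high extension to shorter wall intervals, so
    this shrinks as ``l2`` decreases.
    """
    z = series["z"].to_numpy()
    r = series["r_wall"].to_numpy()
    e = series["E"].to_numpy()
    ds = np.sqrt(np.diff(z) ** 2 + np.diff(r) ** 2)
    above = e >= fraction * e.max()
    seg = 0.5 * (above[:-1].astype(float) + above[1:].astype(float))
    return float(np.sum(ds * seg))


@dataclass
class RegionReport:
    """Summary of the highly elongational core region."""

    threshold: float
    exists: bool
    mask: np.ndarray | None
    max_gamma_dot: float | None
    max_length: float | None
    max_extension: float | None
    extension_pct_of_max: float | None
    n_nodes: int = 0


def elongational_region(
    flow: FlowField,
    field: TensorField | None = None,
    threshold: float = 0.2,
) -> RegionReport:
    """Extract the core region where ``gamma_dot - omega_dot >= threshold``.

    The thresholded node set is restricted to connected components away
    from the wall: a one-cell wall ring is removed first (so "away from
    the wall" is well defined) and any component still touching that ring
    is discarded as part of the wall shear layer.  In a simple shear flow
    ``gamma_dot = omega_dot`` everywhere, so Poiseuille flow yields an
    empty region for any positive threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    _check_matching(flow, field)
    gamma, omega = rate_fields(flow)
    mask = (gamma - omega) >= threshold
    ny = flow.grid.ny
    wall_ring = ny - 2  # wall nodes + one interior ring
    mask[wall_ring:, :] = False

    labels, n = ndimage.label(mask)
    keep = np.zeros_like(mask)
    for lab in range(1, n + 1):
        comp = labels == lab
        if not np.any(comp[wall_ring - 1, :]):
            keep |= comp
    if not np.any(keep):
        return RegionReport(threshold, False, None, None, None, None, None, 0)

    max_gd = float(np.max(gamma[keep]))
    if field is not None:
        max_len = float(np.max(field.length[keep]))
        max_ext = float(np.max(field.extension[keep]))
        pct = float(100.0 * np.max(field.extension_fraction[keep]))
    else:
        max_len = max_ext = pct = None
    return RegionReport(
        threshold=threshold,
        exists=True,
        mask=keep,
        max_gamma_dot=max_gd,
        max_length=max_len,
        max_extension=max_ext,
        extension_pct_of_max=pct,
        n_nodes=int(np.sum(keep)),
    )
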