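"""Config-driven orchestration of the stenosis pipeline.

A case is described by a YAML config (geometry, Reynolds number, VWF
parameters, mesh resolution, artificial-diffusion Peclet number); a run
builds the mesh, solves the flow, solves the tensor transport, and writes
wall series (CSV), field exports (legacy VTK), a JSON summary and a log.
Runs are deterministic for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .calibration import sigmoid_target_curve
from .core import VWFParams
from .flow import detect_recirculation, rate_fields, solve_flow, throat_speedup
from .geometry import MeshSpec, StenosisGeometry, build_mesh
from .postprocess import elongational_region, wall_series
from .transport import solve_vwf_field
from .vtkio import write_vtk

__all__ = ["CaseConfig", "run_pipeline", "make_fixtures"]

_GEOM_KEYS = {"h", "l1", "l2", "z_i", "z_o"}
_VWF_KEYS = {"alpha", "beta", "delta", "gamma_star", "L_max"}
_MESH_KEYS = {"dz_fine", "dz_far", "n_radial", "wall_cluster", "growth"}


@dataclass
class CaseConfig:
    """Validated description of one stenosis case."""

    geometry: dict = field(default_factory=lambda: {"h": 0.5, "l1": 1.5, "l2": 2.0})
    Re: float = 400.0
    vwf: dict = field(default_factory=dict)
    mesh: dict = field(default_factory=dict)
    Pe: float = 1.0e3
    outdir: str = "run"
    seed: int = 0

    def __post_init__(self):
        for block, allowed in (("geometry", _GEOM_KEYS), ("vwf", _VWF_KEYS), ("mesh", _MESH_KEYS)):
            extra = set(getattr(self, block)) - allowed
            if extra:
                raise ValueError(f"unknown keys in {block!r}: {sorted(extra)}")
        # construct eagerly so bad values fail at config time
        self.stenosis_geometry()
        self.mesh_spec()
        self.vwf_params()
        if not self.Re > 0:
            raise ValueError("Re must be positive")

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        known = {"geometry", "Re", "vwf", "mesh", "Pe", "outdir", "seed"}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        missing = {"geometry", "Re"} - set(raw)
        if missing:
            raise ValueError(f"missing required config keys: {sorted(missing)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def stenosis_geometry(self) -> StenosisGeometry:
        return StenosisGeometry(**self.geometry)

    def mesh_spec(self) -> MeshSpec:
        return MeshSpec(**self.mesh)

    def vwf_params(self) -> VWFParams:
        return VWFParams(**self.vwf)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: CaseConfig, write_fields: bool = True) -> dict:
    """Run mesh -> flow -> transport -> postprocessing for one case.

    Writes outputs under ``config.outdir`` and returns the JSON summary
    (max WSR, max extension, wall-maximum location, recirculation report,
    elongational-region report, residuals, mesh statistics).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config digest {config.digest()}"]
    t0 = time.perf_counter()

    def stage(name):
        log_lines.append(f"[{time.perf_counter() - t0:8.2f}s] {name}")

    geom = config.stenosis_geometry()
    mesh = build_mesh(geom, config.mesh_spec())
    stage(f"mesh built: {mesh.ny} x {mesh.nz}, quality {mesh.quality()}")

    flow = solve_flow(mesh, config.Re)
    stage(f"flow solved: residual {flow.residual_norm:.3e}")

    params = config.vwf_params()
    tensors = solve_vwf_field(flow, params, Pe=config.Pe)
    stage(f"transport solved: residual {tensors.residual_norm:.3e}")

    gamma, omega = rate_fields(flow)
    series = wall_series(flow, tensors)
    region = elongational_region(flow, tensors)
    recirc = detect_recirculation(flow)

    i_max = int(series["WSR"].idxmax())
    j_max = int(series["E"].idxmax())
    summary = {
        "config_digest": config.digest(),
        "Re": config.Re,
        "geometry": dict(config.geometry),
        "mesh": mesh.quality(),
        "max_gamma_dot": float(np.max(gamma)),
        "max_speed": float(np.max(flow.speed)),
        "throat_speedup": throat_speedup(flow),
        "max_WSR": float(series["WSR"].max()),
        "wall_max_WSR_z": float(series["z"][i_max]),
        "max_wall_E": float(series["E"].max()),
        "max_wall_E_pct": float(series["E_pct"].max()),
        "wall_max_E_z": float(series["z"][j_max]),
        "max_E": float(np.max(tensors.extension)),
        "recirculation": recirc,
        "elongational_region": {
            "threshold": region.threshold,
            "exists": region.exists,
            "max_gamma_dot": region.max_gamma_dot,
            "max_extension": region.max_extension,
            "extension_pct_of_max": region.extension_pct_of_max,
            "n_nodes": region.n_nodes,
        },
        "residuals": {
            "flow": flow.residual_norm,
            "transport": tensors.residual_norm,
        },
    }

    series.to_csv(out / "wall_series.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    config.to_yaml(out / "case.yaml")
    if write_fields:
        write_vtk(
            out / "fields.vtk",
            mesh,
            {
                "u": flow.u,
                "w": flow.w,
                "gamma_dot": gamma,
                "omega_dot": omega,
                "A_rr": tensors.a_rr,
                "A_rz": tensors.a_rz,
                "A_zz": tensors.a_zz,
                "length": tensors.length,
                "extension": tensors.extension,
            },
        )
    stage("outputs written")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def make_fixtures(kind: str, seed: int = 0, outdir: str | Path = "fixtures"):
    """Generate reproducible fixture files.

    ``target_curve``: synthetic sigmoidal unfolding curve (CSV, half point
    5122 1/s); ``demo_mesh``: coarse straight-pipe grid as legacy VTK;
    ``demo_config``: reference case YAML mirroring the default dimensional
    and dimensionless parameter tables.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if kind == "target_curve":
        grid = np.logspace(2, 5, 60)
        curve = sigmoid_target_curve(half_point=5122.0, width=1500.0, grid=grid)
        noise = 0.0 * rng.standard_normal(len(grid))  # hook for noisy variants
        import pandas as pd

        path = out / "target_curve.csv"
        pd.DataFrame(
            {
                "gamma_dot": curve.gamma_dot_grid,
                "normalized_extension": np.clip(curve.normalized_extension + noise, 0, 1),
            }
        ).to_csv(path, index=False)
        return path
    if kind == "demo_mesh":
        geom = StenosisGeometry(h=0.0, l1=1.5, l2=2.0)
        mesh = build_mesh(geom, MeshSpec(dz_fine=0.5, dz_far=1.0, n_radial=17))
        path = out / "demo_mesh.vtk"
        write_vtk(path, mesh, {"r": mesh.r})
        return path
    if kind == "demo_config":
        cfg = CaseConfig(
            geometry={"h": 0.5, "l1": 1.5, "l2": 2.0},
            Re=400.0,
            vwf={},  # defaults: alpha 0.069 s, beta 3.44e-4 s, delta 9.7e-4,
            #          gamma_star 1e4 1/s, L_max 22.6 -> xi 0.043 at d=1.95 mm
            Pe=1.0e3,
            seed=seed,
        )
        path = out / "demo_config.yaml"
        cfg.to_yaml(path)
        return path
    raise ValueError(f"unknown fixture kind {kind!r}")
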