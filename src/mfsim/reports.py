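"""File writers: CSV profiles/tracks, JSON reports, VTK field dumps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import DropletMetrics
from .mixing import ConcentrationProfile
from .rheology import VelocityProfile
from .usecases import ComparisonReport
from .vtkio import write_vtk_structured_points


def write_profile_csv(path, profile) -> Path:
    """Velocity profiles as (position_um, velocity_mm_s); concentration
    profiles as (position, concentration)."""
    path = Path(path)
    if isinstance(profile, VelocityProfile):
        df = pd.DataFrame(
            {"position_um": profile.z * 1e6, "velocity_mm_s": profile.u * 1e3}
        )
    elif isinstance(profile, ConcentrationProfile):
        df = pd.DataFrame({"position": profile.y, "concentration": profile.alpha})
    else:
        raise TypeError(f"unsupported profile type {type(profile).__name__}")
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def write_track_csv(path, metrics: DropletMetrics) -> Path:
    df = pd.DataFrame(
        {
            "t_ms": np.asarray(metrics.t) * 1e3,
            "s_um": np.asarray(metrics.s_trailing) * 1e6,
            "length_um": np.asarray(metrics.length) * 1e6,
            "n_components": metrics.n_components,
            "branch": metrics.branch,
        }
    )
    df.to_csv(Path(path), index=False, float_format="%.10g")
    return path


def read_profile_csv(path):
    df = pd.read_csv(path)
    if "velocity_mm_s" in df.columns:
        return VelocityProfile(
            z=df["position_um"].to_numpy() * 1e-6,
            u=df["velocity_mm_s"].to_numpy() * 1e-3,
        )
    return ConcentrationProfile(
        y=df["position"].to_numpy(), alpha=df["concentration"].to_numpy(), x=0.0
    )


def write_report_json(path, report: ComparisonReport) -> Path:
    path = Path(path)
    payload = {
        "case": report.case,
        "level": report.level,
        "config_hash": report.config_hash,
        "steps": report.steps,
        "runtime_s": report.runtime_s,
        "results": {
            k: v
            for k, v in report.results.items()
            if isinstance(v, (int, float, str, bool))
        },
        "config": report.config_echo,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")
    return path


def write_outputs(report: ComparisonReport, out_dir, sim=None) -> list[Path]:
    """Write everything a run produced, with deterministic names.

    File names carry the use case, level and config hash so repeated runs
    never collide silently.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{report.case}_{report.level}_{report.config_hash}"
    written = [write_report_json(out / f"{stem}_report.json", report)]
    prof = report.results.get("profile")
    if prof is not None:
        written.append(write_profile_csv(out / f"{stem}_profile.csv", prof))
    metrics = report.results.get("metrics")
    if metrics is not None:
        written.append(write_track_csv(out / f"{stem}_track.csv", metrics))
    traj = report.results.get("trajectory")
    if traj is not None:
        df = pd.DataFrame({"time_ms": traj.t * 1e3, "s_um": traj.s * 1e6})
        p = out / f"{stem}_trajectory.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    if sim is not None:
        fields = {}
        if hasattr(sim, "alpha"):  # two-component
            rho_a, rho_b = sim.densities()
            fields = {
                "rho_a": rho_a,
                "rho_b": rho_b,
                "alpha": sim.alpha(),
                "velocity": sim.velocity(),
            }
        else:
            rho, u = sim.macroscopic()
            fields = {
                "density": rho,
                "velocity": u,
                "shear_rate": sim.strain_rate(),
                "tau": sim.tau,
            }
        written.append(
            write_vtk_structured_points(
                out / f"{stem}_fields.vtk", fields, spacing=sim.scales.dx
            )
        )
    return written


def write_mask_vtk(path, mask, scales) -> Path:
    """Cell-role mask as a VTK scalar field for visual inspection."""
    return write_vtk_structured_points(
        Path(path), {"role": mask.astype(float)}, spacing=scales.dx
    )
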