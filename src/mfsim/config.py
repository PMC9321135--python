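"""Declarative problem configuration: loading, validation, defaults.

Configurations are JSON or YAML mappings with explicit unit suffixes in
the key names (``length_um``, ``u_in_mm_s``, ...), converted to SI on
load.  The three shipped use cases (blood flow, two-fluid mixing, droplet
through a bifurcation) live under ``mfsim/configs/``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .fluids import CarreauYasudaParams, FluidSpec
from .geometry import BifurcationGeometry, ChannelGeometry
from .units import U_LAT_MAX, UnitScales

_UNIT_FACTORS = {
    "_um": 1e-6,
    "_mm": 1e-3,
    "_m": 1.0,
    "_mm_s": 1e-3,
    "_m_s": 1.0,
    "_um2_s": 1e-12,
    "_m2_s": 1.0,
    "_pa_s": 1.0,
    "_pa": 1.0,
    "_kg_m3": 1.0,
    "_n_m": 1.0,
    "_s": 1.0,
    "_ms": 1e-3,
}


class ConfigError(ValueError):
    """Schema or invariant violation, carrying the offending field path."""


def _unit(value, key: str, path: str) -> float:
    for suffix in sorted(_UNIT_FACTORS, key=len, reverse=True):
        if key.endswith(suffix):
            try:
                return float(value) * _UNIT_FACTORS[suffix]
            except (TypeError, ValueError):
                raise ConfigError(f"{path}.{key}: not a number") from None
    raise ConfigError(f"{path}.{key}: key has no recognized unit suffix")


def _get(d: dict, key: str, path: str, required=True, default=None):
    if key in d:
        return d[key]
    if required:
        raise ConfigError(f"{path}: missing required field {key!r}")
    return default


@dataclass
class ProblemConfig:
    """A validated use-case description ready for the drivers."""

    case: str  # flow | mix | droplet
    level: str  # 1d | 2d | 3d
    geometry: ChannelGeometry | BifurcationGeometry
    fluid: FluidSpec
    u_in: float
    p_out: float = 0.0
    dx: float = 1e-6
    u_lat_target: float = 0.05
    shan_chen_g: float | None = None
    species_tau: float | None = None
    minority_floor: float = 0.02
    tolerance: float = 1e-5
    max_steps: int = 200_000
    droplet_length: float | None = None
    slip_factor: float | None = None
    gap_cells: int = 1
    seed: int = 0
    raw: dict = field(default_factory=dict)

    @property
    def dims(self) -> int:
        return 3 if self.level == "3d" else 2


def _parse_fluid(d: dict, path: str) -> FluidSpec:
    density = float(_get(d, "density_kg_m3", path))
    cy = None
    visc = None
    if "carreau_yasuda" in d:
        c = d["carreau_yasuda"]
        p = f"{path}.carreau_yasuda"
        cy = CarreauYasudaParams(
            mu0=float(_get(c, "mu0_pa_s", p)),
            mu_inf=float(_get(c, "mu_inf_pa_s", p)),
            lam=float(_get(c, "lambda_s", p)),
            a=float(_get(c, "a", p)),
            n=float(_get(c, "n", p)),
        )
    if "viscosity_pa_s" in d:
        visc = float(d["viscosity_pa_s"])
    if (cy is None) == (visc is None):
        raise ConfigError(f"{path}: set exactly one of viscosity_pa_s / carreau_yasuda")
    return FluidSpec(
        density=density,
        viscosity=visc,
        carreau_yasuda=cy,
        diffusivity=_unit(d.get("diffusivity_um2_s", 0.0), "diffusivity_um2_s", path),
        surface_tension=float(d.get("surface_tension_n_m", 0.0)),
    )


def parse_config(data: dict, source: str = "<config>") -> ProblemConfig:
    """Validate a raw mapping and convert to SI."""
    if not isinstance(data, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    case = _get(data, "case", source)
    if case not in ("flow", "mix", "droplet"):
        raise ConfigError(f"{source}.case: must be flow, mix or droplet")
    level = _get(data, "level", source)
    if level not in ("1d", "2d", "3d"):
        raise ConfigError(f"{source}.level: must be 1d, 2d or 3d")

    g = _get(data, "geometry", source)
    gpath = f"{source}.geometry"
    h = _unit(g["height_um"], "height_um", gpath) if "height_um" in g else None
    if case == "droplet":
        geometry = BifurcationGeometry(
            l=_unit(_get(g, "length_um", gpath), "length_um", gpath),
            k=_unit(_get(g, "branch_length_um", gpath), "branch_length_um", gpath),
            w=_unit(_get(g, "width_um", gpath), "width_um", gpath),
            h=h,
            p_top=float(_get(data.get("driving", {}), "p_top_pa", f"{source}.driving")),
            p_bot=float(_get(data.get("driving", {}), "p_bot_pa", f"{source}.driving")),
            branch_from=g.get("branch_from", "junction"),
        )
    else:
        geometry = ChannelGeometry(
            l=_unit(_get(g, "length_um", gpath), "length_um", gpath),
            w=_unit(_get(g, "width_um", gpath), "width_um", gpath),
            h=h,
            x_m=_unit(_get(g, "measurement_line_um", gpath), "measurement_line_um", gpath),
        )
    if level == "3d" and h is None:
        raise ConfigError(f"{gpath}: height_um required for level 3d")

    fluid = _parse_fluid(_get(data, "fluid", source), f"{source}.fluid")
    drv = _get(data, "driving", source)
    u_in = _unit(_get(drv, "u_in_mm_s", f"{source}.driving"), "u_in_mm_s", f"{source}.driving")
    p_out = float(drv.get("p_out_pa", 0.0))

    disc = data.get("discretization", {})
    dx = _unit(disc.get("dx_um", 1.0), "dx_um", f"{source}.discretization")
    u_lat = float(disc.get("u_lat", 0.05))
    if not (0 < u_lat < U_LAT_MAX):
        raise ConfigError(
            f"{source}.discretization.u_lat: lattice speed {u_lat} violates the "
            f"compressibility guard (must be in (0, {U_LAT_MAX}))"
        )

    sol = data.get("solver", {})
    drop = data.get("droplet", {})
    cfg = ProblemConfig(
        case=case,
        level=level,
        geometry=geometry,
        fluid=fluid,
        u_in=u_in,
        p_out=p_out,
        dx=dx,
        u_lat_target=u_lat,
        shan_chen_g=float(sol["shan_chen_g"]) if "shan_chen_g" in sol else None,
        species_tau=float(sol["species_tau"]) if "species_tau" in sol else None,
        minority_floor=float(sol.get("minority_floor", 0.02)),
        tolerance=float(sol.get("tolerance", 1e-5)),
        max_steps=int(sol.get("max_steps", 200_000)),
        droplet_length=_unit(drop["length_um"], "length_um", f"{source}.droplet")
        if "length_um" in drop
        else None,
        slip_factor=float(drop.get("slip_factor", 1.28)),
        gap_cells=int(drop.get("gap_cells", 1)),
        seed=int(data.get("seed", 0)),
        raw=data,
    )
    # compressibility guard on the actual inlet speed
    scales = UnitScales(dx=cfg.dx, dt=cfg.u_lat_target * cfg.dx / cfg.u_in,
                        rho_ref=fluid.density)
    scales.validate(u_in=cfg.u_in)
    return cfg


def load_config(path) -> ProblemConfig:
    """Load and validate a JSON or YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return parse_config(data, source=path.name)


def builtin_config(case: str) -> ProblemConfig:
    """One of the three shipped use cases: 'flow', 'mix' or 'droplet'."""
    name = {"flow": "flow_blood.yaml", "mix": "mix_channel.yaml",
            "droplet": "droplet_bifurcation.yaml"}.get(case)
    if name is None:
        raise ValueError("case must be flow, mix or droplet")
    text = resources.files("mfsim").joinpath(f"configs/{name}").read_text()
    return parse_config(yaml.safe_load(text), source=name)
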