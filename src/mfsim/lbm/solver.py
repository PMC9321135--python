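"""Single-phase BGK lattice-Boltzmann solver.

One collide-and-stream update per step with link-wise boundary rules:
half-way bounce-back at walls, bounce-back with a momentum correction at
the velocity inlet, and anti-bounce-back on the density at pressure
outlets.  The relaxation time may be a field, recomputed every step from
the local shear rate through a Carreau–Yasuda law for shear-thinning runs.

All solver arithmetic is in lattice units (dx = dt = 1); a
:class:`~mfsim.units.UnitScales` converts at the interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..fluids import FluidSpec
from ..geometry import FLUID, INLET, OUTLET, OUTLET2, WALL
from ..units import CS2, UnitScales
from .lattice import LatticeDescriptor

TAU_EPS = 1e-6


def tau_from_viscosity(nu_lat) -> np.ndarray | float:
    """BGK relaxation time for a lattice kinematic viscosity: nu/cs^2 + 1/2."""
    return np.asarray(nu_lat) / CS2 + 0.5


def equilibrium(rho, u, lattice: LatticeDescriptor) -> np.ndarray:
    """Second-order truncated Maxwellian f_eq[i] on the whole grid.

    ``rho`` has the grid shape, ``u`` has shape (d, *grid).
    """
    c, w, cs2 = lattice.c, lattice.w, lattice.cs2
    usq = np.zeros_like(rho, dtype=float)
    for a in range(lattice.d):
        usq = usq + u[a] * u[a]
    feq = np.empty((lattice.q,) + np.shape(rho), dtype=float)
    for i in range(lattice.q):
        cu = np.zeros_like(usq)
        for a in range(lattice.d):
            if c[i, a]:
                cu = cu + c[i, a] * u[a]
        feq[i] = w[i] * rho * (1.0 + cu / cs2 + cu * cu / (2 * cs2**2) - usq / (2 * cs2))
    return feq


def macroscopic(f, lattice: LatticeDescriptor):
    """Zeroth and first moments: rho = sum_i f_i, u = sum_i c_i f_i / rho."""
    rho = f.sum(axis=0)
    u = np.zeros((lattice.d,) + rho.shape)
    for i in range(lattice.q):
        for a in range(lattice.d):
            if lattice.c[i, a]:
                u[a] += lattice.c[i, a] * f[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(rho > 0, u / rho, 0.0)
    return rho, u


@dataclass
class ConvergenceMonitor:
    """Windowed steady-state detector on a scalar (mean kinetic energy).

    Declares convergence when consecutive window averages differ by less
    than ``tol`` in relative terms.
    """

    window: int = 1000
    tol: float = 1e-5
    check_every: int = 50
    history: list = field(default_factory=list)
    _prev_avg: float | None = None
    _acc: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")

    def update(self, value: float) -> bool:
        """Feed one sample (taken every ``check_every`` steps); True = converged."""
        self.history.append(value)
        self._acc.append(value)
        if len(self._acc) * self.check_every < self.window:
            return False
        avg = float(np.mean(self._acc))
        self._acc = []
        prev, self._prev_avg = self._prev_avg, avg
        if prev is None:
            return False
        scale = max(abs(avg), abs(prev), 1e-300)
        return abs(avg - prev) / scale < self.tol


class _Links:
    """Precomputed link index lists between fluid cells and boundary cells."""

    def __init__(self, mask: np.ndarray, lattice: LatticeDescriptor) -> None:
        self.fluid = mask == FLUID
        self.wall = [None] * lattice.q
        self.inlet = [None] * lattice.q
        self.outlet = {}
        for i in range(lattice.q):
            if not lattice.c[i].any():
                continue
            shifted = np.roll(mask, tuple(-lattice.c[i]), axis=tuple(range(mask.ndim)))
            here = self.fluid
            self.wall[i] = np.nonzero(here & (shifted == WALL))
            self.inlet[i] = np.nonzero(here & (shifted == INLET))
            for code in (OUTLET, OUTLET2):
                links = np.nonzero(here & (shifted == code))
                if links[0].size:
                    self.outlet.setdefault(code, [None] * lattice.q)[i] = links


class SinglePhaseSim:
    """BGK solver for one fluid on a rasterized geometry.

    Parameters
    ----------
    mask : ndarray
        Cell-role grid from the geometry module.
    lattice : LatticeDescriptor
    scales : UnitScales
        SI <-> lattice mapping; also fixes the relaxation time through the
        fluid viscosity.
    fluid : FluidSpec
        Newtonian or Carreau–Yasuda fluid.
    u_in : float
        Mean inlet speed (SI, m/s), imposed as a uniform plug along +x.
    p_out : dict | float
        Outlet gauge pressure(s) (SI, Pa); a dict maps outlet role codes
        (OUTLET / OUTLET2) to pressures.
    """

    def __init__(
        self,
        mask: np.ndarray,
        lattice: LatticeDescriptor,
        scales: UnitScales,
        fluid: FluidSpec,
        u_in: float = 0.0,
        p_out=0.0,
        body_force=None,
        periodic: bool = False,
        tau_max: float = 3.0,
    ) -> None:
        if mask.ndim != lattice.d:
            raise ValueError("mask dimensionality does not match the lattice")
        self.mask = mask
        self.lattice = lattice
        self.scales = scales
        self.fluid = fluid
        self.periodic = periodic
        self.tau_max = tau_max
        self.links = None if periodic else _Links(mask, lattice)
        self.fluid_cells = mask == FLUID

        self.u_in_lat = scales.to_lattice(u_in, "velocity")
        if abs(self.u_in_lat) >= 0.1:
            raise ValueError(f"lattice inlet speed {self.u_in_lat:.3g} >= 0.1")
        if not isinstance(p_out, dict):
            p_out = {OUTLET: p_out, OUTLET2: p_out}
        # outlet density from the lattice equation of state p = cs^2 (rho - rho0)
        self.rho_out_lat = {
            code: 1.0 + scales.to_lattice(p, "pressure") / CS2
            for code, p in p_out.items()
        }
        self.body_force = (
            None
            if body_force is None
            else np.asarray(
                [scales.to_lattice(g, "acceleration") for g in body_force]
            )
        )

        nu_min, nu_max = fluid.nu_bounds()
        self.tau_min_nominal = float(tau_from_viscosity(scales.to_lattice(nu_min, "kinematic-viscosity")))
        tau0 = tau_from_viscosity(scales.to_lattice(nu_max, "kinematic-viscosity"))
        if not (0.5 < self.tau_min_nominal and tau0 <= tau_max + 1e-12):
            raise ValueError(
                f"relaxation time range [{self.tau_min_nominal:.4g}, {tau0:.4g}] "
                f"outside (0.5, {tau_max}]: adjust dt"
            )
        self.tau = np.full(mask.shape, float(tau0))
        self.non_newtonian = not fluid.is_newtonian
        self.step_count = 0
        self.f = None

    # -- setup -------------------------------------------------------------

    def initialize(self, rho=None, u=None) -> None:
        """Start from equilibrium at the given density/velocity fields.

        Defaults to unit density at rest; ``u`` is in lattice units and may
        be used to seed a pre-converged or analytically guessed flow.
        """
        shape = self.mask.shape
        rho = np.ones(shape) if rho is None else np.asarray(rho, dtype=float)
        if u is None:
            u = np.zeros((self.lattice.d,) + shape)
        self.f = equilibrium(rho, u, self.lattice)
        self.step_count = 0

    # -- per-step pieces ---------------------------------------------------

    def macroscopic(self):
        """Bare moments (rho, u) in lattice units.

        With a body force active the physical velocity is the bare moment
        plus half the acceleration; that correction is applied in
        :meth:`velocity_si`, not here.
        """
        rho, u = macroscopic(self.f, self.lattice)
        if np.any(rho[self.fluid_cells] <= 0):
            raise FloatingPointError("non-positive density on a fluid cell")
        return rho, u

    def update_tau(self, rho, u, feq=None) -> None:
        """Refresh the relaxation-time field from the local shear rate."""
        if not self.non_newtonian:
            return
        gdot_lat = self.strain_rate(rho, u, feq)
        gdot_si = gdot_lat / self.scales.dt
        nu_si = self.fluid.nu(gdot_si)
        nu_lat = nu_si * self.scales.dt / self.scales.dx**2
        tau = tau_from_viscosity(nu_lat)
        self.tau = np.clip(tau, 0.5 + TAU_EPS, self.tau_max)

    def strain_rate(self, rho=None, u=None, feq=None) -> np.ndarray:
        """Local shear-rate magnitude (lattice units, 1/step).

        Computed from the non-equilibrium populations:
        S_ab = -1/(2 rho cs^2 tau) * sum_i c_ia c_ib (f_i - feq_i),
        gdot = sqrt(2 S:S).  No finite differences are involved.
        """
        if rho is None or u is None:
            rho, u = self.macroscopic()
        if feq is None:
            feq = equilibrium(rho, u, self.lattice)
        fneq = self.f - feq
        d = self.lattice.d
        ssum = np.zeros(rho.shape)
        for a in range(d):
            for b in range(d):
                pi = np.zeros(rho.shape)
                for i in range(self.lattice.q):
                    ca, cb = self.lattice.c[i, a], self.lattice.c[i, b]
                    if ca and cb:
                        pi += ca * cb * fneq[i]
                with np.errstate(divide="ignore", invalid="ignore"):
                    s_ab = np.where(
                        rho > 0, -pi / (2.0 * rho * self.lattice.cs2 * self.tau), 0.0
                    )
                ssum += s_ab * s_ab
        return np.sqrt(2.0 * ssum)

    def collide(self, rho, u) -> np.ndarray:
        """BGK relaxation toward equilibrium; returns post-collision populations."""
        u_eq = u
        if self.body_force is not None:
            # velocity-shift forcing: equilibrium evaluated at u + tau * g
            u_eq = u.copy()
            for a in range(self.lattice.d):
                u_eq[a] = u[a] + self.tau * self.body_force[a]
        feq = equilibrium(rho, u_eq, self.lattice)
        return self.f - (self.f - feq) / self.tau, feq

    def stream_and_bound(self, fpost: np.ndarray, rho) -> None:
        """Propagate populations one cell and apply the boundary rules."""
        lat = self.lattice
        axes = tuple(range(self.mask.ndim))
        saved = None
        if not self.periodic:
            saved = []
            for i in range(lat.q):
                rec = {}
                if lat.c[i].any():
                    if self.links.wall[i][0].size:
                        rec["wall"] = fpost[i][self.links.wall[i]]
                    if self.links.inlet[i][0].size:
                        rec["inlet"] = (
                            fpost[i][self.links.inlet[i]],
                            rho[self.links.inlet[i]],
                        )
                    for code, per_dir in self.links.outlet.items():
                        if per_dir[i] is not None:
                            rec[code] = fpost[i][per_dir[i]]
                saved.append(rec)
        for i in range(lat.q):
            if lat.c[i].any():
                self.f[i] = np.roll(fpost[i], tuple(lat.c[i]), axis=axes)
            else:
                self.f[i] = fpost[i]
        if self.periodic:
            return
        cs2 = lat.cs2
        for i in range(lat.q):
            if not lat.c[i].any():
                continue
            io = lat.opp[i]
            rec = saved[i]
            if "wall" in rec:
                self.f[io][self.links.wall[i]] = rec["wall"]
            if "inlet" in rec:
                vals, rho_b = rec["inlet"]
                cu = float(lat.c[i, 0]) * self.u_in_lat  # plug along +x
                self.f[io][self.links.inlet[i]] = vals - 2.0 * lat.w[i] * rho_b * cu / cs2
            for code, per_dir in self.links.outlet.items():
                if per_dir[i] is None or code not in rec:
                    continue
                links = per_dir[i]
                rho_o = self.rho_out_lat[code]
                # anti-bounce-back on the density, second order in the
                # boundary velocity taken from the adjacent fluid cell
                ub = self._u_cache
                cu = np.zeros(links[0].shape)
                usq = np.zeros(links[0].shape)
                for a in range(lat.d):
                    ua = ub[a][links]
                    if lat.c[i, a]:
                        cu += lat.c[i, a] * ua
                    usq += ua * ua
                corr = 1.0 + cu * cu / (2 * cs2 * cs2) - usq / (2 * cs2)
                self.f[io][links] = -rec[code] + 2.0 * lat.w[i] * rho_o * corr

    # -- driver ------------------------------------------------------------

    def step(self) -> None:
        rho, u = self.macroscopic()
        self._u_cache = u
        fpost, feq = self.collide(rho, u)
        if self.non_newtonian:
            self.update_tau(rho, u, feq)
        self.stream_and_bound(fpost, rho)
        self.step_count += 1

    def check_health(self) -> None:
        if not np.all(np.isfinite(self.f[:, self.fluid_cells])):
            bad = np.argwhere(~np.isfinite(self.f).all(axis=0) & self.fluid_cells)
            raise FloatingPointError(
                f"non-finite populations, first at cell {tuple(bad[0])} "
                f"(step {self.step_count})"
            )

    def mean_kinetic_energy(self) -> float:
        rho, u = macroscopic(self.f, self.lattice)
        ke = 0.5 * rho * sum(u[a] ** 2 for a in range(self.lattice.d))
        return float(ke[self.fluid_cells].mean())

    def run_steady(
        self,
        monitor: ConvergenceMonitor | None = None,
        max_steps: int = 200_000,
        min_steps: int = 0,
    ) -> int:
        """Iterate to steady state; returns the number of steps taken.

        Raises ``RuntimeError`` when the step budget is exhausted and
        ``FloatingPointError`` on numerical blow-up.
        """
        if self.f is None:
            self.initialize()
        monitor = monitor or ConvergenceMonitor()
        while self.step_count < max_steps:
            self.step()
            if self.step_count % monitor.check_every == 0:
                self.check_health()
                if monitor.update(self.mean_kinetic_energy()) and self.step_count >= min_steps:
                    return self.step_count
        raise RuntimeError(f"no steady state within {max_steps} steps")

    # -- output ------------------------------------------------------------

    def velocity_si(self) -> np.ndarray:
        """Velocity field (d, *grid) in m/s, zero outside the fluid."""
        _, u = self.macroscopic()
        if self.body_force is not None:
            for a in range(self.lattice.d):
                u[a] += 0.5 * self.body_force[a]
        u = u * (self.scales.dx / self.scales.dt)
        u[:, ~self.fluid_cells] = 0.0
        return u

    def density_si(self) -> np.ndarray:
        rho, _ = self.macroscopic()
        return rho * self.scales.rho_ref

    def strain_rate_si(self) -> np.ndarray:
        return self.strain_rate() / self.scales.dt
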