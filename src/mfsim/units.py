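"""SI <-> lattice-unit conversion.

The lattice-Boltzmann solver works in nondimensional lattice units where the
cell spacing, the time step and a reference density are all 1.  A
:class:`UnitScales` instance fixes the three base scales (dx in metres per
cell, dt in seconds per step, rho_ref in kg/m^3 per lattice density unit);
every derived quantity converts through products of powers of those three.
"""

from __future__ import annotations

from dataclasses import dataclass

# exponents of (dx, dt, rho_ref) for each supported quantity kind
_KIND_EXPONENTS: dict[str, tuple[int, int, int]] = {
    "length": (1, 0, 0),
    "time": (0, 1, 0),
    "velocity": (1, -1, 0),
    "acceleration": (1, -2, 0),
    "density": (0, 0, 1),
    "kinematic-viscosity": (2, -1, 0),
    "dynamic-viscosity": (2, -1, 1),  # rho * nu
    "pressure": (2, -2, 1),
    "surface-tension": (3, -2, 1),
    "shear-rate": (0, -1, 0),
    "flow-rate-3d": (3, -1, 0),
    "flow-rate-2d": (2, -1, 0),
    "diffusivity": (2, -1, 0),
}

#: maximum admissible lattice velocity (weak-compressibility guard)
U_LAT_MAX = 0.1

#: admissible BGK relaxation-time interval (lattice units)
TAU_MIN, TAU_MAX = 0.5, 3.0

#: lattice speed of sound squared for the stencils used here
CS2 = 1.0 / 3.0


@dataclass(frozen=True)
class UnitScales:
    """Base scales linking SI quantities to lattice units.

    Parameters
    ----------
    dx : float
        Metres per lattice cell.
    dt : float
        Seconds per lattice step.
    rho_ref : float
        kg/m^3 per lattice density unit.
    """

    dx: float
    dt: float
    rho_ref: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("dx", "dt", "rho_ref"):
            if not getattr(self, name) > 0:
                raise ValueError(f"UnitScales.{name} must be positive")

    # -- generic conversion ------------------------------------------------

    def _factor(self, kind: str) -> float:
        try:
            a, b, c = _KIND_EXPONENTS[kind]
        except KeyError:
            raise ValueError(
                f"unknown quantity kind {kind!r}; known: {sorted(_KIND_EXPONENTS)}"
            ) from None
        return self.dx**a * self.dt**b * self.rho_ref**c

    def to_lattice(self, value: float, kind: str) -> float:
        """Convert an SI quantity to lattice units."""
        return value / self._factor(kind)

    def to_si(self, value: float, kind: str) -> float:
        """Convert a lattice quantity to SI."""
        return value * self._factor(kind)

    # -- convenience / validation -----------------------------------------

    def lattice_velocity(self, u_si: float) -> float:
        return self.to_lattice(u_si, "velocity")

    def tau_for(self, nu_si: float) -> float:
        """BGK relaxation time (lattice units) for a kinematic viscosity."""
        return 0.5 + self.to_lattice(nu_si, "kinematic-viscosity") / CS2

    def validate(self, u_in: float | None = None, nu: float | None = None) -> None:
        """Check the compressibility and relaxation-time guards.

        Raises ``ValueError`` if the converted inlet speed reaches
        :data:`U_LAT_MAX` or the relaxation time leaves ``(0.5, 3]``.
        """
        if u_in is not None:
            u_lat = abs(self.lattice_velocity(u_in))
            if u_lat >= U_LAT_MAX:
                raise ValueError(
                    f"lattice inlet speed {u_lat:.4g} >= {U_LAT_MAX} "
                    "(compressibility guard); decrease dt or the inlet velocity"
                )
        if nu is not None:
            tau = self.tau_for(nu)
            if not (TAU_MIN < tau <= TAU_MAX):
                raise ValueError(
                    f"relaxation time tau = {tau:.4g} outside ({TAU_MIN}, {TAU_MAX}]; "
                    "adjust dt or dx"
                )


def si_to_lattice(value: float, kind: str, scales: UnitScales) -> float:
    """Functional form of :meth:`UnitScales.to_lattice`."""
    return scales.to_lattice(value, kind)


def lattice_to_si(value: float, kind: str, scales: UnitScales) -> float:
    """Functional form of :meth:`UnitScales.to_si`."""
    return scales.to_si(value, kind)


def scales_for_velocity(
    dx: float, u_in: float, rho_ref: float = 1000.0, u_lat: float = 0.05
) -> UnitScales:
    """Pick dt so the inlet maps to a target lattice speed (default 0.05)."""
    if u_in <= 0:
        raise ValueError("u_in must be positive")
    return UnitScales(dx=dx, dt=u_lat * dx / u_in, rho_ref=rho_ref)


def scales_for_viscosity(
    dx: float, nu: float, rho_ref: float = 1000.0, tau: float = 1.0
) -> UnitScales:
    """Pick dt so the kinematic viscosity maps to a target relaxation time."""
    if not (TAU_MIN < tau <= TAU_MAX):
        raise ValueError(f"target tau must lie in ({TAU_MIN}, {TAU_MAX}]")
    nu_lat = CS2 * (tau - 0.5)
    return UnitScales(dx=dx, dt=nu_lat * dx**2 / nu, rho_ref=rho_ref)
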