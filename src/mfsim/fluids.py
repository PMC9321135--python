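"""Fluid property containers: rheology, diffusivity, surface tension.

A :class:`FluidSpec` carries either a Newtonian viscosity or the five
Carreau–Yasuda parameters (shear-thinning rheology, used here for blood),
plus the pair properties needed by the two-fluid use cases: the mutual
diffusivity of a miscible pair and the surface-tension coefficient of an
immiscible pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Carreau–Yasuda parameters for blood (whole blood, literature fit).
BLOOD_CY = None  # assigned below, after the class definition


@dataclass(frozen=True)
class CarreauYasudaParams:
    """Five-parameter shear-thinning viscosity law.

    mu_eff(gdot) = mu_inf + (mu0 - mu_inf) * (1 + (lam*gdot)^a)^((n-1)/a)

    Parameters
    ----------
    mu0, mu_inf : float
        Zero-shear and infinite-shear dynamic viscosities (Pa s).
    lam : float
        Relaxation time (s); 1/lam is the shear rate where thinning sets in.
    a, n : float
        Yasuda transition index and power-law index (dimensionless).
    """

    mu0: float
    mu_inf: float
    lam: float
    a: float
    n: float

    def __post_init__(self) -> None:
        if not (self.mu0 >= self.mu_inf > 0):
            raise ValueError("require mu0 >= mu_inf > 0")
        if self.lam < 0:
            raise ValueError("relaxation time lam must be >= 0")
        if self.a <= 0:
            raise ValueError("Yasuda index a must be positive")

    def viscosity(self, gamma_dot):
        """Effective viscosity (Pa s) at shear rate(s) ``gamma_dot`` (1/s)."""
        g = np.asarray(gamma_dot, dtype=float)
        if np.any(g < 0):
            raise ValueError("shear rate must be non-negative")
        mu = self.mu_inf + (self.mu0 - self.mu_inf) * (
            1.0 + (self.lam * g) ** self.a
        ) ** ((self.n - 1.0) / self.a)
        return float(mu) if np.isscalar(gamma_dot) else mu

    def newtonian(self) -> bool:
        return math.isclose(self.mu0, self.mu_inf)


BLOOD_CY = CarreauYasudaParams(mu0=22e-3, mu_inf=2.2e-3, lam=0.110, a=0.644, n=0.392)

#: density of blood used in the channel-flow use case (kg/m^3)
BLOOD_DENSITY = 1060.0


@dataclass(frozen=True)
class FluidSpec:
    """Density plus exactly one rheology variant, and optional pair properties.

    Parameters
    ----------
    density : float
        kg/m^3.
    viscosity : float, optional
        Newtonian dynamic viscosity (Pa s).  Mutually exclusive with
        ``carreau_yasuda``.
    carreau_yasuda : CarreauYasudaParams, optional
        Shear-thinning rheology.  Mutually exclusive with ``viscosity``.
    diffusivity : float, optional
        Mutual diffusivity D of a miscible fluid pair (m^2/s).
    surface_tension : float, optional
        Surface-tension coefficient gamma of an immiscible pair (N/m).
    """

    density: float
    viscosity: float | None = None
    carreau_yasuda: CarreauYasudaParams | None = None
    diffusivity: float = 0.0
    surface_tension: float = 0.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if (self.viscosity is None) == (self.carreau_yasuda is None):
            raise ValueError("set exactly one of viscosity / carreau_yasuda")
        if self.viscosity is not None and self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.diffusivity < 0:
            raise ValueError("diffusivity must be >= 0")
        if self.surface_tension < 0:
            raise ValueError("surface tension must be >= 0")

    @property
    def is_newtonian(self) -> bool:
        return self.viscosity is not None or self.carreau_yasuda.newtonian()

    def mu(self, gamma_dot=0.0):
        """Dynamic viscosity at a shear rate (constant if Newtonian)."""
        if self.viscosity is not None:
            if np.isscalar(gamma_dot):
                return self.viscosity
            return np.full_like(np.asarray(gamma_dot, dtype=float), self.viscosity)
        return self.carreau_yasuda.viscosity(gamma_dot)

    def nu(self, gamma_dot=0.0):
        """Kinematic viscosity at a shear rate (m^2/s)."""
        return self.mu(gamma_dot) / self.density

    def nu_bounds(self) -> tuple[float, float]:
        """(min, max) kinematic viscosity over all shear rates."""
        if self.viscosity is not None:
            nu = self.viscosity / self.density
            return nu, nu
        p = self.carreau_yasuda
        return p.mu_inf / self.density, p.mu0 / self.density


@dataclass(frozen=True)
class DrivingConditions:
    """Inlet/outlet driving of a straight-channel problem.

    Exactly one of ``u_in`` (mean inlet velocity, m/s) or ``dp`` (applied
    pressure difference, Pa) must be set; ``p_out`` is the outlet gauge
    pressure (Pa).
    """

    u_in: float | None = None
    dp: float | None = None
    p_out: float = 0.0

    def __post_init__(self) -> None:
        if (self.u_in is None) == (self.dp is None):
            raise ValueError("set exactly one of u_in / dp")
        for v in (self.u_in, self.dp, self.p_out):
            if v is not None and not math.isfinite(v):
                raise ValueError("driving conditions must be finite")
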