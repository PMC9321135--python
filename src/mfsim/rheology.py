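"""Semi-analytic shear-thinning channel profiles (Carreau–Yasuda).

Between parallel plates the shear stress varies linearly across the gap,
vanishing on the centerline.  For a generalized-Newtonian fluid the local
shear rate therefore solves the scalar balance

    gdot * mu_eff(gdot) = tau_s(z),   tau_s(z) = (dp/l) * (w/2 - z),

with ``z`` measured from a wall.  The velocity profile follows by
quadrature of the shear rate from the wall to the centerline.  The balance
is solved per point with damped Newton iteration and a guaranteed-bracket
bisection fallback (the left-hand side is strictly increasing in gdot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_simpson, simpson
from scipy.optimize import brentq

from .fluids import CarreauYasudaParams
from .geometry import ChannelGeometry


@dataclass(frozen=True)
class VelocityProfile:
    """Sampled cross-channel velocity profile.

    ``z`` runs from one wall (0) to the other (w), in metres; ``u`` is the
    streamwise velocity at those positions (m/s), zero at both walls.
    """

    z: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        z, u = np.asarray(self.z), np.asarray(self.u)
        if z.shape != u.shape or z.ndim != 1:
            raise ValueError("z and u must be 1D arrays of equal length")
        if np.any(np.diff(z) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(u)):
            raise ValueError("velocities must be finite")

    @property
    def u_max(self) -> float:
        return float(np.max(self.u))

    @property
    def u_mean(self) -> float:
        """Cross-sectional mean velocity (integral average)."""
        return float(simpson(self.u, x=self.z) / (self.z[-1] - self.z[0]))

    @property
    def flatness(self) -> float:
        """u_max / u_mean: 1.5 for a parabola, -> 1 for plug flow."""
        return self.u_max / self.u_mean


def carreau_yasuda_viscosity(gamma_dot, params: CarreauYasudaParams):
    """Effective viscosity mu_eff (Pa s) at shear rate(s) (1/s)."""
    return params.viscosity(gamma_dot)


def local_shear_rate(
    tau_s: float,
    params: CarreauYasudaParams,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> float:
    """Shear rate satisfying gdot * mu_eff(gdot) = tau_s for stress tau_s >= 0.

    Newton iteration from gdot0 = tau_s/mu0 with bisection fallback on the
    bracket [0, tau_s/mu_inf] (mu_inf <= mu_eff <= mu0 guarantees the root
    lies there and is unique).
    """
    if tau_s < 0:
        raise ValueError("shear stress magnitude must be >= 0")
    if tau_s == 0.0:
        return 0.0
    mu0, mu_inf, lam, a, n = params.mu0, params.mu_inf, params.lam, params.a, params.n
    dmu = mu0 - mu_inf

    def g(gd: float) -> float:
        return gd * params.viscosity(gd) - tau_s

    def gprime(gd: float) -> float:
        t = (lam * gd) ** a
        mu = mu_inf + dmu * (1.0 + t) ** ((n - 1.0) / a)
        dmu_dgd = dmu * (n - 1.0) * (1.0 + t) ** ((n - 1.0 - a) / a) * t / max(gd, 1e-300)
        return mu + gd * dmu_dgd

    hi = tau_s / mu_inf
    gd = tau_s / mu0
    for _ in range(max_iter):
        r = g(gd)
        if abs(r) <= tol * tau_s:  # residual tolerance relative to the stress
            return gd
        step = r / gprime(gd)
        gd_new = gd - step
        if not (0.0 < gd_new <= hi * 1.0000001):
            break  # Newton left the admissible bracket
        if abs(step) <= 1e-16 * gd:
            return gd_new
        gd = gd_new
    # bisection fallback on the guaranteed bracket
    if g(hi) < 0:  # numerically impossible unless tau_s ~ overflow
        raise RuntimeError("shear-rate bracket invalid")
    return brentq(g, 0.0, hi, xtol=1e-300, rtol=1e-14)


def shear_stress(z, dp: float, l: float, w: float, literal: bool = False):
    """Shear-stress magnitude at distance z from the nearest wall.

    The default is the momentum balance (dp/l)(w/2 - z), zero on the
    centerline.  ``literal=True`` evaluates z*dp/l instead — the published
    formula taken verbatim — which places zero stress at the wall and is
    kept only for inspection.
    """
    z = np.asarray(z, dtype=float)
    if literal:
        return z * dp / l
    return (dp / l) * (w / 2.0 - z)


def velocity_profile_cy(
    geom: ChannelGeometry,
    dp: float,
    params: CarreauYasudaParams,
    n_points: int = 1001,
    tol: float = 1e-10,
    literal_stress: bool = False,
) -> VelocityProfile:
    """Cross-channel velocity profile for a Carreau–Yasuda fluid.

    Integrates the local shear rate from the wall to the centerline with
    composite Simpson quadrature on ``n_points`` (odd, >= 3) samples across
    the full width and mirrors the half profile about the centerline.
    """
    if n_points < 3 or n_points % 2 == 0:
        raise ValueError("n_points must be odd and >= 3")
    w = geom.w
    n_half = (n_points + 1) // 2
    z_half = np.linspace(0.0, w / 2.0, n_half)
    tau = np.abs(shear_stress(z_half, dp, geom.l, w, literal=literal_stress))
    gd = np.array([local_shear_rate(t, params, tol=tol) for t in tau])
    u_half = cumulative_simpson(gd, x=z_half, initial=0.0)
    z = np.concatenate([z_half, w - z_half[-2::-1]])
    u = np.concatenate([u_half, u_half[-2::-1]])
    return VelocityProfile(z=z, u=u)


def newtonian_dp_for_mean(u_mean: float, mu: float, l: float, w: float) -> float:
    """Plane-Poiseuille pressure drop giving a prescribed mean velocity."""
    return 12.0 * mu * l * u_mean / w**2


def profile_for_mean_velocity(
    geom: ChannelGeometry,
    u_in: float,
    params: CarreauYasudaParams,
    n_points: int = 1001,
    rtol: float = 1e-6,
) -> tuple[float, VelocityProfile]:
    """Invert the dp -> mean-velocity map for an inlet-driven channel.

    The mean velocity grows monotonically with dp, and for a shear-thinning
    fluid the required dp is bracketed by the Newtonian drops evaluated at
    mu_inf and mu0.  Returns ``(dp, profile)`` with the profile mean within
    ``rtol`` of ``u_in``.
    """
    if u_in <= 0:
        raise ValueError("u_in must be positive")

    def mean_for(dp: float) -> float:
        return velocity_profile_cy(geom, dp, params, n_points=n_points).u_mean

    lo = newtonian_dp_for_mean(u_in, params.mu_inf, geom.l, geom.w)
    hi = newtonian_dp_for_mean(u_in, params.mu0, geom.l, geom.w)
    # guard against degenerate (Newtonian) parameter sets
    f_lo, f_hi = mean_for(lo) - u_in, mean_for(hi) - u_in
    grow = 0
    while f_lo > 0 and grow < 60:  # expand downwards if needed
        lo *= 0.5
        f_lo = mean_for(lo) - u_in
        grow += 1
    while f_hi < 0 and grow < 120:
        hi *= 2.0
        f_hi = mean_for(hi) - u_in
        grow += 1
    if f_lo > 0 or f_hi < 0:
        raise RuntimeError("failed to bracket the pressure drop")
    dp = brentq(lambda p: mean_for(p) - u_in, lo, hi, rtol=rtol)
    return dp, velocity_profile_cy(geom, dp, params, n_points=n_points)
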