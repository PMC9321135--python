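"""Advection–diffusion mixing of two miscible streams in a straight channel.

Two fluids enter side by side (concentration 1 in one half of the inlet, 0
in the other).  With uniform advection u along x and diffusion D across the
width w, the depth-averaged concentration obeys

    d^2 c / dy^2 = Pe * dc/dx~ ,   Pe = u w / D,  x~ = x/w,

with no-flux walls.  Measuring the cross coordinate from the channel
centerline (y in [-1/2, 1/2], interface at y=0) the solution is the odd
sine series

    c = 1/2 + (2/pi) * sum_{k odd} exp(-pi^2 k^2 x~ / Pe) sin(pi k y) / k,

whose odd-k modes have zero gradient at the walls.  The series is summed
until the next term's amplitude falls below a tail tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ChannelGeometry


@dataclass(frozen=True)
class ConcentrationProfile:
    """Cross-channel concentration samples at one axial station.

    ``y`` is the dimensionless cross coordinate in [0, 1] (wall to wall),
    ``alpha`` the concentration of the stream that entered at 1, and ``x``
    the axial station in metres.
    """

    y: np.ndarray
    alpha: np.ndarray
    x: float

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha)
        if np.any(a < -1e-9) or np.any(a > 1 + 1e-9):
            raise ValueError("concentrations must lie in [0, 1]")


def mixing_concentration(
    x_tilde,
    y,
    Pe: float,
    n_max: int = 100_000,
    tail_tol: float = 1e-12,
):
    """Series solution c(x~, y) with y measured from the centerline.

    Parameters
    ----------
    x_tilde : float or array
        Axial coordinate in channel widths, x/w.
    y : float or array
        Cross coordinate from the centerline, in [-1/2, 1/2].
    Pe : float
        Peclet number u*w/D.
    n_max : int
        Hard cap on the number of series terms.
    tail_tol : float
        Terms are added until the next amplitude falls below this.
    """
    if Pe <= 0:
        raise ValueError("Peclet number must be positive")
    if tail_tol <= 0:
        raise ValueError("tail_tol must be positive")
    xt = np.asarray(x_tilde, dtype=float)
    yy = np.asarray(y, dtype=float)
    if np.any(yy < -0.5 - 1e-12) or np.any(yy > 0.5 + 1e-12):
        raise ValueError("cross coordinate must lie in [-1/2, 1/2]")
    c = np.full(np.broadcast(xt, yy).shape, 0.5)
    xmin = float(np.min(xt))
    k = 1
    while k <= 2 * n_max:
        amp = (2.0 / np.pi) * np.exp(-np.pi**2 * k**2 * xmin / Pe) / k
        if amp < tail_tol:
            break
        c = c + (2.0 / np.pi) / k * np.exp(-np.pi**2 * k**2 * xt / Pe) * np.sin(
            np.pi * k * yy
        )
        k += 2
    if c.ndim == 0:
        return float(c)
    return c


def mixing_profile_at_line(
    geom: ChannelGeometry,
    u_in: float,
    D: float,
    n_points: int | None = None,
    dx: float | None = None,
    tail_tol: float = 1e-12,
) -> ConcentrationProfile:
    """Concentration profile at the measurement line of a mixing channel.

    Samples the series solution at ``n_points`` cell-center positions
    across the width (default: one per grid cell of spacing ``dx``, or 40).
    """
    if D <= 0:
        raise ValueError("diffusivity must be positive")
    if geom.x_m is None:
        raise ValueError("geometry has no measurement line")
    if n_points is None:
        n_points = int(round(geom.w / dx)) if dx else 40
    Pe = u_in * geom.w / D
    y01 = (np.arange(n_points) + 0.5) / n_points  # cell centers, wall to wall
    y_c = y01 - 0.5
    alpha = mixing_concentration(geom.x_m / geom.w, y_c, Pe, tail_tol=tail_tol)
    # off the inlet discontinuity the series lies in [0, 1]; only truncation
    # residue of order tail_tol may poke out, which is asserted, not clamped
    slack = 10.0 * tail_tol
    if np.any(alpha < -slack) or np.any(alpha > 1.0 + slack):
        raise AssertionError("series value left [0, 1] beyond truncation residue")
    return ConcentrationProfile(
        y=y01, alpha=np.clip(alpha, 0.0, 1.0), x=geom.x_m
    )


def diffusion_distance(D: float, t: float) -> float:
    """Typical diffusion distance d = 2 sqrt(D t) (m)."""
    if D < 0 or t < 0:
        raise ValueError("diffusivity and time must be >= 0")
    return 2.0 * np.sqrt(D * t)
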