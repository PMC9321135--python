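"""Pressure-driven laminar flow in rectangular ducts and between plates.

The duct flow rate uses the classical series solution for a rectangular
cross-section (width ``w``, height ``h``); its odd-``n`` series converges so
fast that two terms already carry a truncation error of order 1e-4 for a
square duct.  The parallel-plate (2D) forms are the ``w/h -> 0`` limit and
are used when comparing against the two-dimensional lattice solver.
"""

from __future__ import annotations

import numpy as np

from .geometry import ChannelGeometry


def rect_correction_factor(w: float, h: float, n_terms: int = 2) -> float:
    """Bracketed series factor of the rectangular-duct flow rate.

    ``1 - (h/w)(192/pi^5) * sum_{n odd} tanh(n pi w / (2h)) / n^5`` with the
    sum truncated after ``n_terms`` odd terms.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    n = np.arange(1, 2 * n_terms, 2, dtype=float)
    s = np.sum(np.tanh(n * np.pi * w / (2.0 * h)) / n**5)
    return 1.0 - (h / w) * (192.0 / np.pi**5) * s


def rect_channel_flow_rate(
    geom: ChannelGeometry, dp: float, mu: float, n_terms: int = 2
) -> float:
    """Volumetric flow rate Q (m^3/s) of a rectangular duct under dp (Pa)."""
    if mu <= 0:
        raise ValueError("viscosity must be positive")
    if geom.h is None:
        raise ValueError("duct flow rate requires a channel height h")
    w, h = geom.w, geom.h
    return w * h**3 * dp / (12.0 * mu * geom.l) * rect_correction_factor(w, h, n_terms)


def plate_flow_rate(geom: ChannelGeometry, dp: float, mu: float) -> float:
    """Plane-Poiseuille flow rate per unit depth (m^2/s) between plates."""
    if mu <= 0:
        raise ValueError("viscosity must be positive")
    return geom.w**3 * dp / (12.0 * mu * geom.l)


def hydraulic_resistance(
    geom: ChannelGeometry, mu: float, n_terms: int = 2, dims: int = 3
) -> float:
    """Hydraulic resistance R = dp/Q of a channel segment.

    ``dims=3`` gives the duct resistance (Pa s/m^3); ``dims=2`` the
    parallel-plate resistance per unit depth (Pa s/m^2), used when the 1D
    network mirrors a two-dimensional solver.
    """
    if dims == 3:
        return 1.0 / rect_channel_flow_rate(geom, 1.0, mu, n_terms)
    if dims == 2:
        return 1.0 / plate_flow_rate(geom, 1.0, mu)
    raise ValueError("dims must be 2 or 3")
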