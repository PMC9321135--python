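"""Channel and bifurcation geometries and their cell-role rasterization.

Geometries are axis-aligned: the main channel runs along +x, the cross
coordinate is y (and z in 3D).  Rasterization produces a dense integer mask
one ghost cell larger than the fluid region on every side; the physical
walls sit half-way between the outermost fluid cells and the ghost wall
cells (half-way bounce-back convention), so a channel of width ``w``
contains exactly ``w/dx`` fluid cells across.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import UnitScales

# cell-role codes
FLUID, WALL, INLET, OUTLET, OUTLET2 = 0, 1, 2, 3, 4

ROLE_NAMES = {FLUID: "fluid", WALL: "wall", INLET: "inlet", OUTLET: "outlet", OUTLET2: "outlet2"}


def _cells(extent: float, dx: float, axis: str) -> int:
    n = extent / dx
    if abs(n - round(n)) > 1e-6:
        raise ValueError(
            f"extent along {axis} ({extent} m) is not an integer multiple of dx={dx} m"
        )
    n = int(round(n))
    if n < 1:
        raise ValueError(f"extent along {axis} must cover at least one cell")
    return n


@dataclass(frozen=True)
class ChannelGeometry:
    """Straight rectangular channel.

    Parameters
    ----------
    l, w : float
        Length and width (m).
    h : float, optional
        Height (m); omit for 2D problems.
    x_m : float, optional
        Measurement-line position, distance downstream of the inlet (m).
    """

    l: float
    w: float
    h: float | None = None
    x_m: float | None = None

    def __post_init__(self) -> None:
        if self.l <= 0 or self.w <= 0:
            raise ValueError("channel length and width must be positive")
        if self.h is not None and self.h <= 0:
            raise ValueError("channel height must be positive")
        if self.x_m is not None and not (0 < self.x_m <= self.l):
            raise ValueError("measurement line must satisfy 0 < x_m <= l")

    def measurement_column(self, dx: float) -> int:
        """0-based fluid-cell column whose center is nearest x_m."""
        if self.x_m is None:
            raise ValueError("geometry has no measurement line")
        nx = _cells(self.l, dx, "l")
        return min(nx - 1, max(0, int(round(self.x_m / dx - 0.5))))


@dataclass(frozen=True)
class BifurcationGeometry:
    """T-junction: an inlet channel feeding two perpendicular branches.

    The inlet channel (length ``l``, width ``w``) runs along +x and ends in
    a ``w`` x ``w`` junction from which two branches of length ``k`` extend
    in +y and -y.  Each branch ends in its own pressure outlet
    (``p_top``/``p_bot``).  With ``branch_from="axis"`` the outlets sit a
    distance ``k`` from the channel axis instead of ``k`` beyond the
    junction (the two readings of the published figure).
    """

    l: float
    k: float
    w: float
    h: float | None = None
    p_top: float = 0.0
    p_bot: float = 0.0
    branch_from: str = "junction"

    def __post_init__(self) -> None:
        if self.l <= 0 or self.k <= 0 or self.w <= 0:
            raise ValueError("bifurcation l, k, w must all be positive")
        if self.h is not None and self.h <= 0:
            raise ValueError("height must be positive")
        for p in (self.p_top, self.p_bot):
            if not np.isfinite(p):
                raise ValueError("outlet pressures must be finite")
        if self.branch_from not in ("junction", "axis"):
            raise ValueError("branch_from must be 'junction' or 'axis'")

    def branch_cells(self, dx: float) -> int:
        """Fluid cells a branch extends beyond the junction square."""
        nk = _cells(self.k, dx, "k")
        if self.branch_from == "axis":
            nk -= _cells(self.w, dx, "w") // 2
            if nk < 1:
                raise ValueError("branch length k too short for branch_from='axis'")
        return nk


def build_channel_mask(
    geom: ChannelGeometry, scales: UnitScales, dims: int = 2
) -> np.ndarray:
    """Rasterize a straight channel into a cell-role mask.

    Returns an int8 array of shape ``(nx+2, ny+2[, nz+2])``: interior fluid
    cells, a full-face inlet column at low x, a full-face outlet column at
    high x, walls everywhere else on the one-cell ghost ring.
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    dx = scales.dx
    nx, ny = _cells(geom.l, dx, "l"), _cells(geom.w, dx, "w")
    if dims == 3:
        if geom.h is None:
            raise ValueError("3D rasterization requires a channel height h")
        nz = _cells(geom.h, dx, "h")
        mask = np.full((nx + 2, ny + 2, nz + 2), WALL, dtype=np.int8)
        mask[1:-1, 1:-1, 1:-1] = FLUID
        mask[0, 1:-1, 1:-1] = INLET
        mask[-1, 1:-1, 1:-1] = OUTLET
    else:
        mask = np.full((nx + 2, ny + 2), WALL, dtype=np.int8)
        mask[1:-1, 1:-1] = FLUID
        mask[0, 1:-1] = INLET
        mask[-1, 1:-1] = OUTLET
    return mask


def build_bifurcation_mask(
    geom: BifurcationGeometry, scales: UnitScales, dims: int = 2
) -> np.ndarray:
    """Rasterize a T-junction into a cell-role mask.

    The two branch outlets carry distinct labels (top: ``OUTLET``, bottom:
    ``OUTLET2``) so each can be driven by its own pressure.
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    dx = scales.dx
    nl, nw = _cells(geom.l, dx, "l"), _cells(geom.w, dx, "w")
    nk = geom.branch_cells(dx)

    nx = nl + nw  # inlet channel + junction square
    ny = nw + 2 * nk  # branch spans above and below the channel
    shape2 = (nx + 2, ny + 2)

    mask = np.full(shape2, WALL, dtype=np.int8)
    ylo = 1 + nk  # first cross-channel fluid row of the inlet channel
    yhi = ylo + nw
    # inlet channel
    mask[1 : 1 + nl, ylo:yhi] = FLUID
    # junction square and branches
    mask[1 + nl : 1 + nl + nw, 1:-1] = FLUID
    # faces
    mask[0, ylo:yhi] = INLET
    mask[1 + nl : 1 + nl + nw, -1] = OUTLET  # top branch outlet (+y)
    mask[1 + nl : 1 + nl + nw, 0] = OUTLET2  # bottom branch outlet (-y)

    if dims == 3:
        if geom.h is None:
            raise ValueError("3D rasterization requires a height h")
        nz = _cells(geom.h, dx, "h")
        m3 = np.full(shape2 + (nz + 2,), WALL, dtype=np.int8)
        m3[:, :, 1:-1] = mask[:, :, None]
        return m3
    return mask


def fluid_shape(mask: np.ndarray) -> tuple[int, ...]:
    """Shape of the interior (ghost ring stripped)."""
    return tuple(n - 2 for n in mask.shape)


def check_mask(mask: np.ndarray) -> None:
    """Validate structural invariants of a cell-role mask.

    Every fluid cell must be reachable from an inlet cell by face
    adjacency, and roles must partition the grid.
    """
    roles = np.unique(mask)
    if not set(roles.tolist()) <= {FLUID, WALL, INLET, OUTLET, OUTLET2}:
        raise ValueError("mask contains unknown role codes")
    if not (mask == INLET).any() or not (mask == OUTLET).any():
        raise ValueError("mask must contain at least one inlet and one outlet cell")
    # flood fill from cells adjacent to the inlet face
    fluid = mask == FLUID
    reach = np.zeros_like(fluid)
    seeds = np.zeros_like(fluid)
    for axis in range(mask.ndim):
        for shift in (1, -1):
            seeds |= np.roll(mask == INLET, shift, axis=axis)
    reach = seeds & fluid
    while True:
        grow = reach.copy()
        for axis in range(mask.ndim):
            for shift in (1, -1):
                grow |= np.roll(reach, shift, axis=axis)
        grow &= fluid
        if (grow == reach).all():
            break
        reach = grow
    if not (reach == fluid).all():
        raise ValueError("mask has fluid cells unreachable from the inlet")
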