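"""1D droplet transport through a bifurcation.

The droplet is reduced to a slug of length ``dl`` whose trailing edge moves
along the center path at the slip-corrected mean carrier speed
``u_d = alpha * Q / A`` of the segment currently containing it; corners are
taken at constant speed.  The branch taken is the one carrying the larger
outward flow.  Shape, deformation and stability are outside this
abstraction level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BifurcationGeometry
from .network import NetworkSolution


def laplace_pressure(gamma: float, r: float) -> float:
    """Interfacial pressure jump 2*gamma/r across a droplet of radius r."""
    if r <= 0:
        raise ValueError("droplet radius must be positive")
    if gamma < 0:
        raise ValueError("surface tension must be >= 0")
    return 2.0 * gamma / r


@dataclass(frozen=True)
class DropletTrajectory:
    """Trailing-edge kinematics along the center path.

    ``t`` are the sample times (s), ``s`` the trailing-edge arc length along
    the path (m), ``dl`` the (undeformed) droplet length mapped ahead of the
    trailing edge, and ``branch`` the branch label taken at the junction.
    """

    t: np.ndarray
    s: np.ndarray
    dl: float
    branch: str
    segments: tuple[tuple[float, float], ...]  # (end arc length, speed)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.s) < -1e-15):
            raise ValueError("trailing-edge position must be non-decreasing")

    def time_to(self, s_target: float) -> float:
        """Time at which the trailing edge reaches an arc-length position."""
        if s_target < self.s[0]:
            raise ValueError("target lies behind the initial position")
        t, s_prev = 0.0, self.s[0]
        for s_end, speed in self.segments:
            seg_end = min(s_end, s_target)
            if seg_end > s_prev:
                t += (seg_end - s_prev) / speed
                s_prev = seg_end
            if s_prev >= s_target:
                return t
        raise ValueError("target lies beyond the path")


def droplet_trajectory(
    geom: BifurcationGeometry,
    sol: NetworkSolution,
    alpha: float,
    dl: float,
    t_samples: np.ndarray,
    u_in: float,
    s0: float = 0.0,
    tie_break: str = "top",
) -> DropletTrajectory:
    """Piecewise-linear trailing-edge trajectory through the T-junction.

    Speeds: ``alpha * u_in`` until the junction center, then
    ``alpha * |Q_branch| / A`` in the chosen branch (``Q_branch`` from the
    solved network, branch = larger outward flow, ties broken per
    ``tie_break``).
    """
    if alpha <= 0:
        raise ValueError("slip factor must be positive")
    if dl < 0:
        raise ValueError("droplet length must be >= 0")
    q_top, q_bot = sol.edge_flow("top"), sol.edge_flow("bot")
    scale = max(abs(q_top), abs(q_bot), 1e-300)
    if abs(q_top - q_bot) <= 1e-9 * scale:
        branch = tie_break
    else:
        branch = "top" if q_top > q_bot else "bot"
    q_branch = q_top if branch == "top" else q_bot
    # mean branch velocity: network flows and u_in share the same area norm
    q_in = sol.edge_flow("inlet")
    u_branch = u_in * q_branch / q_in

    half_w = geom.w / 2.0
    k_beyond = geom.k if geom.branch_from == "junction" else geom.k - half_w
    seg1_end = geom.l + half_w  # junction center
    total = seg1_end + half_w + k_beyond  # to the branch outlet
    segments = ((seg1_end, alpha * u_in), (total, alpha * abs(u_branch)))

    t = np.asarray(t_samples, dtype=float)
    if np.any(t < 0):
        raise ValueError("sample times must be >= 0")
    s = np.empty_like(t)
    t1 = (seg1_end - s0) / (alpha * u_in)  # time to reach the junction center
    early = t <= t1
    s[early] = s0 + alpha * u_in * t[early]
    s[~early] = seg1_end + alpha * abs(u_branch) * (t[~early] - t1)
    if np.any(s + dl > total + 1e-12):
        raise ValueError("droplet leading edge leaves the path at the sampled times")
    return DropletTrajectory(t=t, s=s, dl=dl, branch=branch, segments=segments)
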