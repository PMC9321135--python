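"""Hydraulic-resistance network analysis (the electrical-circuit analogy).

Channel segments act as resistors (R = dp/Q), junctions as nodes; imposing
Kirchhoff's current law at every junction yields a linear system in the
unknown node pressures.  Boundary nodes carry either a fixed pressure or a
fixed inflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ChannelGeometry
from .poiseuille import hydraulic_resistance


@dataclass(frozen=True)
class Edge:
    a: str
    b: str
    R: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("edge resistance must be positive")


@dataclass
class HydraulicNetwork:
    """Nodes, resistive edges, and boundary conditions.

    ``fixed_pressure`` maps node -> pressure (Pa); ``inflow`` maps
    node -> imposed external inflow (positive into the node; units must be
    consistent with the resistances: m^3/s against Pa s/m^3, or m^2/s
    against plate resistances).
    """

    edges: list[Edge] = field(default_factory=list)
    fixed_pressure: dict[str, float] = field(default_factory=dict)
    inflow: dict[str, float] = field(default_factory=dict)

    def add_edge(self, a: str, b: str, R: float, label: str = "") -> None:
        self.edges.append(Edge(a, b, R, label))

    def add_channel(
        self, a: str, b: str, geom: ChannelGeometry, mu: float,
        dims: int = 3, label: str = "",
    ) -> None:
        self.add_edge(a, b, hydraulic_resistance(geom, mu, dims=dims), label)

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.a)
            seen.setdefault(e.b)
        for n in list(self.fixed_pressure) + list(self.inflow):
            seen.setdefault(n)
        return list(seen)


@dataclass(frozen=True)
class NetworkSolution:
    pressures: dict[str, float]
    flows: dict[str, float]  # edge label (or "a->b") -> flow from a to b

    def edge_flow(self, label: str) -> float:
        return self.flows[label]


def solve_network(net: HydraulicNetwork) -> NetworkSolution:
    """Solve node pressures and edge flows by nodal analysis.

    Raises ``ValueError`` for an ill-posed network (no fixed-pressure node,
    or a floating subnetwork making the system singular).
    """
    if not net.edges:
        raise ValueError("network has no edges")
    if not net.fixed_pressure:
        raise ValueError("ill-posed: at least one fixed-pressure node required")
    nodes = net.nodes
    unknown = [n for n in nodes if n not in net.fixed_pressure]
    idx = {n: i for i, n in enumerate(unknown)}
    m = len(unknown)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for n in unknown:
        b[idx[n]] += net.inflow.get(n, 0.0)
    for e in net.edges:
        g = 1.0 / e.R
        for x, y in ((e.a, e.b), (e.b, e.a)):
            if x in idx:
                A[idx[x], idx[x]] += g
                if y in idx:
                    A[idx[x], idx[y]] -= g
                else:
                    b[idx[x]] += g * net.fixed_pressure[y]
    pressures = dict(net.fixed_pressure)
    if m:
        try:
            p = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"ill-posed network: {err}") from None
        if not np.all(np.isfinite(p)):
            raise ValueError("ill-posed network: singular system")
        # singular-but-consistent systems slip through solve on some BLAS
        if np.linalg.cond(A) > 1e14:
            raise ValueError("ill-posed network: floating subnetwork")
        pressures.update({n: float(p[idx[n]]) for n in unknown})
    flows = {}
    for e in net.edges:
        q = (pressures[e.a] - pressures[e.b]) / e.R
        flows[e.label or f"{e.a}->{e.b}"] = q
    return NetworkSolution(pressures=pressures, flows=flows)


def bifurcation_network(
    l: float, k: float, w: float, h: float | None, mu: float,
    u_in: float, p_top: float, p_bot: float, dims: int = 3,
) -> tuple[HydraulicNetwork, NetworkSolution]:
    """Assemble and solve the T-junction network of the droplet use case.

    The inlet channel carries a fixed inflow Q = u_in * A (A = w*h in 3D,
    w per unit depth in 2D); each branch runs from the junction to its
    pressure outlet.
    """
    A = w * h if dims == 3 else w
    inlet = ChannelGeometry(l=l, w=w, h=h)
    branch = ChannelGeometry(l=k, w=w, h=h)
    net = HydraulicNetwork()
    net.add_channel("in", "jct", inlet, mu, dims=dims, label="inlet")
    net.add_channel("jct", "top_out", branch, mu, dims=dims, label="top")
    net.add_channel("jct", "bot_out", branch, mu, dims=dims, label="bot")
    net.fixed_pressure = {"top_out": p_top, "bot_out": p_bot}
    net.inflow = {"in": u_in * A}
    return net, solve_network(net)
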