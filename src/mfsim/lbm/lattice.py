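"""Discrete velocity sets (D2Q9, D3Q19) and their isotropy invariants."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LatticeDescriptor:
    """A discrete velocity stencil.

    ``c`` has shape (q, d) with integer components, ``w`` the matching
    weights, ``cs2`` the squared sound speed, and ``opp[i]`` the index of
    the opposite velocity ``-c[i]``.
    """

    name: str
    d: int
    q: int
    c: np.ndarray
    w: np.ndarray
    cs2: float
    opp: np.ndarray

    def validate(self) -> None:
        """Check the moment identities the stencil must satisfy."""
        w, c = self.w, self.c.astype(float)
        assert abs(w.sum() - 1.0) < 1e-14
        assert np.allclose(w @ c, 0.0, atol=1e-14)
        second = np.einsum("i,ia,ib->ab", w, c, c)
        assert np.allclose(second, self.cs2 * np.eye(self.d), atol=1e-14)
        assert np.array_equal(self.c[self.opp], -self.c)


def _descriptor(name, c, w, cs2) -> LatticeDescriptor:
    c = np.asarray(c, dtype=np.int64)
    w = np.asarray(w, dtype=float)
    q, d = c.shape
    opp = np.empty(q, dtype=np.int64)
    for i in range(q):
        (j,) = np.nonzero((c == -c[i]).all(axis=1))[0][:1]
        opp[i] = j
    desc = LatticeDescriptor(name=name, d=d, q=q, c=c, w=w, cs2=cs2, opp=opp)
    desc.validate()
    return desc


def make_lattice(kind: str) -> LatticeDescriptor:
    """Build a validated D2Q9 or D3Q19 descriptor."""
    if kind == "D2Q9":
        c = [(0, 0), (1, 0), (0, 1), (-1, 0), (0, -1),
             (1, 1), (-1, 1), (-1, -1), (1, -1)]
        w = [4 / 9] + [1 / 9] * 4 + [1 / 36] * 4
        return _descriptor(kind, c, w, 1 / 3)
    if kind == "D3Q19":
        axis = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        diag = [
            (1, 1, 0), (-1, -1, 0), (1, -1, 0), (-1, 1, 0),
            (1, 0, 1), (-1, 0, -1), (1, 0, -1), (-1, 0, 1),
            (0, 1, 1), (0, -1, -1), (0, 1, -1), (0, -1, 1),
        ]
        c = [(0, 0, 0)] + axis + diag
        w = [1 / 3] + [1 / 18] * 6 + [1 / 36] * 12
        return _descriptor(kind, c, w, 1 / 3)
    raise ValueError(f"unknown lattice kind {kind!r} (use 'D2Q9' or 'D3Q19')")
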