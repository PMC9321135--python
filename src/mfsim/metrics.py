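"""Comparison metrics: mixing index, profile extraction, droplet tracking."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mixing import ConcentrationProfile
from .rheology import VelocityProfile

#: AMI normalization variants.  ``calibrated`` is the package default:
#: sqrt of the mean squared deviation over the mean; it reproduces the
#: published 1D reference value for the straight-channel mixing problem.
#: ``mad`` (mean absolute deviation over mean, 1 for a perfect step) and
#: ``rms`` (relative standard deviation) are the common textbook variants.
AMI_METHODS = ("calibrated", "mad", "rms")


def absolute_mixing_index(profile, method: str = "calibrated") -> float:
    """Absolute Mixing Index of a concentration profile.

    0 means fully mixed (uniform); larger means less mixed.  ``profile``
    may be a :class:`~mfsim.mixing.ConcentrationProfile` or a plain array
    of concentration samples.

    Methods (alpha_i samples, m their mean):

    - ``calibrated``: sqrt( mean((alpha_i - m)^2) / m )  (default; a
      perfect half/half step gives 1/sqrt(2))
    - ``mad``: mean(|alpha_i - m|) / m  (step gives 1)
    - ``rms``: sqrt(mean((alpha_i - m)^2)) / m
    """
    a = profile.alpha if isinstance(profile, ConcentrationProfile) else np.asarray(profile, float)
    if a.size < 2:
        raise ValueError("need at least two samples")
    m = float(a.mean())
    if m <= 0:
        raise ValueError("mean concentration is zero; AMI undefined")
    dev = a - m
    if method == "calibrated":
        return float(np.sqrt(np.mean(dev**2) / m))
    if method == "mad":
        return float(np.mean(np.abs(dev)) / m)
    if method == "rms":
        return float(np.sqrt(np.mean(dev**2)) / m)
    raise ValueError(f"unknown AMI method {method!r}; use one of {AMI_METHODS}")


def extract_profile(
    field_grid: np.ndarray,
    mask: np.ndarray,
    column: int,
    scales,
    kind: str = "velocity",
    x_si: float | None = None,
):
    """Sample a field along the cross-channel measurement line.

    ``column`` is the 0-based fluid column (the ghost ring is handled
    here); returns a :class:`VelocityProfile` (``kind="velocity"``, field
    in lattice units, converted to SI) or a :class:`ConcentrationProfile`
    (``kind="concentration"``, dimensionless).  In 3D the line is taken at
    the mid-height plane.
    """
    from .geometry import FLUID

    ic = column + 1
    if not (1 <= ic < mask.shape[0] - 1):
        raise ValueError("measurement line outside the domain")
    if mask.ndim == 3:
        iz = mask.shape[2] // 2
        line = field_grid[ic, :, iz]
        roles = mask[ic, :, iz]
    else:
        line = field_grid[ic, :]
        roles = mask[ic, :]
    sel = roles == FLUID
    if not sel.any():
        raise ValueError("measurement line crosses no fluid cells")
    vals = line[sel]
    n = vals.size
    if kind == "velocity":
        z = (np.arange(n) + 0.5) * scales.dx
        u = vals * scales.dx / scales.dt
        # pad wall values so the container's wall condition is explicit
        z = np.concatenate([[0.0], z, [n * scales.dx]])
        u = np.concatenate([[0.0], u, [0.0]])
        return VelocityProfile(z=z, u=u)
    if kind == "concentration":
        y = (np.arange(n) + 0.5) / n
        return ConcentrationProfile(
            y=y, alpha=np.clip(vals, 0.0, 1.0), x=x_si if x_si is not None else 0.0
        )
    raise ValueError("kind must be 'velocity' or 'concentration'")


@dataclass
class DropletMetrics:
    """Time series of droplet integrity and position measurements.

    Arc-length positions are measured along the center path (inlet ->
    junction -> branch); ``n_components`` counts face-connected droplet
    blobs (1 = intact).
    """

    t: list = field(default_factory=list)
    s_trailing: list = field(default_factory=list)
    length: list = field(default_factory=list)
    n_components: list = field(default_factory=list)
    branch: list = field(default_factory=list)

    def record(self, t, s, length, n_comp, branch) -> None:
        self.t.append(float(t))
        self.s_trailing.append(float(s))
        self.length.append(float(length))
        self.n_components.append(int(n_comp))
        self.branch.append(branch)

    def max_components(self) -> int:
        return max(self.n_components) if self.n_components else 0


def label_components(binary: np.ndarray) -> tuple[np.ndarray, int]:
    """Face-adjacency connected-component labeling of a boolean grid."""
    from scipy import ndimage

    structure = ndimage.generate_binary_structure(binary.ndim, 1)
    labels, n = ndimage.label(binary, structure=structure)
    return labels, int(n)


def droplet_track(
    alpha_field: np.ndarray,
    path_coord: np.ndarray,
    threshold: float = 0.5,
):
    """Locate the droplet phase on a grid and measure it along a path.

    ``path_coord`` assigns every grid cell its arc-length coordinate along
    the center path (NaN off-path cells are excluded).  Returns
    ``(s_trailing, length, n_components)`` of the ``alpha >= threshold``
    phase.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    phase = alpha_field >= threshold
    if not phase.any():
        raise ValueError("droplet phase is empty")
    _, n = label_components(phase)
    coords = path_coord[phase]
    coords = coords[np.isfinite(coords)]
    if coords.size == 0:
        raise ValueError("droplet phase lies entirely off the measurement path")
    s_min, s_max = float(coords.min()), float(coords.max())
    return s_min, s_max - s_min, n
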