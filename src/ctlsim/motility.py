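"""Binned motility distributions and direction kinematics.

CTLs perform a persistent random walk: every persistence time they draw a
new speed from a binned speed distribution (µm/min) and turn by an angle
drawn from a binned turning-angle distribution (radians on [0, π]), applied
in a uniformly random plane containing the current heading.  Both
distributions are empirical histograms supplied by the user (in the original
imaging setting they come from 2-photon cell tracks); synthetic stand-ins
live in :mod:`ctlsim.reference`.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BinnedDistribution",
    "MotilityModel",
    "sample_from_histogram",
    "reorient_direction",
    "read_histogram_tsv",
    "write_histogram_tsv",
]

_HIST_HEADER = "bin_left\tbin_right\tprobability"


@dataclass(frozen=True)
class BinnedDistribution:
    """A histogram distribution: probability mass per bin, uniform within bins.

    Parameters
    ----------
    edges
        Strictly increasing bin edges, length ``n_bins + 1``.
    probabilities
        Nonnegative bin masses summing to 1 (within 1e-9).
    """

    edges: np.ndarray
    probabilities: np.ndarray
    _cum: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        if edges.ndim != 1 or probs.ndim != 1 or edges.size != probs.size + 1:
            raise ValueError("edges must have exactly one more entry than probabilities")
        if probs.size == 0:
            raise ValueError("histogram has no bins")
        if np.any(np.diff(edges) < 0):
            raise ValueError("bin edges must be non-decreasing")
        if np.any(probs < 0):
            raise ValueError("bin probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"bin probabilities must sum to 1, got {probs.sum()!r}")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "probabilities", probs)
        object.__setattr__(self, "_cum", np.cumsum(probs))
        object.__setattr__(self, "_cum_list", self._cum.tolist())
        object.__setattr__(self, "_edges_list", edges.tolist())

    @property
    def mean(self) -> float:
        """Expected value (bin centers weighted by mass)."""
        centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        return float(np.dot(centers, self.probabilities))

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw values: pick a bin by mass, then uniform within the bin."""
        if size is None:
            idx = bisect_right(self._cum_list, rng.random() * self._cum_list[-1])
            idx = min(idx, len(self._cum_list) - 1)
            left = self._edges_list[idx]
            return left + (self._edges_list[idx + 1] - left) * rng.random()
        n = int(size)
        idx = np.searchsorted(self._cum, rng.random(n) * self._cum[-1], side="right")
        idx = np.minimum(idx, self.probabilities.size - 1)
        left = self.edges[idx]
        width = self.edges[idx + 1] - left
        return left + width * rng.random(n)


@dataclass(frozen=True)
class MotilityModel:
    """Speed and turning-angle histograms driving the persistent random walk."""

    speed_hist: BinnedDistribution
    turn_hist: BinnedDistribution

    def __post_init__(self) -> None:
        if self.speed_hist.edges[0] < 0:
            raise ValueError("speeds must be nonnegative")
        if self.turn_hist.edges[0] < -1e-12 or self.turn_hist.edges[-1] > np.pi + 1e-9:
            raise ValueError("turning angles must lie in [0, pi]")


def sample_from_histogram(hist: BinnedDistribution, rng: np.random.Generator) -> float:
    """Draw one value from a binned distribution (uniform within the chosen bin)."""
    return hist.sample(rng)


def reorient_direction(
    direction: np.ndarray, angle: float, rng: np.random.Generator
) -> np.ndarray:
    """Rotate a unit vector by ``angle`` about a uniformly random azimuth.

    The new heading keeps ``dot(old, new) = cos(angle)``; the rotation plane is
    spanned by the old heading and a perpendicular axis uniform over the circle
    of perpendicular directions.
    """
    dx, dy, dz = (float(v) for v in direction)
    norm = math.sqrt(dx * dx + dy * dy + dz * dz)
    if norm < 1e-12:
        raise ValueError("direction must be a nonzero vector")
    dx, dy, dz = dx / norm, dy / norm, dz / norm
    # Build a unit vector perpendicular to d, uniform in azimuth.
    if abs(dx) < 0.9:
        hx, hy, hz = 1.0, 0.0, 0.0
    else:
        hx, hy, hz = 0.0, 1.0, 0.0
    proj = hx * dx + hy * dy + hz * dz
    e1x, e1y, e1z = hx - proj * dx, hy - proj * dy, hz - proj * dz
    n1 = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x, e1y, e1z = e1x / n1, e1y / n1, e1z / n1
    e2x = dy * e1z - dz * e1y
    e2y = dz * e1x - dx * e1z
    e2z = dx * e1y - dy * e1x
    phi = rng.uniform(0.0, 2.0 * np.pi)
    cp, sp = math.cos(phi), math.sin(phi)
    px, py, pz = cp * e1x + sp * e2x, cp * e1y + sp * e2y, cp * e1z + sp * e2z
    ca, sa = math.cos(angle), math.sin(angle)
    nx, ny, nz = ca * dx + sa * px, ca * dy + sa * py, ca * dz + sa * pz
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    return np.array([nx / nn, ny / nn, nz / nn])


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniform random direction on the unit sphere."""
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - probability ~0
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def read_histogram_tsv(path: str | Path) -> BinnedDistribution:
    """Read a 3-column TSV histogram (bin_left, bin_right, probability).

    A header line is required.  Bins must be contiguous.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or lines[0].split("\t")[:3] != _HIST_HEADER.split("\t"):
        raise ValueError(f"{path}: missing histogram header '{_HIST_HEADER}'")
    rows = [tuple(float(x) for x in ln.split("\t")[:3]) for ln in lines[1:]]
    if not rows:
        raise ValueError(f"{path}: empty histogram")
    lefts = np.array([r[0] for r in rows])
    rights = np.array([r[1] for r in rows])
    probs = np.array([r[2] for r in rows])
    if not np.allclose(lefts[1:], rights[:-1], atol=1e-9):
        raise ValueError(f"{path}: bins are not contiguous")
    edges = np.append(lefts, rights[-1])
    return BinnedDistribution(edges=edges, probabilities=probs)


def write_histogram_tsv(hist: BinnedDistribution, path: str | Path) -> None:
    """Write a histogram as a 3-column TSV with header (bit-exact round trip)."""
    path = Path(path)
    lines = [_HIST_HEADER]
    for left, right, p in zip(hist.edges[:-1], hist.edges[1:], hist.probabilities):
        lines.append(f"{float(left)!r}\t{float(right)!r}\t{float(p)!r}")
    path.write_text("\n".join(lines) + "\n")
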