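"""Structural diagnostics: degree maps, feedforward-path discovery, eigenspectra.

The feedforward finder starts from 64 neurons in an 8x8 block and
iteratively selects, 50 times, the 64 neurons receiving the most
connections (with multiplicity) from the current group, restricted to the
recurrent anisotropy-carrying projection class (E-to-E in EI networks,
I-to-I in I networks). A path qualifies as an effective feedforward pathway
when the distance between the centroids of the first and last group exceeds
16 grid points (half the diameter of the combined connection region of the
start block); pFF is the fraction of random starts that qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network import Network, TorusGrid, _wrap_delta

__all__ = [
    "FeedforwardPath",
    "PFFResult",
    "degree_maps",
    "next_group",
    "group_centroid",
    "find_ffw_path",
    "effective_length",
    "effective_length_threshold",
    "pff",
    "eigen_spectrum",
]


def degree_maps(network: Network) -> dict:
    """Per-neuron in-degree images, one per projection class."""
    out = {}
    for (sp, tp) in network.targets:
        g = network.grids[tp]
        out[(sp, tp)] = network.in_degrees(sp, tp).reshape(g.nrow, g.ncol)
    return out


def _ffw_class(network: Network):
    p = network.populations[0]
    return (p, p)


def next_group(network: Network, group: np.ndarray, group_size: int = 64,
               cls=None):
    """Top-``group_size`` receivers of connections from ``group``.

    Connections are counted with multiplicity over the recurrent class;
    ties are broken by ascending neuron id. Returns (ids, short_flag) where
    ``short_flag`` marks fewer than ``group_size`` distinct receivers.
    """
    if cls is None:
        cls = _ffw_class(network)
    group = np.asarray(group, dtype=int)
    if group.size == 0:
        raise ValueError("group must be non-empty")
    t = network.targets[cls]
    counts = np.bincount(t[group].ravel(), minlength=network.grids[cls[1]].size)
    nz = int(np.count_nonzero(counts))
    k = min(group_size, nz)
    # stable selection: sort by (-count, id)
    order = np.lexsort((np.arange(counts.size), -counts))
    return order[:k].astype(np.int64), nz < group_size


def group_centroid(ids: np.ndarray, grid: TorusGrid):
    """Torus-aware (circular-mean) centroid (x, y) of a neuron group."""
    row, col = grid.rowcol(np.asarray(ids, dtype=np.int64))

    def cmean(c, length):
        ang = c * (2.0 * np.pi / length)
        m = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
        return float((m * length / (2.0 * np.pi)) % length)

    return cmean(col, grid.ncol), cmean(row, grid.nrow)


@dataclass
class FeedforwardPath:
    """Ordered groups F_1..F_n with centroids and summary measures."""

    groups: list
    centroids: np.ndarray            # wrapped (n, 2)
    centroids_unwrapped: np.ndarray  # cumulative minimal-image (n, 2)
    grid: TorusGrid
    short: bool = False              # some group had < group_size receivers

    @property
    def n_ff(self) -> int:
        """Number of unique neurons over all groups (each counted once)."""
        return int(np.unique(np.concatenate(self.groups)).size)

    @property
    def wrapped_extent_exceeded(self) -> bool:
        ext = self.centroids_unwrapped.max(axis=0) - self.centroids_unwrapped.min(axis=0)
        return bool(ext[0] > self.grid.ncol / 2 or ext[1] > self.grid.nrow / 2)


def effective_length(path: FeedforwardPath) -> float:
    """Distance between the centroids of the first and last group.

    Minimal-image Euclidean distance; when the path's unwrapped extent
    exceeds half the torus (so the wrapped distance would alias a long
    excursion back), the unwrapped first-to-last distance is used instead.
    """
    d = path.centroids_unwrapped[-1] - path.centroids_unwrapped[0]
    if path.wrapped_extent_exceeded:
        return float(np.hypot(d[0], d[1]))
    dx = _wrap_delta(np.asarray([d[0]]), path.grid.ncol)[0]
    dy = _wrap_delta(np.asarray([d[1]]), path.grid.nrow)[0]
    return float(np.hypot(dx, dy))


def effective_length_threshold(sigma: float = 12.0, block: int = 8):
    """Derive the qualifying path length from the start block's reach.

    The combined connection region of an 8x8 start block with projection
    space constant sigma has diameter sigma + block + sigma; a path escapes
    it when the F_1 -> F_50 centroid distance exceeds half that diameter.
    Returns (diameter, threshold).
    """
    diameter = sigma + block + sigma
    return diameter, diameter / 2.0


def _block_ids(grid: TorusGrid, corner_row: int, corner_col: int, block: int = 8
               ) -> np.ndarray:
    rows = (np.arange(block) + corner_row) % grid.nrow
    cols = (np.arange(block) + corner_col) % grid.ncol
    return (rows[:, None] * grid.ncol + cols[None, :]).ravel()


def find_ffw_path(network: Network, start_corner=(0, 0), *, steps: int = 50,
                  group_size: int = 64, block: int = 8) -> FeedforwardPath:
    """Iterate the top-receiver selection from an 8x8 start block."""
    cls = _ffw_class(network)
    g = network.grids[cls[0]]
    f = _block_ids(g, start_corner[0], start_corner[1], block)
    groups = [f]
    short = False
    for _ in range(steps - 1):
        f, s = next_group(network, f, group_size, cls)
        short = short or s
        groups.append(f)
    cents = np.array([group_centroid(gr, g) for gr in groups])
    dx = _wrap_delta(np.diff(cents[:, 0]), g.ncol)
    dy = _wrap_delta(np.diff(cents[:, 1]), g.nrow)
    unw = np.column_stack((
        cents[0, 0] + np.concatenate(([0.0], np.cumsum(dx))),
        cents[0, 1] + np.concatenate(([0.0], np.cumsum(dy)))))
    return FeedforwardPath(groups, cents, unw, g, short)


@dataclass
class PFFResult:
    """Frequency of effective feedforward paths over random starts."""

    n_starts: int
    threshold: float
    lengths: np.ndarray
    n_ff: np.ndarray

    @property
    def pff(self) -> float:
        return float(np.mean(self.lengths > self.threshold))


def pff(network: Network, *, n_starts: int = 100, steps: int = 50,
        threshold: float = 16.0, group_size: int = 64, block: int = 8,
        seed: int = 0) -> PFFResult:
    """pFF: fraction of 100 random 8x8 starts whose 50-step feedforward
    path has effective length above threshold."""
    cls = _ffw_class(network)
    g = network.grids[cls[0]]
    rng = np.random.default_rng(seed)
    lengths = np.empty(n_starts)
    n_ff = np.empty(n_starts, dtype=np.int64)
    for k in range(n_starts):
        corner = (int(rng.integers(g.nrow)), int(rng.integers(g.ncol)))
        path = find_ffw_path(network, corner, steps=steps,
                             group_size=group_size, block=block)
        lengths[k] = effective_length(path)
        n_ff[k] = path.n_ff
    return PFFResult(n_starts, threshold, lengths, n_ff)


def eigen_spectrum(network: Network, sample_size: int = 1000, *, seed: int = 0,
                   pop: Optional[str] = None, weighted: bool = True,
                   weight_scale: str = "psp") -> np.ndarray:
    """Eigenvalues of the connectivity submatrix of randomly sampled neurons.

    The submatrix W[i, j] holds the signed, multiplicity-weighted connection
    from sampled neuron j to sampled neuron i, in units of the unitary PSP
    amplitude (mV) by default (``weight_scale='pA'`` keeps pA;
    ``weighted=False`` uses signed multiplicities).
    """
    if pop is None:
        pop = network.populations[0]
    cls = (pop, pop)
    g = network.grids[pop]
    if sample_size > g.size:
        raise ValueError("sample_size exceeds population size")
    rng = np.random.default_rng(seed)
    sample = np.sort(rng.choice(g.size, size=sample_size, replace=False))
    lut = np.full(g.size, -1, dtype=np.int64)
    lut[sample] = np.arange(sample_size)
    t = network.targets[cls]
    w = np.zeros((sample_size, sample_size))
    j = network.weights_pA[pop]
    if weighted and weight_scale == "psp":
        from .dynamics import psp_peak
        j = np.sign(j) * psp_peak(abs(j))
    elif not weighted:
        j = np.sign(j)
    for si, src in enumerate(sample):
        tl = lut[t[src]]
        tl = tl[tl >= 0]
        if tl.size:
            np.add.at(w[:, si], tl, j)
    return np.linalg.eigvals(w)
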