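"""Construction of locally connected random networks (LCRN) on a torus.

Neurons sit on a regular square grid folded into a torus. Each neuron makes
a fixed number of outgoing connections whose displacements are drawn from a
distance-dependent profile: a Gamma radial profile for purely inhibitory
networks (non-monotonic, ring-like) or an isotropic Gaussian for
excitatory/inhibitory networks. Anisotropy is introduced by translating the
sampled connectivity cloud of each neuron by ``s`` grid points along the
neuron's preferred direction ``phi``; the spatial layout of ``phi`` across
neurons follows one of four configurations (symmetric, random, perlin,
homogeneous). Out-degree is exact; multiple edges between a pair are kept;
self-connections are rejected and redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "TorusGrid",
    "ConnectivityProfile",
    "DirectionField",
    "ShiftSpec",
    "Network",
    "ConnectivityChangeMap",
    "DIRECTIONS",
    "torus_displacement",
    "perlin_coarse_size",
    "perlin_field",
    "assign_phi",
    "sample_targets",
    "build_I_network",
    "build_EI_network",
    "measured_phi",
    "connectivity_change",
    "multiplicity_histogram",
]

#: The eight canonical preferred directions (multiples of 45 degrees),
#: chosen because neurons sit on a square grid.
DIRECTIONS = np.arange(8) * (np.pi / 4.0)

_CHUNK = 2_000_000  # max offsets sampled per vectorized chunk


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TorusGrid:
    """A ``nrow`` x ``ncol`` grid with periodic boundary conditions.

    Neuron index ``i`` maps to ``row = i // ncol``, ``col = i % ncol``;
    positions are reported as ``(x, y) = (col, row)`` in grid units.
    """

    nrow: int
    ncol: int

    def __post_init__(self):
        if self.nrow < 2 or self.ncol < 2:
            raise ValueError(f"grid must be at least 2x2, got {self.nrow}x{self.ncol}")

    @property
    def size(self) -> int:
        return self.nrow * self.ncol

    def positions(self) -> np.ndarray:
        """(size, 2) float array of (x, y) positions."""
        idx = np.arange(self.size)
        return np.column_stack((idx % self.ncol, idx // self.ncol)).astype(float)

    def index(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return np.asarray(row) * self.ncol + np.asarray(col)

    def rowcol(self, idx: np.ndarray):
        idx = np.asarray(idx)
        return idx // self.ncol, idx % self.ncol


def _wrap_delta(d: np.ndarray, length: int) -> np.ndarray:
    """Wrap coordinate differences into the minimal image [-length/2, length/2)."""
    return (d + length / 2.0) % length - length / 2.0


def torus_displacement(a, b, grid: TorusGrid):
    """Minimal-image displacement from position ``a`` to position ``b``.

    Positions are ``(x, y)`` pairs (or arrays of them) in grid units.
    Returns ``(dx, dy)`` with ``|dx| <= ncol/2`` and ``|dy| <= nrow/2``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, p in (("a", a), ("b", b)):
        x, y = p[..., 0], p[..., 1]
        if np.any((x < 0) | (x >= grid.ncol) | (y < 0) | (y >= grid.nrow)):
            bad = np.argwhere((x < 0) | (x >= grid.ncol) | (y < 0) | (y >= grid.nrow))
            raise ValueError(
                f"position {name!r} out of bounds for {grid.nrow}x{grid.ncol} grid "
                f"(offending entry {bad.ravel()[:1]})"
            )
    dx = _wrap_delta(b[..., 0] - a[..., 0], grid.ncol)
    dy = _wrap_delta(b[..., 1] - a[..., 1], grid.nrow)
    return dx, dy


# ---------------------------------------------------------------------------
# connectivity profiles and direction fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnectivityProfile:
    """Distance-dependent connection profile for one projection class.

    ``gamma`` draws a radial distance r ~ Gamma(kappa, theta) with a uniform
    angle (non-monotonic in distance, peak at (kappa-1)*theta); ``gaussian``
    draws an isotropic 2-D Gaussian offset with standard deviation ``sigma``
    in units of the *target* grid.
    """

    kind: str  # 'gamma' | 'gaussian'
    n_conn: int
    kappa: float = 4.0
    theta: float = 3.0
    sigma: float = 9.0

    def __post_init__(self):
        if self.kind not in ("gamma", "gaussian"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.kind == "gamma" and (self.kappa <= 0 or self.theta <= 0):
            raise ValueError("gamma profile requires kappa > 0 and theta > 0")
        if self.kind == "gaussian" and self.sigma <= 0:
            raise ValueError("gaussian profile requires sigma > 0")
        if self.n_conn < 1:
            raise ValueError("n_conn must be >= 1")


@dataclass(frozen=True)
class DirectionField:
    """Per-neuron preferred projection directions.

    ``phi`` is quantized to the eight canonical directions; it is ``None``
    for the symmetric configuration, which carries no directional bias.
    """

    configuration: str
    phi: Optional[np.ndarray]
    perlin_scale: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.configuration not in ("symmetric", "random", "perlin", "homogeneous"):
            raise ValueError(f"unknown configuration {self.configuration!r}")
        if self.configuration == "symmetric" and self.phi is not None:
            raise ValueError("symmetric configuration carries no phi")


@dataclass(frozen=True)
class ShiftSpec:
    """Connectivity-cloud displacement in grid points along phi."""

    s: int = 1

    def __post_init__(self):
        if self.s < 0:
            raise ValueError("shift must be >= 0")


def _quantize_phi(phi: np.ndarray) -> np.ndarray:
    """Snap angles to the nearest of the 8 canonical directions."""
    k = np.rint(np.asarray(phi) / (np.pi / 4.0)).astype(int) % 8
    return DIRECTIONS[k]


def _smoothstep(t: np.ndarray) -> np.ndarray:
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def perlin_coarse_size(n: int, perlin_scale: int) -> int:
    """Side length of the coarse noise lattice, p = N / perlin_scale."""
    p = int(round(n / perlin_scale))
    if p < 1:
        raise ValueError(
            f"perlin_scale={perlin_scale} too large for grid size {n} (coarse grid < 1)"
        )
    return p


def perlin_field(grid: TorusGrid, perlin_scale: int, seed: int = 0) -> np.ndarray:
    """Spatially correlated angle field from interpolated coarse-grid noise.

    A ``p x p`` coarse lattice (``p = N / perlin_scale``) is filled with
    i.i.d. angles from U[0, 2*pi). Their unit vectors (cos, sin) are
    interpolated to the full grid with smoothstep-weighted bilinear
    interpolation, periodic in both dimensions (a circular quantity cannot
    be interpolated linearly), and the interpolated angle is quantized to
    the eight canonical directions with equal-occupancy bins: neurons are
    ordered by angle and split into eight equal groups, so the direction
    marginal over the network is exactly uniform, as specified for this
    configuration, while neighboring neurons keep similar directions.
    Larger ``perlin_scale`` gives longer-range spatial correlation. A 1x1
    lattice carries no spatial variation and degenerates to a constant
    (homogeneous-like) field.
    """
    if grid.nrow != grid.ncol:
        raise ValueError("perlin fields require a square grid")
    n = grid.nrow
    p = perlin_coarse_size(n, perlin_scale)
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(p, p))
    if p == 1:
        return np.full(grid.size, _quantize_phi(theta[0, 0]))
    cx, sx = np.cos(theta), np.sin(theta)

    # coarse-cell coordinates of each neuron, periodic in [0, p)
    u = np.arange(n) * (p / n)
    i0 = np.floor(u).astype(int) % p
    i1 = (i0 + 1) % p
    w = _smoothstep(u - np.floor(u))

    def interp(v):
        top = v[np.ix_(i0, i0)] * (1 - w[None, :]) + v[np.ix_(i0, i1)] * w[None, :]
        bot = v[np.ix_(i1, i0)] * (1 - w[None, :]) + v[np.ix_(i1, i1)] * w[None, :]
        return top * (1 - w[:, None]) + bot * w[:, None]

    phi = (np.arctan2(interp(sx), interp(cx)) % (2 * np.pi)).ravel()
    # equal-occupancy quantization preserving angular order; offset by half
    # a sector so bin 0 is centred on angle 0
    shifted = (phi + np.pi / 8.0) % (2.0 * np.pi)
    order = np.argsort(shifted, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(phi.size)
    labels = (ranks * 8) // phi.size
    return DIRECTIONS[labels]


def assign_phi(configuration: str, grid: TorusGrid, perlin_scale: Optional[int] = None,
               seed: int = 0) -> DirectionField:
    """Assign per-neuron preferred directions under one of the four layouts."""
    if configuration == "symmetric":
        return DirectionField("symmetric", None, seed=seed)
    rng = np.random.default_rng(seed)
    if configuration == "homogeneous":
        k = int(rng.integers(8))
        phi = np.full(grid.size, DIRECTIONS[k])
    elif configuration == "random":
        phi = DIRECTIONS[rng.integers(0, 8, size=grid.size)]
    elif configuration == "perlin":
        if perlin_scale is None:
            raise ValueError("perlin configuration requires perlin_scale")
        phi = perlin_field(grid, perlin_scale, seed=seed)
    else:
        raise ValueError(f"unknown configuration {configuration!r}")
    return DirectionField(configuration, phi, perlin_scale=perlin_scale, seed=seed)


# ---------------------------------------------------------------------------
# target sampling
# ---------------------------------------------------------------------------

def _sample_targets_block(pos_x, pos_y, phi, s, profile, tgt_grid, self_id, rng):
    """Sample one target per entry of the flat position arrays.

    ``pos_x``/``pos_y`` are source positions already mapped into target-grid
    coordinates (fractional for cross-population projections). ``self_id``
    is the source's id in the target population, or -1 where a
    self-connection is impossible. All rejections (gamma offsets that round
    to the origin, and post-shift self-targets) are redrawn until valid, so
    out-degree stays exact.
    """
    m = pos_x.shape[0]
    out = np.full(m, -1, dtype=np.int64)
    if phi is None or s == 0:
        sx = np.zeros(m)
        sy = np.zeros(m)
    else:
        sx = s * np.cos(phi)
        sy = s * np.sin(phi)
    todo = np.arange(m)
    while todo.size:
        k = todo.size
        if profile.kind == "gamma":
            r = rng.gamma(profile.kappa, profile.theta, size=k)
            ang = rng.uniform(0.0, 2.0 * np.pi, size=k)
            dx = r * np.cos(ang)
            dy = r * np.sin(ang)
            # discretization rule: offsets that would round to the origin
            # are not a connection at any shift; redraw them
            bad = (np.rint(dx) == 0) & (np.rint(dy) == 0)
        else:
            dx = rng.normal(0.0, profile.sigma, size=k)
            dy = rng.normal(0.0, profile.sigma, size=k)
            bad = np.zeros(k, dtype=bool)
        tx = np.rint(pos_x[todo] + dx + sx[todo]).astype(np.int64) % tgt_grid.ncol
        ty = np.rint(pos_y[todo] + dy + sy[todo]).astype(np.int64) % tgt_grid.nrow
        tgt = ty * tgt_grid.ncol + tx
        bad |= tgt == self_id[todo]
        ok = ~bad
        out[todo[ok]] = tgt[ok]
        todo = todo[bad]
    return out


def sample_targets(source: int, profile: ConnectivityProfile, field: DirectionField,
                   shift: ShiftSpec, src_grid: TorusGrid, tgt_grid: Optional[TorusGrid] = None,
                   rng=None) -> np.ndarray:
    """Draw the full set of ``n_conn`` targets for one source neuron.

    When ``tgt_grid`` differs from ``src_grid`` (cross-population
    projection) the source position is mapped into target-grid coordinates
    and self-connections are impossible; otherwise the source id is excluded.
    """
    if rng is None:
        rng = np.random.default_rng()
    if tgt_grid is None:
        tgt_grid = src_grid
    same_pop = tgt_grid == src_grid
    row, col = src_grid.rowcol(np.asarray([source]))
    fx = tgt_grid.ncol / src_grid.ncol
    fy = tgt_grid.nrow / src_grid.nrow
    n = profile.n_conn
    pos_x = np.full(n, col[0] * fx)
    pos_y = np.full(n, row[0] * fy)
    if field.phi is None:
        phi = None
    else:
        phi = np.full(n, field.phi[source])
    self_id = np.full(n, source if same_pop else -1, dtype=np.int64)
    return _sample_targets_block(pos_x, pos_y, phi, shift.s, profile, tgt_grid, self_id, rng)


def _build_projection(src_grid, tgt_grid, profile, phi, s, rng) -> np.ndarray:
    """(n_src, n_conn) int32 target ids for one projection class."""
    n_src = src_grid.size
    n_conn = profile.n_conn
    same_pop = tgt_grid == src_grid
    fx = tgt_grid.ncol / src_grid.ncol
    fy = tgt_grid.nrow / src_grid.nrow
    out = np.empty((n_src, n_conn), dtype=np.int32)
    rows_per_chunk = max(1, _CHUNK // n_conn)
    for start in range(0, n_src, rows_per_chunk):
        stop = min(start + rows_per_chunk, n_src)
        ids = np.arange(start, stop)
        row, col = src_grid.rowcol(ids)
        m = (stop - start) * n_conn
        pos_x = np.repeat(col * fx, n_conn)
        pos_y = np.repeat(row * fy, n_conn)
        phi_blk = None if phi is None else np.repeat(phi[start:stop], n_conn)
        self_id = (np.repeat(ids, n_conn) if same_pop
                   else np.full(m, -1, dtype=np.int64))
        blk = _sample_targets_block(pos_x, pos_y, phi_blk, s, profile, tgt_grid,
                                    self_id, rng)
        out[start:stop] = blk.reshape(stop - start, n_conn)
    return out


# ---------------------------------------------------------------------------
# the network container
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """A built LCRN: populations, grids, and per-class target arrays.

    ``targets[(sp, tp)]`` is an (n_src, n_conn) array of *local* target ids
    in population ``tp`` for every source neuron of population ``sp``.
    Global neuron ids enumerate populations in ``populations`` order.
    """

    populations: tuple
    grids: dict
    targets: dict
    weights_pA: dict
    fields: dict
    shift: int
    delay_ms: float = 1.0
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    @property
    def configuration(self) -> str:
        for f in self.fields.values():
            if f is not None:
                return f.configuration
        return "symmetric"

    def pop_offset(self, pop: str) -> int:
        off = 0
        for p in self.populations:
            if p == pop:
                return off
            off += self.grids[p].size
        raise KeyError(pop)

    @property
    def n_total(self) -> int:
        return sum(self.grids[p].size for p in self.populations)

    def out_degree(self, pop: str) -> int:
        return sum(self.targets[(sp, tp)].shape[1]
                   for (sp, tp) in self.targets if sp == pop)

    def positions_global(self) -> np.ndarray:
        """(n_total, 2) positions; cross-population coordinates are scaled
        onto the grid of the first (reference) population."""
        ref = self.grids[self.populations[0]]
        chunks = []
        for p in self.populations:
            g = self.grids[p]
            pos = g.positions()
            pos[:, 0] *= ref.ncol / g.ncol
            pos[:, 1] *= ref.nrow / g.nrow
            chunks.append(pos)
        return np.vstack(chunks)

    def in_degrees(self, sp: str, tp: str) -> np.ndarray:
        """Per-target-neuron in-degree for one projection class."""
        t = self.targets[(sp, tp)]
        return np.bincount(t.ravel(), minlength=self.grids[tp].size)

    def edge_arrays(self):
        """Flat (source, target, weight_pA) arrays with global ids."""
        srcs, tgts, ws = [], [], []
        for (sp, tp), t in self.targets.items():
            n_src, n_conn = t.shape
            srcs.append(np.repeat(np.arange(n_src) + self.pop_offset(sp), n_conn))
            tgts.append(t.ravel().astype(np.int64) + self.pop_offset(tp))
            ws.append(np.full(t.size, self.weights_pA[sp]))
        return np.concatenate(srcs), np.concatenate(tgts), np.concatenate(ws)

    def flat_connectivity(self):
        """CSR-like (indptr, flat global targets, per-source weight) for the
        simulator. Targets of each source are concatenated across classes."""
        n = self.n_total
        per_src = []
        w = np.zeros(n)
        for p in self.populations:
            off = self.pop_offset(p)
            w[off:off + self.grids[p].size] = self.weights_pA[p]
        cls_by_pop = {p: [(sp, tp) for (sp, tp) in self.targets if sp == p]
                      for p in self.populations}
        counts = np.zeros(n, dtype=np.int64)
        for p in self.populations:
            off = self.pop_offset(p)
            tot = sum(self.targets[c].shape[1] for c in cls_by_pop[p])
            counts[off:off + self.grids[p].size] = tot
        indptr = np.concatenate(([0], np.cumsum(counts)))
        flat = np.empty(indptr[-1], dtype=np.int32)
        for p in self.populations:
            off = self.pop_offset(p)
            arrs = [self.targets[(sp, tp)] + self.pop_offset(tp)
                    for (sp, tp) in cls_by_pop[p]]
            block = np.hstack(arrs) if len(arrs) > 1 else arrs[0]
            npop = self.grids[p].size
            flat[indptr[off]:indptr[off + npop]] = block.ravel()
        return indptr, flat, w


def build_I_network(*, nrow: int = 100, ncol: int = 100, p_conn: float = 0.1,
                    n_conn: Optional[int] = None, kappa: float = 4.0, theta: float = 3.0,
                    configuration: str = "perlin", shift: int = 1,
                    perlin_scale: Optional[int] = 20, j_pA: float = -10.0,
                    delay_ms: float = 1.0, seed: int = 0) -> Network:
    """Purely inhibitory LCRN: Gamma(kappa, theta) radial profile.

    Defaults give the full-size model: 100x100 grid (10,000 neurons), 1,000
    outgoing connections per neuron (10%), kappa=4, theta=3, synaptic weight
    -10 pA (a -0.22 mV unitary IPSP), delay 1 ms.
    """
    grid = TorusGrid(nrow, ncol)
    if n_conn is None:
        n_conn = int(round(p_conn * grid.size))
    if n_conn >= grid.size:
        raise ValueError("n_conn must be smaller than the population size")
    profile = ConnectivityProfile("gamma", n_conn, kappa=kappa, theta=theta)
    ss = np.random.SeedSequence(seed)
    field_seed, conn_seed = ss.spawn(2)
    dfield = assign_phi(configuration, grid, perlin_scale,
                        seed=field_seed.generate_state(1)[0])
    s = 0 if configuration == "symmetric" else shift
    rng = np.random.default_rng(conn_seed)
    targets = {("I", "I"): _build_projection(grid, grid, profile, dfield.phi, s, rng)}
    return Network(populations=("I",), grids={"I": grid}, targets=targets,
                   weights_pA={"I": j_pA}, fields={"I": dfield}, shift=s,
                   delay_ms=delay_ms, seed=seed,
                   meta={"model": "I", "profile": profile, "perlin_scale": perlin_scale,
                         "configuration": configuration})


def build_EI_network(*, nrow_E: int = 120, ncol_E: int = 120, nrow_I: int = 60,
                     ncol_I: int = 60, p_conn: float = 0.05,
                     sigma_EE: float = 9.0, sigma_EI: float = 4.5,
                     sigma_IE: float = 12.0, sigma_II: float = 6.0,
                     configuration: str = "perlin", shift: int = 1,
                     perlin_scale: Optional[int] = 20, j_E_pA: float = 10.0,
                     g: float = 8.0, delay_ms: float = 1.0, seed: int = 0) -> Network:
    """Excitatory/inhibitory LCRN with Gaussian profiles.

    Defaults give the full-size model: 14,400 E on 120x120 and 3,600 I on
    60x60 (4:1), each neuron projecting to 720 E and 180 I targets (5%).
    Sigmas are in units of the respective *target* grid, so excitatory
    projections have equal physical extent onto E and I sheets (9 vs 4.5)
    and inhibitory projections likewise (12 vs 6). The connectivity-cloud
    shift is applied to E-to-E projections only; all other classes stay
    isotropic. Inhibitory weight is -g times the excitatory weight.
    """
    gE = TorusGrid(nrow_E, ncol_E)
    gI = TorusGrid(nrow_I, ncol_I)
    if gE.size % gI.size:
        raise ValueError("E grid size must be a multiple of the I grid size")
    n_connE = int(round(p_conn * gE.size))
    n_connI = int(round(p_conn * gI.size))
    ss = np.random.SeedSequence(seed)
    field_seed, conn_seed = ss.spawn(2)
    dfield = assign_phi(configuration, gE, perlin_scale,
                        seed=field_seed.generate_state(1)[0])
    s = 0 if configuration == "symmetric" else shift
    rng = np.random.default_rng(conn_seed)
    prof = {
        ("E", "E"): ConnectivityProfile("gaussian", n_connE, sigma=sigma_EE),
        ("E", "I"): ConnectivityProfile("gaussian", n_connI, sigma=sigma_EI),
        ("I", "E"): ConnectivityProfile("gaussian", n_connE, sigma=sigma_IE),
        ("I", "I"): ConnectivityProfile("gaussian", n_connI, sigma=sigma_II),
    }
    grids = {"E": gE, "I": gI}
    targets = {}
    for (sp, tp), pr in prof.items():
        phi = dfield.phi if (sp, tp) == ("E", "E") else None
        targets[(sp, tp)] = _build_projection(grids[sp], grids[tp], pr, phi,
                                              s if phi is not None else 0, rng)
    return Network(populations=("E", "I"), grids=grids, targets=targets,
                   weights_pA={"E": j_E_pA, "I": -g * j_E_pA},
                   fields={"E": dfield, "I": None}, shift=s, delay_ms=delay_ms,
                   seed=seed,
                   meta={"model": "EI", "profiles": prof, "g": g,
                         "perlin_scale": perlin_scale, "configuration": configuration})


# ---------------------------------------------------------------------------
# structural measures on built networks
# ---------------------------------------------------------------------------

def _recurrent_class(network: Network):
    """The same-population projection class that carries the anisotropy."""
    p = network.populations[0]
    return (p, p)


def _edge_displacements(network: Network, cls=None):
    """Minimal-image displacement (dx, dy) of every edge of one class."""
    if cls is None:
        cls = _recurrent_class(network)
    sp, tp = cls
    t = network.targets[cls]
    g_s, g_t = network.grids[sp], network.grids[tp]
    n_src, n_conn = t.shape
    src = np.repeat(np.arange(n_src), n_conn)
    srow, scol = g_s.rowcol(src)
    trow, tcol = g_t.rowcol(t.ravel().astype(np.int64))
    fx = g_t.ncol / g_s.ncol
    fy = g_t.nrow / g_s.nrow
    dx = _wrap_delta(tcol - scol * fx, g_t.ncol)
    dy = _wrap_delta(trow - srow * fy, g_t.nrow)
    return src, dx, dy


def measured_phi(network: Network, neuron: int, pop: Optional[str] = None) -> float:
    """Preferred direction measured from the locations of a neuron's targets.

    Circular mean of the minimal-image displacement angles to all
    postsynaptic targets of the anisotropy-carrying (same-population)
    projection class. ``neuron`` is a local id within ``pop`` (default:
    the first population).
    """
    if pop is None:
        pop = network.populations[0]
    cls = (pop, pop)
    t = network.targets[cls][neuron]
    if t.size == 0:
        raise ValueError(f"neuron {neuron} has zero out-degree")
    g = network.grids[pop]
    row, col = g.rowcol(np.int64(neuron))
    trow, tcol = g.rowcol(t.astype(np.int64))
    dx = _wrap_delta(tcol - col, g.ncol)
    dy = _wrap_delta(trow - row, g.nrow)
    ang = np.arctan2(dy, dx)
    return float(np.arctan2(np.sin(ang).sum(), np.cos(ang).sum()) % (2 * np.pi))


@dataclass
class ConnectivityChangeMap:
    """Distance- and direction-resolved connectivity comparison.

    ``S`` and ``H`` are mean per-bin connection counts (per source neuron)
    for the symmetric and homogeneous networks; ``delta = (S - H) / S``.
    Direction bins are measured relative to the homogeneous network's
    assigned phi.
    """

    dist_edges: np.ndarray
    dir_centers: np.ndarray
    S: np.ndarray  # (n_dist, n_dir)
    H: np.ndarray
    delta: np.ndarray


def connectivity_change(network_S: Network, network_H: Network,
                        n_dist_bins: int = 20, max_dist: Optional[float] = None
                        ) -> ConnectivityChangeMap:
    """Relative connectivity change (S - H)/S between a symmetric and a
    homogeneous network sharing geometry and profile."""
    cls = _recurrent_class(network_S)
    if network_S.grids[cls[0]] != network_H.grids[cls[0]]:
        raise ValueError("networks have mismatched geometry")
    fH = network_H.fields[cls[0]]
    if fH is None or fH.configuration != "homogeneous":
        raise ValueError("network_H must use the homogeneous configuration")
    phi0 = float(fH.phi[0])
    g = network_S.grids[cls[0]]
    if max_dist is None:
        max_dist = min(g.nrow, g.ncol) / 2.0
    dist_edges = np.linspace(0, max_dist, n_dist_bins + 1)
    # 8 direction sectors centred on the canonical directions
    dir_centers = DIRECTIONS.copy()

    def binned(net):
        _, dx, dy = _edge_displacements(net, cls)
        r = np.hypot(dx, dy)
        ang = (np.arctan2(dy, dx) - phi0) % (2 * np.pi)
        sec = np.rint(ang / (np.pi / 4.0)).astype(int) % 8
        db = np.searchsorted(dist_edges, r, side="right") - 1
        keep = (db >= 0) & (db < n_dist_bins)
        counts = np.zeros((n_dist_bins, 8))
        np.add.at(counts, (db[keep], sec[keep]), 1.0)
        return counts / net.grids[cls[0]].size

    S = binned(network_S)
    H = binned(network_H)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(S > 0, (S - H) / S, 0.0)
    return ConnectivityChangeMap(dist_edges, dir_centers, S, H, delta)


def multiplicity_histogram(network: Network) -> np.ndarray:
    """Count distribution of parallel edges per connected ordered pair.

    Returns an array ``h`` where ``h[m]`` is the number of ordered neuron
    pairs connected by exactly ``m`` parallel edges (``h[0] = 0``).
    """
    src, tgt, _ = network.edge_arrays()
    key = src.astype(np.int64) * network.n_total + tgt
    _, mult = np.unique(key, return_counts=True)
    return np.bincount(mult)
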