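"""Detection and kinematics of spatio-temporal activity sequences (STAS).

Spikes are rendered as points in a 3-D space (two wrapped spatial network
dimensions, one rescaled time dimension) and clustered with DBSCAN inside
sliding 1 s windows (0.9 s overlap). Clusters sharing spikes across
overlapping windows are merged. Each cluster's activity-bump trajectory is
tracked by torus-aware centroids in short time bins, from which speed,
movement direction alpha_t, and the wrapped direction change
d_alpha = alpha_t - alpha_{t-1} in (-pi, pi] are derived.

The periodic spatial axes are handled by embedding each axis on a ring of
matching circumference before running (Euclidean) DBSCAN; for distances on
the order of eps the chord length is indistinguishable from the wrapped
arc-length metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import DBSCAN

from .network import TorusGrid, _wrap_delta

__all__ = [
    "ClusterParams",
    "ClusterSet",
    "SequenceTrack",
    "cluster_spikes",
    "qualifying_tracks",
    "centroid_track",
    "direction_change",
    "count_sequences",
    "direction_distribution",
    "flow_velocity",
    "rate_map",
    "circular_variance",
]


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN and windowing parameters for STAS detection.

    ``time_rescale`` divides spike times (ms) before clustering so that the
    temporal spread of a moving bump matches its spatial spread (20 for
    I-networks, 3-5 for EI-networks; default 4 there). ``min_pts`` is not
    reported with the published analysis; defaults of 25 (I) and 10 (EI)
    are exposed here.
    """

    eps: float = 3.0
    min_pts: int = 25
    time_rescale: float = 20.0
    window_ms: float = 1000.0
    overlap_ms: float = 900.0
    merge_jaccard: float = 0.5

    def __post_init__(self):
        if self.eps <= 0 or self.min_pts < 1 or self.time_rescale <= 0:
            raise ValueError("eps, min_pts and time_rescale must be positive")
        if self.overlap_ms >= self.window_ms:
            raise ValueError("overlap must be shorter than the window")


@dataclass
class ClusterSet:
    """Per-spike cluster labels (-1 = noise) over a spike point cloud."""

    labels: np.ndarray
    times_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    grid: TorusGrid
    params: Optional[ClusterParams] = None

    @property
    def cluster_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids >= 0]

    def members(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cid)


@dataclass
class SequenceTrack:
    """Centroid trajectory of one cluster on the torus."""

    cluster_id: int
    t_ms: np.ndarray            # bin centers with spikes
    x: np.ndarray               # wrapped centroids
    y: np.ndarray
    x_unwrapped: np.ndarray     # cumulative minimal-image trajectory
    y_unwrapped: np.ndarray
    alpha: np.ndarray           # movement direction per step (len-1)
    speed: np.ndarray           # grid units / ms per step (len-1)

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0]) if self.t_ms.size > 1 else 0.0

    @property
    def displacement(self) -> float:
        """Net unwrapped distance between first and last centroid."""
        if self.t_ms.size < 2:
            return 0.0
        return float(np.hypot(self.x_unwrapped[-1] - self.x_unwrapped[0],
                              self.y_unwrapped[-1] - self.y_unwrapped[0]))

    @property
    def mean_speed(self) -> float:
        return float(np.mean(self.speed)) if self.speed.size else 0.0

    @property
    def net_velocity(self) -> float:
        """Net displacement over lifetime, grid units / s."""
        d = self.duration_ms
        return float(self.displacement / d * 1000.0) if d > 0 else 0.0

    @property
    def persistence(self) -> float:
        """Mean resultant length of step directions; 1 = straight motion,
        near 0 = direction-less jitter."""
        if self.alpha.size == 0:
            return 0.0
        return float(np.hypot(np.sin(self.alpha).mean(), np.cos(self.alpha).mean()))


def _torus_embed(coord: np.ndarray, length: int) -> np.ndarray:
    """Embed a periodic axis on a ring whose arc length equals the axis."""
    r = length / (2.0 * np.pi)
    ang = coord * (2.0 * np.pi / length)
    return np.column_stack((r * np.cos(ang), r * np.sin(ang)))


def cluster_spikes(times_ms: np.ndarray, x: np.ndarray, y: np.ndarray,
                   grid: TorusGrid, params: ClusterParams) -> ClusterSet:
    """DBSCAN over (x, y, t / time_rescale) in sliding windows.

    Windows advance by ``window_ms - overlap_ms``; clusters from
    overlapping windows are merged when the Jaccard overlap of their member
    spikes exceeds ``merge_jaccard``. Spikes never assigned to a core
    region stay labeled -1 (noise).
    """
    times_ms = np.asarray(times_ms, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.full(times_ms.size, -1, dtype=np.int64)
    if times_ms.size == 0:
        return ClusterSet(labels, times_ms, x, y, grid, params)

    emb = np.hstack((_torus_embed(x, grid.ncol), _torus_embed(y, grid.nrow),
                     (times_ms / params.time_rescale)[:, None]))
    t0 = float(times_ms.min())
    t_end = float(times_ms.max())
    step = params.window_ms - params.overlap_ms

    next_label = 0
    parent: dict = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    start = t0
    while True:
        in_win = np.flatnonzero((times_ms >= start) & (times_ms < start + params.window_ms))
        if in_win.size >= params.min_pts:
            win_labels = DBSCAN(eps=params.eps, min_samples=params.min_pts
                                ).fit_predict(emb[in_win])
            for wl in np.unique(win_labels):
                if wl < 0:
                    continue
                members = in_win[win_labels == wl]
                gid = next_label
                next_label += 1
                parent[gid] = gid
                # merge with already-assigned overlapping clusters
                prev = labels[members]
                prev_ids, counts = np.unique(prev[prev >= 0], return_counts=True)
                for pid, cnt in zip(prev_ids, counts):
                    size_prev = int(np.sum(labels == pid))
                    jac = cnt / (size_prev + members.size - cnt)
                    if jac > params.merge_jaccard or cnt == size_prev or cnt == members.size:
                        union(gid, int(pid))
                unassigned = members[prev < 0]
                labels[unassigned] = gid
        if start + params.window_ms >= t_end:
            break
        start += step

    # resolve union-find and compact ids
    if next_label:
        root = np.array([find(i) for i in range(next_label)])
        remap = {r: k for k, r in enumerate(np.unique(root))}
        lut = np.array([remap[r] for r in root])
        pos = labels >= 0
        labels[pos] = lut[labels[pos]]
    return ClusterSet(labels, times_ms, x, y, grid, params)


def _circular_centroid(coord: np.ndarray, length: int) -> float:
    ang = coord * (2.0 * np.pi / length)
    mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((mean * length / (2.0 * np.pi)) % length)


def centroid_track(clusters: ClusterSet, cluster_id: int, bin_ms: float = 10.0
                   ) -> SequenceTrack:
    """Torus-aware centroid trajectory of one cluster in ``bin_ms`` bins.

    Bins without spikes are skipped (the gap shows up as a longer interval
    between consecutive track samples). Consecutive centroids are unwrapped
    with minimal-image increments, so a bump crossing the torus seam yields
    a continuous trajectory.
    """
    m = clusters.members(cluster_id)
    if m.size == 0:
        raise ValueError(f"cluster {cluster_id} has no member spikes")
    t = clusters.times_ms[m]
    order = np.argsort(t, kind="stable")
    m = m[order]
    t = t[order]
    bins = np.floor((t - t[0]) / bin_ms).astype(int)
    g = clusters.grid

    tc, xs, ys = [], [], []
    for b in np.unique(bins):
        sel = m[bins == b]
        tc.append(t[0] + (b + 0.5) * bin_ms)
        xs.append(_circular_centroid(clusters.x[sel], g.ncol))
        ys.append(_circular_centroid(clusters.y[sel], g.nrow))
    tc = np.asarray(tc)
    xs = np.asarray(xs)
    ys = np.asarray(ys)

    dx = _wrap_delta(np.diff(xs), g.ncol)
    dy = _wrap_delta(np.diff(ys), g.nrow)
    xu = xs[0] + np.concatenate(([0.0], np.cumsum(dx)))
    yu = ys[0] + np.concatenate(([0.0], np.cumsum(dy)))
    dt = np.diff(tc)
    alpha = np.arctan2(dy, dx)
    speed = np.hypot(dx, dy) / dt
    return SequenceTrack(cluster_id, tc, xs, ys, xu, yu, alpha, speed)


def direction_change(track: SequenceTrack) -> np.ndarray:
    """Wrapped step-to-step change of movement direction, in (-pi, pi]."""
    if track.alpha.size < 2:
        raise ValueError("track needs at least two direction samples")
    d = np.diff(track.alpha)
    d = (d + np.pi) % (2.0 * np.pi) - np.pi
    d[d == -np.pi] = np.pi
    return d


def tracks_from_clusters(clusters: ClusterSet, bin_ms: float = 10.0,
                         min_spikes: int = 2):
    """Centroid tracks for every cluster with enough spikes."""
    out = []
    for cid in clusters.cluster_ids:
        if clusters.members(cid).size >= min_spikes:
            out.append(centroid_track(clusters, cid, bin_ms))
    return out


def qualifying_tracks(clusters: ClusterSet, *, min_displacement: float = 7.0,
                      min_duration_ms: float = 150.0, min_persistence: float = 0.8,
                      bin_ms: float = 50.0):
    """Centroid tracks that qualify as moving sequences (STAS).

    A cluster qualifies when its centroid travels at least
    ``min_displacement`` grid points net, lasts at least
    ``min_duration_ms``, and moves with directional persistence (mean
    resultant of step directions) of at least ``min_persistence``. The
    persistence requirement separates coherently moving bumps from bumps
    that jitter around a fixed location, whose centroid can random-walk a
    comparable distance over a long lifetime. Centroids are taken in
    ``bin_ms`` bins, coarse enough that per-bin centroid jitter does not
    drown the drift.
    """
    out = []
    for tr in tracks_from_clusters(clusters, bin_ms):
        if (tr.displacement >= min_displacement
                and tr.duration_ms >= min_duration_ms
                and tr.alpha.size >= 2
                and tr.persistence >= min_persistence):
            out.append(tr)
    return out


def count_sequences(clusters: ClusterSet, *, epoch_ms: float = 1000.0,
                    n_epochs: Optional[int] = None, min_displacement: float = 7.0,
                    min_duration_ms: float = 150.0, min_persistence: float = 0.8,
                    bin_ms: float = 50.0, t0_ms: float = 0.0) -> np.ndarray:
    """Number of qualifying STAS per 1 s epoch.

    See :func:`qualifying_tracks` for the qualification rule; a qualifying
    cluster is counted in every epoch its lifetime intersects.
    """
    if n_epochs is None:
        if clusters.times_ms.size == 0:
            return np.zeros(0, dtype=int)
        n_epochs = int(np.ceil((clusters.times_ms.max() - t0_ms) / epoch_ms))
    counts = np.zeros(n_epochs, dtype=int)
    for tr in qualifying_tracks(clusters, min_displacement=min_displacement,
                                min_duration_ms=min_duration_ms,
                                min_persistence=min_persistence, bin_ms=bin_ms):
        e0 = int(np.floor((tr.t_ms[0] - t0_ms) / epoch_ms))
        e1 = int(np.floor((tr.t_ms[-1] - t0_ms) / epoch_ms))
        for e in range(max(e0, 0), min(e1, n_epochs - 1) + 1):
            counts[e] += 1
    return counts


def direction_distribution(tracks, n_bins: int = 36):
    """Circular histogram of per-step movement directions pooled over tracks.

    Returns (bin_centers, counts, pooled_alpha).
    """
    if not tracks:
        raise ValueError("need at least one track")
    alpha = np.concatenate([tr.alpha for tr in tracks if tr.alpha.size])
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(alpha, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts, alpha


def circular_variance(angles: np.ndarray) -> float:
    """1 - |mean resultant|; 0 for a single direction, ->1 for uniform."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("no angles")
    r = np.hypot(np.sin(angles).mean(), np.cos(angles).mean())
    return float(1.0 - r)


def flow_velocity(times_ms: np.ndarray, ids: np.ndarray, grid: TorusGrid, *,
                  t0_ms: float, t1_ms: float, frame_ms: float = 20.0,
                  lag_frames: int = 2, min_spikes: int = 30):
    """Global drift velocity of the activity pattern by phase correlation.

    Spikes are binned into activity frames on the grid; for every frame
    pair separated by ``lag_frames`` the wrapped cross-correlation (via
    FFT, periodic by construction) is maximized over integer displacements.
    The mean displacement over pairs divided by the lag gives the drift
    velocity (grid units / s) and its direction; per-pair argmax noise is
    direction-symmetric and averages out. The lag must stay well below the
    bump-pattern period (40 ms by default): longer lags alias the
    correlation peak to the spacing of the bump lattice. Suited to regimes
    where bumps move coherently (e.g. a homogeneous direction field); with
    spatially mixed movement directions the estimate averages towards the
    net flow.

    Returns (speed, vx, vy).
    """
    times_ms = np.asarray(times_ms, dtype=float)
    ids = np.asarray(ids, dtype=int)
    nf = int((t1_ms - t0_ms) // frame_ms)
    if nf < lag_frames + 1:
        raise ValueError("window too short for the requested lag")
    frames = np.zeros((nf, grid.nrow, grid.ncol))
    fi = ((times_ms - t0_ms) // frame_ms).astype(int)
    ok = (fi >= 0) & (fi < nf)
    np.add.at(frames, (fi[ok], ids[ok] // grid.ncol, ids[ok] % grid.ncol), 1.0)
    dxs, dys = [], []
    for k in range(nf - lag_frames):
        a, b = frames[k], frames[k + lag_frames]
        if a.sum() < min_spikes or b.sum() < min_spikes:
            continue
        a = a - a.mean()
        b = b - b.mean()
        c = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
        iy, ix = np.unravel_index(int(np.argmax(c)), c.shape)
        dxs.append(ix if ix <= grid.ncol // 2 else ix - grid.ncol)
        dys.append(iy if iy <= grid.nrow // 2 else iy - grid.nrow)
    if not dxs:
        return 0.0, 0.0, 0.0
    dt_s = lag_frames * frame_ms / 1000.0
    vx = float(np.mean(dxs) / dt_s)
    vy = float(np.mean(dys) / dt_s)
    return float(np.hypot(vx, vy)), vx, vy


def rate_map(times_ms: np.ndarray, ids: np.ndarray, duration_ms: float,
             grid: TorusGrid) -> np.ndarray:
    """Per-neuron time-averaged firing rate (Hz) arranged on the grid."""
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    counts = np.bincount(np.asarray(ids, dtype=int), minlength=grid.size)
    return (counts / (duration_ms / 1000.0)).reshape(grid.nrow, grid.ncol)
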