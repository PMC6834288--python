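"""Configuration, file IO, fixture generation and experiment orchestration.

Configs are YAML (JSON accepted) with units embedded in key names; every
omitted key falls back to the published model defaults. Networks are saved
as a directed edge-list CSV (source, target, weight_pA, delay_ms) plus a
JSON metadata sidecar (grids, configuration, phi field, seed) and a Matrix
Market sparse matrix of summed signed weights. Spikes are CSV
(time_ms, neuron_id) or HDF5 with metadata attributes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import network as netmod
from .network import Network, TorusGrid, build_EI_network, build_I_network
from .dynamics import (LIFParams, NoiseInput, SpikeData, StimulusProtocol,
                       SynapseParams, simulate)
from .sequences import ClusterParams, cluster_spikes, count_sequences, tracks_from_clusters
from .spectral import peak_frequency, population_rate, welch_spectrum

__all__ = [
    "ExperimentConfig",
    "load_config",
    "save_network",
    "load_network",
    "save_spikes",
    "load_spikes",
    "make_fixture",
    "moving_bump_spikes",
    "sinusoid_rate_spikes",
    "run_experiment",
]

_MODEL_MU = {"I": 700.0, "EI": 350.0}
_MODEL_CLUSTER = {
    "I": dict(eps=3.0, min_pts=25, time_rescale=20.0),
    "EI": dict(eps=3.5, min_pts=10, time_rescale=4.0),
}


@dataclass
class ExperimentConfig:
    """Full description of one build+simulate+analyze run.

    Defaults reproduce the published models: pass ``model='I'`` for the
    100x100 inhibitory network (Gamma(4, 3) profile, mu=700 pA) or
    ``model='EI'`` for the 120x120/60x60 network (Gaussian profiles,
    mu=350 pA, g=8).
    """

    model: str = "I"
    configuration: str = "perlin"
    shift: int = 1
    perlin_scale: int = 20
    seed: int = 0
    duration_ms: float = 1000.0
    dt_ms: float = 0.1
    mu_gwn_pA: Optional[float] = None      # default: 700 (I) / 350 (EI)
    sigma_gwn_pA: float = 100.0
    noise_dt_ms: float = 1.0
    transient_ms: float = 200.0
    network: dict = field(default_factory=dict)   # overrides for the builder
    neuron: dict = field(default_factory=dict)    # LIFParams overrides
    synapse: dict = field(default_factory=dict)   # SynapseParams overrides
    cluster: dict = field(default_factory=dict)   # ClusterParams overrides
    spectral: dict = field(default_factory=dict)  # band etc.
    ffw: dict = field(default_factory=dict)       # feedforward finder settings

    def __post_init__(self):
        if self.model not in ("I", "EI"):
            raise ValueError(f"model must be 'I' or 'EI', got {self.model!r}")
        if self.mu_gwn_pA is None:
            self.mu_gwn_pA = _MODEL_MU[self.model]

    # -- resolved parameter objects -------------------------------------
    def lif_params(self) -> LIFParams:
        return LIFParams(**self.neuron)

    def synapse_params(self) -> SynapseParams:
        return SynapseParams(**self.synapse)

    def noise_input(self) -> NoiseInput:
        return NoiseInput(self.mu_gwn_pA, self.sigma_gwn_pA, self.noise_dt_ms)

    def cluster_params(self) -> ClusterParams:
        kw = dict(_MODEL_CLUSTER[self.model])
        kw.update(self.cluster)
        return ClusterParams(**kw)

    def build_network(self) -> Network:
        kw = dict(configuration=self.configuration, shift=self.shift,
                  perlin_scale=self.perlin_scale, seed=self.seed)
        kw.update(self.network)
        if self.model == "I":
            return build_I_network(**kw)
        return build_EI_network(**kw)


def _check_keys(data: dict, cls, path: str = ""):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} at {path or 'top level'}; "
            f"allowed: {sorted(allowed)}")


_SUBKEYS = {
    "neuron": LIFParams,
    "synapse": SynapseParams,
    "cluster": ClusterParams,
}


def load_config(path) -> ExperimentConfig:
    """Read and validate a YAML/JSON experiment config.

    An empty file yields the full model defaults; unknown keys raise with
    the offending names.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    _check_keys(data, ExperimentConfig)
    for key, sub_cls in _SUBKEYS.items():
        if key in data and data[key]:
            _check_keys(data[key], sub_cls, path=key)
    return ExperimentConfig(**data)


# ---------------------------------------------------------------------------
# network / spike IO
# ---------------------------------------------------------------------------

def save_network(net: Network, out_dir, mtx: bool = True) -> Path:
    """Write edge-list CSV + JSON sidecar (+ Matrix Market matrix)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    src, tgt, w = net.edge_arrays()
    pd.DataFrame({"source": src, "target": tgt, "weight_pA": w,
                  "delay_ms": net.delay_ms}).to_csv(out / "edges.csv", index=False)
    meta = {
        "populations": list(net.populations),
        "grids": {p: [net.grids[p].nrow, net.grids[p].ncol] for p in net.populations},
        "n_conn": {f"{sp}->{tp}": int(net.targets[(sp, tp)].shape[1])
                   for (sp, tp) in net.targets},
        "weights_pA": net.weights_pA,
        "delay_ms": net.delay_ms,
        "shift": net.shift,
        "seed": net.seed,
        "configuration": net.configuration,
        "model": net.meta.get("model"),
        "perlin_scale": net.meta.get("perlin_scale"),
        "phi": {p: (net.fields[p].phi.tolist() if net.fields.get(p) is not None
                    and net.fields[p].phi is not None else None)
                for p in net.populations},
    }
    (out / "meta.json").write_text(json.dumps(meta))
    if mtx:
        from scipy import sparse
        from scipy.io import mmwrite
        n = net.n_total
        m = sparse.coo_matrix((w, (tgt, src)), shape=(n, n)).tocsr()
        mmwrite(out / "adjacency.mtx", m.tocoo())
    return out


def load_network(in_dir) -> Network:
    """Reconstruct a Network from :func:`save_network` output."""
    out = Path(in_dir)
    meta = json.loads((out / "meta.json").read_text())
    df = pd.read_csv(out / "edges.csv")
    pops = tuple(meta["populations"])
    grids = {p: TorusGrid(*meta["grids"][p]) for p in pops}
    offsets, off = {}, 0
    for p in pops:
        offsets[p] = off
        off += grids[p].size
    src = df["source"].to_numpy()
    tgt = df["target"].to_numpy()
    targets = {}
    for key, n_conn in meta["n_conn"].items():
        sp, tp = key.split("->")
        lo, hi = offsets[sp], offsets[sp] + grids[sp].size
        t_lo = offsets[tp]
        m = ((src >= lo) & (src < hi)
             & (tgt >= t_lo) & (tgt < t_lo + grids[tp].size))
        sub_t = tgt[m] - t_lo
        # cross-class rows of one source are contiguous per class because
        # edge_arrays writes class blocks; order within source is preserved
        order = np.argsort(src[m], kind="stable")
        targets[(sp, tp)] = sub_t[order].reshape(grids[sp].size, n_conn).astype(np.int32)
    fields = {}
    for p in pops:
        phi = meta["phi"].get(p)
        if phi is None:
            fields[p] = (netmod.DirectionField("symmetric", None)
                         if meta["configuration"] == "symmetric" else None)
        else:
            fields[p] = netmod.DirectionField(meta["configuration"], np.asarray(phi),
                                              perlin_scale=meta.get("perlin_scale"))
    return Network(populations=pops, grids=grids, targets=targets,
                   weights_pA={p: float(meta["weights_pA"][p]) for p in pops},
                   fields=fields, shift=int(meta["shift"]),
                   delay_ms=float(meta["delay_ms"]), seed=meta["seed"],
                   meta={"model": meta.get("model"),
                         "perlin_scale": meta.get("perlin_scale"),
                         "configuration": meta["configuration"]})


def save_spikes(spikes: SpikeData, path) -> Path:
    """CSV (time_ms, neuron_id) or HDF5 (by suffix) with metadata."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("time_ms", data=spikes.times_ms)
            f.create_dataset("neuron_id", data=spikes.ids)
            f.attrs["n_neurons"] = spikes.n_neurons
            f.attrs["duration_ms"] = spikes.duration_ms
            f.attrs["dt_ms"] = spikes.dt_ms
            for k, v in spikes.meta.items():
                if isinstance(v, (int, float, str)):
                    f.attrs[k] = v
    else:
        pd.DataFrame({"time_ms": spikes.times_ms, "neuron_id": spikes.ids}
                     ).to_csv(path, index=False)
    return path


def load_spikes(path, n_neurons: Optional[int] = None,
                duration_ms: Optional[float] = None, dt_ms: float = 0.1) -> SpikeData:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "r") as f:
            t = f["time_ms"][:]
            i = f["neuron_id"][:]
            n_neurons = int(f.attrs["n_neurons"])
            duration_ms = float(f.attrs["duration_ms"])
            dt_ms = float(f.attrs["dt_ms"])
    else:
        df = pd.read_csv(path)
        t = df["time_ms"].to_numpy(float)
        i = df["neuron_id"].to_numpy(int)
        if n_neurons is None:
            n_neurons = int(i.max()) + 1 if i.size else 0
        if duration_ms is None:
            duration_ms = float(t.max()) if t.size else 0.0
    return SpikeData(t, i, n_neurons, duration_ms, dt_ms)


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

def moving_bump_spikes(grid: TorusGrid, *, speed: float = 0.05,
                       direction_rad: float = 0.0, duration_ms: float = 500.0,
                       rate_per_ms: float = 25.0, bump_sigma: float = 1.5,
                       start=(10.0, 10.0), seed: int = 0) -> SpikeData:
    """Spike train of a Gaussian activity bump moving at a known velocity.

    The bump center travels ``speed`` grid units/ms along
    ``direction_rad``; per 1 ms slice, Poisson(rate_per_ms) spikes are
    placed at Gaussian offsets around the center, rounded to neurons and
    wrapped on the torus.
    """
    rng = np.random.default_rng(seed)
    times, ids = [], []
    vx = speed * np.cos(direction_rad)
    vy = speed * np.sin(direction_rad)
    for t in range(int(duration_ms)):
        cx = start[0] + vx * t
        cy = start[1] + vy * t
        n = rng.poisson(rate_per_ms)
        xs = np.rint(cx + rng.normal(0, bump_sigma, n)).astype(int) % grid.ncol
        ys = np.rint(cy + rng.normal(0, bump_sigma, n)).astype(int) % grid.nrow
        times.append(t + np.sort(rng.uniform(0, 1, n)))
        ids.append(ys * grid.ncol + xs)
    t = np.concatenate(times)
    i = np.concatenate(ids)
    order = np.argsort(t, kind="stable")
    return SpikeData(t[order], i[order].astype(np.int32), grid.size, duration_ms,
                     0.1, meta={"kind": "moving-bump", "speed": speed,
                                "direction_rad": direction_rad, "seed": seed})


def sinusoid_rate_spikes(grid: TorusGrid, *, freq_hz: float = 60.0,
                         duration_ms: float = 2000.0, base_rate_hz: float = 20.0,
                         depth: float = 0.8, seed: int = 0) -> SpikeData:
    """Inhomogeneous-Poisson population whose rate oscillates at freq_hz."""
    rng = np.random.default_rng(seed)
    dt = 0.5  # ms
    t_axis = np.arange(0, duration_ms, dt)
    rate = base_rate_hz * (1 + depth * np.sin(2 * np.pi * freq_hz * t_axis / 1000.0))
    lam = rate * dt / 1000.0  # per-neuron per-slice expectation
    counts = rng.poisson(lam[:, None] * np.ones(grid.size), size=(t_axis.size, grid.size))
    slices, neurons = np.nonzero(counts)
    reps = counts[slices, neurons]
    t = np.repeat(t_axis[slices], reps) + rng.uniform(0, dt, reps.sum())
    i = np.repeat(neurons, reps)
    order = np.argsort(t, kind="stable")
    return SpikeData(t[order], i[order].astype(np.int32), grid.size, duration_ms,
                     0.1, meta={"kind": "sinusoid-rate", "freq_hz": freq_hz})


def make_fixture(kind: str, params: Optional[dict] = None, seed: int = 0,
                 out_dir=None):
    """Deterministic synthetic data for tests and scaled-down experiments.

    Kinds: 'toy-network' (30x30 inhibitory net with scaled connection
    count), 'moving-bump-spikes', 'stationary-bump-spikes',
    'sinusoid-rate'. With ``out_dir`` the fixture is also written to disk.
    """
    params = dict(params or {})
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    if kind == "toy-network":
        kw = dict(nrow=30, ncol=30, n_conn=90, configuration="perlin",
                  perlin_scale=10, shift=1)
        kw.update(params)
        obj = build_I_network(seed=seed, **kw)
        if out_dir is not None:
            save_network(obj, out_dir)
    elif kind == "moving-bump-spikes":
        grid = params.pop("grid", TorusGrid(40, 40))
        obj = moving_bump_spikes(grid, seed=seed, **params)
        if out_dir is not None:
            save_spikes(obj, Path(out_dir) / "spikes.csv")
    elif kind == "stationary-bump-spikes":
        grid = params.pop("grid", TorusGrid(40, 40))
        obj = moving_bump_spikes(grid, speed=0.0, seed=seed, **params)
        if out_dir is not None:
            save_spikes(obj, Path(out_dir) / "spikes.csv")
    elif kind == "sinusoid-rate":
        grid = params.pop("grid", TorusGrid(10, 10))
        obj = sinusoid_rate_spikes(grid, seed=seed, **params)
        if out_dir is not None:
            save_spikes(obj, Path(out_dir) / "spikes.csv")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return obj


# ---------------------------------------------------------------------------
# end-to-end experiment
# ---------------------------------------------------------------------------

def run_experiment(config: ExperimentConfig, out_dir) -> Path:
    """Build, simulate and analyze one configuration; write all outputs.

    The output directory receives the network, spikes, per-spike cluster
    labels, track tables, the Welch spectrum, a summary and a provenance
    manifest. A stage failure keeps earlier outputs and marks the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "status": "running", "stages": []}

    def checkpoint(stage):
        manifest["stages"].append(stage)
        (out / "manifest.json").write_text(json.dumps(manifest, default=str))

    try:
        net = config.build_network()
        save_network(net, out / "network", mtx=False)
        checkpoint("build")

        spikes = simulate(net, config.lif_params(), config.synapse_params(),
                          config.noise_input(), duration_ms=config.duration_ms,
                          dt_ms=config.dt_ms, seed=config.seed)
        save_spikes(spikes, out / "spikes.csv")
        checkpoint("simulate")

        ana = spikes.window(config.transient_ms, config.duration_ms)
        sig = population_rate(ana.times_ms, ana.ids,
                              duration_ms=config.duration_ms,
                              t0_ms=config.transient_ms)
        spec = welch_spectrum(sig)
        pd.DataFrame({"frequency_hz": spec.frequency_hz, "power": spec.power}
                     ).to_csv(out / "spectrum.csv", index=False)
        band = tuple(config.spectral.get("band_hz",
                                         (20.0, 100.0) if config.model == "I"
                                         else (15.0, 80.0)))
        checkpoint("spectrum")

        grid = net.grids[net.populations[0]]
        pos = grid.positions()
        npop0 = grid.size
        local = ana.ids < npop0  # cluster the anisotropy-carrying population
        cp = config.cluster_params()
        cs = cluster_spikes(ana.times_ms[local], pos[ana.ids[local], 0],
                            pos[ana.ids[local], 1], grid, cp)
        pd.DataFrame({"time_ms": cs.times_ms, "x": cs.x, "y": cs.y,
                      "cluster": cs.labels}).to_csv(out / "labels.csv", index=False)
        tracks = tracks_from_clusters(cs)
        rows = []
        for tr in tracks:
            for k in range(tr.alpha.size):
                rows.append((tr.cluster_id, tr.t_ms[k + 1], tr.x[k + 1],
                             tr.y[k + 1], tr.alpha[k], tr.speed[k]))
        pd.DataFrame(rows, columns=["cluster", "t_ms", "x", "y", "alpha", "speed"]
                     ).to_csv(out / "tracks.csv", index=False)
        counts = count_sequences(cs, t0_ms=config.transient_ms)
        checkpoint("sequences")

        analysis_s = (config.duration_ms - config.transient_ms) / 1000.0
        summary = {
            "n_spikes": int(spikes.n_spikes),
            "mean_rate_hz": float(ana.n_spikes / ana.n_neurons / analysis_s),
            "peak_frequency_hz": peak_frequency(spec, band),
            "n_clusters": int(cs.cluster_ids.size),
            "sequences_per_epoch": counts.tolist(),
        }
        (out / "summary.json").write_text(json.dumps(summary))
        manifest["status"] = "ok"
        manifest["summary"] = summary
        checkpoint("summary")
    except Exception as exc:  # pragma: no cover - forensic path
        manifest["status"] = "failed"
        manifest["error"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, default=str))
        raise
    return out
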