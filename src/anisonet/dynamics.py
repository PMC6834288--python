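"""Fixed-step simulation of LIF neurons with alpha-function current synapses.

Membrane dynamics: C_m dv/dt = -g_L (v - E_L) + I_syn(t) + I_ext(t), with
threshold/reset spiking and an absolute refractory period. A presynaptic
spike at t0 injects, after the synaptic delay, an alpha-shaped current
transient I(t) = J * e * ((t - t0)/tau_syn) * exp(-(t - t0)/tau_syn), whose
peak equals the amplitude parameter J (reached at t - t0 = tau_syn). With
the default parameters (C_m = 250 pF, tau_m = 10 ms, tau_syn = 5 ms) the
base amplitude J_x = 10 pA produces a unitary PSP of ~0.22 mV.

External drive is Gaussian white noise: an independent current value
mu + sigma * xi is drawn per neuron per integration step (standard
deviation exactly sigma, no 1/sqrt(dt) scaling); ``noise_dt_ms`` can
lengthen the hold interval between redraws.

The linear subthreshold system is integrated exactly (propagator-based) at
dt = 0.1 ms by default; see :mod:`anisonet._kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from ._kernels import run_lif
from .network import Network

__all__ = [
    "LIFParams",
    "SynapseParams",
    "NoiseInput",
    "StimulusProtocol",
    "SpikeData",
    "EvokedResult",
    "simulate",
    "psp_peak",
    "calibrate_weight",
    "select_stimulus_block",
    "run_evoked_protocol",
]


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire neuron parameters (defaults: both models)."""

    c_m_pF: float = 250.0
    g_l_nS: float = 25.0
    e_l_mV: float = -70.0
    v_th_mV: float = -55.0
    v_reset_mV: float = -70.0
    t_ref_ms: float = 2.0

    def __post_init__(self):
        if self.v_reset_mV >= self.v_th_mV:
            raise ValueError("v_reset must be below v_th")

    @property
    def tau_m_ms(self) -> float:
        return self.c_m_pF / self.g_l_nS


@dataclass(frozen=True)
class SynapseParams:
    """Alpha-current synapse parameters (identical time constants)."""

    tau_exc_ms: float = 5.0
    tau_inh_ms: float = 5.0
    j_x_pA: float = 10.0
    delay_ms: float = 1.0


@dataclass(frozen=True)
class NoiseInput:
    """Gaussian white-noise current drive, piecewise constant."""

    mu_pA: float = 0.0
    sigma_pA: float = 0.0
    noise_dt_ms: float = 0.1

    def __post_init__(self):
        if self.sigma_pA < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class StimulusProtocol:
    """Repeated DC current injection into a fixed set of neurons."""

    neuron_ids: np.ndarray
    amplitude_pA: float = 500.0
    duration_ms: float = 50.0
    n_trials: int = 20
    inter_trial_ms: float = 1000.0
    onsets_ms: Optional[np.ndarray] = None

    def resolve_onsets(self, warmup_ms: float) -> np.ndarray:
        if self.onsets_ms is not None:
            return np.asarray(self.onsets_ms, dtype=float)
        return warmup_ms + self.inter_trial_ms * np.arange(self.n_trials)


@dataclass
class SpikeData:
    """Recorded spike events, sorted by time, plus simulation metadata."""

    times_ms: np.ndarray
    ids: np.ndarray
    n_neurons: int
    duration_ms: float
    dt_ms: float
    meta: dict = dc_field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return self.times_ms.size

    def window(self, t0_ms: float, t1_ms: float) -> "SpikeData":
        m = (self.times_ms >= t0_ms) & (self.times_ms < t1_ms)
        return SpikeData(self.times_ms[m], self.ids[m], self.n_neurons,
                         self.duration_ms, self.dt_ms, dict(self.meta))

    def counts_per_neuron(self) -> np.ndarray:
        return np.bincount(self.ids, minlength=self.n_neurons)

    def rates_hz(self) -> np.ndarray:
        return self.counts_per_neuron() / (self.duration_ms / 1000.0)


@dataclass
class EvokedResult:
    """Outcome of the repeated-stimulation experiment."""

    n_trials: int
    evoked: np.ndarray  # bool per trial
    reaction_times_ms: np.ndarray  # nan where no stimulated spike occurred
    lifespans_ms: np.ndarray  # nan for non-evoked trials

    @property
    def c_e(self) -> int:
        return int(self.evoked.sum())

    @property
    def probability(self) -> float:
        return self.c_e / self.n_trials


def simulate(network: Network, lif: LIFParams = LIFParams(),
             syn: SynapseParams = SynapseParams(),
             noise: NoiseInput = NoiseInput(), *, duration_ms: float,
             dt_ms: float = 0.1, seed: int = 0,
             stimulus: Optional[StimulusProtocol] = None,
             warmup_ms: float = 0.0, init: str = "reset",
             v_init: Optional[np.ndarray] = None) -> SpikeData:
    """Simulate the network and return recorded spikes.

    ``init='reset'`` starts all membranes at E_L; ``init='uniform'`` draws
    v(0) uniformly in [v_reset, v_th). ``warmup_ms`` only positions default
    stimulus onsets; no spikes are discarded here (analysis routines
    discard transients themselves).
    """
    if syn.tau_exc_ms != syn.tau_inh_ms:
        raise NotImplementedError("kernel assumes tau_exc == tau_inh")
    delay_steps = syn.delay_ms / dt_ms
    if abs(delay_steps - round(delay_steps)) > 1e-9:
        raise ValueError(f"dt={dt_ms} must divide the synaptic delay {syn.delay_ms}")
    delay_steps = int(round(delay_steps))
    noise_steps = max(1, int(round(noise.noise_dt_ms / dt_ms)))
    n_steps = int(round(duration_ms / dt_ms))
    n = network.n_total

    indptr, flat, w = network.flat_connectivity()
    tau_s = syn.tau_exc_ms
    w_scaled = w * np.e / tau_s  # impulse on y1 so the current peak equals J

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if v_init is not None:
        v0 = np.asarray(v_init, dtype=float).copy()
    elif init == "uniform":
        v0 = rng.uniform(lif.v_reset_mV, lif.v_th_mV, size=n)
    else:
        v0 = np.full(n, lif.e_l_mV)

    stim_amp = np.zeros(n)
    if stimulus is not None:
        onsets = stimulus.resolve_onsets(warmup_ms)
        stim_amp[np.asarray(stimulus.neuron_ids, dtype=int)] = stimulus.amplitude_pA
        starts = np.rint(onsets / dt_ms).astype(np.int64)
        stops = np.rint((onsets + stimulus.duration_ms) / dt_ms).astype(np.int64)
    else:
        starts = np.empty(0, dtype=np.int64)
        stops = np.empty(0, dtype=np.int64)

    capacity = int(max(10_000, n * duration_ms / 1000.0 * 50))  # ~50 Hz headroom
    kernel_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    times, ids, v_final = run_lif(
        n_steps, dt_ms, indptr.astype(np.int64), flat, w_scaled, delay_steps,
        lif.tau_m_ms, lif.c_m_pF, lif.e_l_mV, lif.v_th_mV, lif.v_reset_mV,
        int(round(lif.t_ref_ms / dt_ms)), tau_s,
        noise.mu_pA, noise.sigma_pA, noise_steps, stim_amp, starts, stops,
        v0, kernel_seed, capacity)
    if times.size and not np.all(np.isfinite(v_final)):
        raise FloatingPointError("non-finite membrane state at end of simulation")
    return SpikeData(times, ids, n, duration_ms, dt_ms,
                     meta={"seed": seed, "mu_pA": noise.mu_pA,
                           "sigma_pA": noise.sigma_pA,
                           "noise_dt_ms": noise.noise_dt_ms,
                           "v_final": v_final,
                           "model": network.meta.get("model"),
                           "configuration": network.configuration})


# ---------------------------------------------------------------------------
# unitary PSP and weight calibration
# ---------------------------------------------------------------------------

def _psp_deflection(t, j_pA, lif: LIFParams, tau_syn_ms: float):
    """Analytic membrane deflection (mV) after a single alpha-current event.

    Solution of the linear membrane equation driven by
    I(t) = J e (t/tau_s) exp(-t/tau_s) from rest.
    """
    tau_m = lif.tau_m_ms
    a = 1.0 / tau_syn_ms - 1.0 / tau_m
    y10 = j_pA * np.e / tau_syn_ms
    t = np.asarray(t, dtype=float)
    if abs(a) < 1e-12:
        core = t * t / 2.0
    else:
        core = (1.0 - (1.0 + a * t) * np.exp(-a * t)) / (a * a)
    return (y10 / lif.c_m_pF) * np.exp(-t / tau_m) * core


def psp_peak(j_pA: float, lif: LIFParams = LIFParams(),
             tau_syn_ms: float = 5.0) -> float:
    """Peak deflection (mV) of a resting neuron to one synaptic event of
    amplitude parameter ``j_pA`` (signed)."""
    if j_pA == 0:
        return 0.0
    horizon = 10.0 * max(tau_syn_ms, lif.tau_m_ms)
    grid = np.linspace(0.0, horizon, 2000)
    vals = _psp_deflection(grid, abs(j_pA), lif, tau_syn_ms)
    t0 = grid[int(np.argmax(vals))]
    res = minimize_scalar(lambda t: -_psp_deflection(t, abs(j_pA), lif, tau_syn_ms),
                          bounds=(max(t0 - 1.0, 0.0), t0 + 1.0), method="bounded")
    return float(np.sign(j_pA) * -res.fun)


def calibrate_weight(target_psp_mV: float, lif: LIFParams = LIFParams(),
                     tau_syn_ms: float = 5.0) -> float:
    """Amplitude J (pA) producing the requested unitary PSP peak (mV).

    The PSP is linear in J, so a single unit-amplitude evaluation suffices.
    """
    if target_psp_mV <= 0:
        raise ValueError("target PSP must be positive")
    return target_psp_mV / psp_peak(1.0, lif, tau_syn_ms)


# ---------------------------------------------------------------------------
# evoked-sequence protocol
# ---------------------------------------------------------------------------

def select_stimulus_block(network: Network, n_neurons: int = 50,
                          center: Optional[tuple] = None, pop: Optional[str] = None
                          ) -> np.ndarray:
    """Global ids of ~n_neurons mutually neighboring neurons (excitatory in
    EI networks), the ``n_neurons`` nearest to ``center`` on the torus."""
    if pop is None:
        pop = network.populations[0]
    g = network.grids[pop]
    if center is None:
        center = (g.ncol / 2.0, g.nrow / 2.0)
    pos = g.positions()
    from .network import _wrap_delta
    d2 = (_wrap_delta(pos[:, 0] - center[0], g.ncol) ** 2
          + _wrap_delta(pos[:, 1] - center[1], g.nrow) ** 2)
    local = np.argsort(d2, kind="stable")[:n_neurons]
    return np.sort(local) + network.pop_offset(pop)


def _has_spike_cluster(times: np.ndarray, k: int, window_ms: float) -> bool:
    """True if any ``window_ms`` sub-window holds >= k of the given spikes."""
    if times.size < k:
        return False
    t = np.sort(times)
    return bool(np.any(t[k - 1:] - t[:t.size - k + 1] <= window_ms))


def run_evoked_protocol(network: Network, background: NoiseInput,
                        stim: StimulusProtocol, *, lif: LIFParams = LIFParams(),
                        syn: SynapseParams = SynapseParams(), seed: int = 0,
                        dt_ms: float = 0.1, warmup_ms: float = 200.0,
                        k_spikes: int = 10, cluster_window_ms: float = 10.0,
                        response_window_ms: float = 50.0,
                        spikes: Optional[SpikeData] = None) -> EvokedResult:
    """Repeatedly stimulate a neighboring group and score evoked sequences.

    A trial counts as evoked when the stimulated neurons fire a spike
    cluster (>= ``k_spikes`` spikes within any ``cluster_window_ms``) inside
    ``response_window_ms`` after stimulus onset AND no such cluster occurred
    in the ``response_window_ms`` before onset. Reaction time is the first
    stimulated-neuron spike after onset; lifespan is last minus first spike
    of the evoked cluster episode (stimulated-set spikes from onset until
    activity lapses for more than ``cluster_window_ms``).
    """
    onsets = stim.resolve_onsets(warmup_ms)
    if spikes is None:
        duration = float(onsets[-1] + stim.inter_trial_ms)
        spikes = simulate(network, lif, syn, background, duration_ms=duration,
                          dt_ms=dt_ms, seed=seed, stimulus=stim,
                          warmup_ms=warmup_ms)
    stim_ids = np.asarray(stim.neuron_ids, dtype=int)
    mask = np.isin(spikes.ids, stim_ids)
    st = spikes.times_ms[mask]

    n_trials = len(onsets)
    evoked = np.zeros(n_trials, dtype=bool)
    reaction = np.full(n_trials, np.nan)
    lifespan = np.full(n_trials, np.nan)
    for k, t0 in enumerate(onsets):
        pre = st[(st >= t0 - response_window_ms) & (st < t0)]
        post = st[(st >= t0) & (st < t0 + response_window_ms)]
        after = st[st >= t0]
        if post.size:
            reaction[k] = post[0] - t0
        ok = (_has_spike_cluster(post, k_spikes, cluster_window_ms)
              and not _has_spike_cluster(pre, k_spikes, cluster_window_ms))
        evoked[k] = ok
        if ok:
            # follow the evoked episode until a gap longer than the cluster window
            t = np.sort(after)
            gaps = np.diff(t)
            stop = np.argmax(gaps > cluster_window_ms) if np.any(
                gaps > cluster_window_ms) else t.size - 1
            lifespan[k] = t[stop] - t[0]
    if n_trials < stim.n_trials:
        raise ValueError(f"recorded {n_trials} trials, protocol requires {stim.n_trials}")
    return EvokedResult(n_trials, evoked, reaction, lifespan)
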