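"""Spectra of summed population spiking activity.

The population rate is the spike count of a neuron selection in 5 ms bins
(sampling rate 200 Hz), z-scored. Power spectra use Welch's method with
nfft = 4096 (Hann window, segments of at most 1024 samples, 50% overlap);
spectrograms use 200 ms epochs overlapping by 50 ms. Selections follow the
three published sampling schemes: the whole population, 100 random neurons,
or the neurons of a 10x10 region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .network import TorusGrid

__all__ = [
    "RateSignal",
    "Spectrum",
    "select_neurons",
    "population_rate",
    "welch_spectrum",
    "spectrogram",
    "peak_frequency",
]

BIN_MS = 5.0
FS_HZ = 1000.0 / BIN_MS
NFFT = 4096


@dataclass
class RateSignal:
    """Z-scored binned population spike counts."""

    z: np.ndarray
    counts: np.ndarray
    fs_hz: float
    n_neurons: int
    selection: str = "all"

    @property
    def bin_ms(self) -> float:
        return 1000.0 / self.fs_hz


@dataclass
class Spectrum:
    frequency_hz: np.ndarray
    power: np.ndarray
    meta: dict = field(default_factory=dict)


def select_neurons(grid: TorusGrid, selection: str, *, seed: int = 0,
                   region_corner=(0, 0), region_size: int = 10,
                   n_random: int = 100, offset: int = 0) -> np.ndarray:
    """Neuron ids for a sampling scheme: 'all', 'random' or 'region'.

    ``offset`` shifts local grid ids to global ids for multi-population
    networks. The region selection takes a ``region_size`` x ``region_size``
    block with top-left (row, col) at ``region_corner``, wrapped.
    """
    if selection == "all":
        ids = np.arange(grid.size)
    elif selection == "random":
        rng = np.random.default_rng(seed)
        ids = rng.choice(grid.size, size=n_random, replace=False)
    elif selection == "region":
        r0, c0 = region_corner
        rows = (np.arange(region_size) + r0) % grid.nrow
        cols = (np.arange(region_size) + c0) % grid.ncol
        ids = (rows[:, None] * grid.ncol + cols[None, :]).ravel()
    else:
        raise ValueError(f"unknown selection {selection!r}")
    return np.sort(ids) + offset


def population_rate(times_ms: np.ndarray, ids: np.ndarray, duration_ms: float,
                    neuron_ids: Optional[np.ndarray] = None, *,
                    bin_ms: float = BIN_MS, t0_ms: float = 0.0,
                    selection: str = "all") -> RateSignal:
    """Summed, z-scored spike counts of the selected neurons in 5 ms bins."""
    times_ms = np.asarray(times_ms, dtype=float)
    ids = np.asarray(ids)
    if neuron_ids is not None:
        neuron_ids = np.asarray(neuron_ids)
        if neuron_ids.size == 0:
            raise ValueError("empty neuron selection")
        keep = np.isin(ids, neuron_ids)
        times_ms = times_ms[keep]
        n_sel = neuron_ids.size
    else:
        n_sel = int(ids.max()) + 1 if ids.size else 0
    n_bins = int(np.ceil((duration_ms - t0_ms) / bin_ms))
    if n_bins < 2:
        raise ValueError("signal too short")
    edges = t0_ms + np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(times_ms, bins=edges)
    sd = counts.std()
    z = (counts - counts.mean()) / sd if sd > 0 else np.zeros_like(counts, dtype=float)
    return RateSignal(z=z, counts=counts.astype(np.int64), fs_hz=1000.0 / bin_ms,
                      n_neurons=n_sel, selection=selection)


def welch_spectrum(sig: RateSignal, *, nfft: int = NFFT,
                   max_nperseg: int = 1024) -> Spectrum:
    """Welch periodogram of the z-scored rate signal."""
    n = sig.z.size
    nperseg = min(n, max_nperseg)
    if nperseg < 8:
        raise ValueError("signal too short for a Welch segment")
    f, p = sps.welch(sig.z, fs=sig.fs_hz, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, nfft=max(nfft, nperseg),
                     detrend="constant", scaling="density")
    return Spectrum(f, p, meta={"nperseg": nperseg, "nfft": nfft,
                                "selection": sig.selection})


def spectrogram(sig: RateSignal, *, epoch_ms: float = 200.0,
                overlap_ms: float = 50.0, nfft: int = NFFT):
    """Per-epoch spectra of the rate signal.

    Epochs of ``epoch_ms`` advance by ``epoch_ms - overlap_ms``; the number
    of epochs for a signal of duration T ms is
    floor((T - epoch) / (epoch - overlap)) + 1.

    Returns (frequency_hz, epoch_centers_ms, power[freq, epoch]).
    """
    nperseg = int(round(epoch_ms / sig.bin_ms))
    noverlap = int(round(overlap_ms / sig.bin_ms))
    if sig.z.size < nperseg:
        raise ValueError("signal shorter than one epoch")
    f, t, p = sps.spectrogram(sig.z, fs=sig.fs_hz, window="hann",
                              nperseg=nperseg, noverlap=noverlap,
                              nfft=max(nfft, nperseg), detrend="constant",
                              scaling="density")
    return f, t * 1000.0, p


def peak_frequency(spec: Spectrum, band_hz=(20.0, 100.0)) -> float:
    """Frequency of maximal power inside a band."""
    lo, hi = band_hz
    m = (spec.frequency_hz >= lo) & (spec.frequency_hz <= hi)
    if not np.any(m):
        raise ValueError(f"band {band_hz} contains no frequency bins")
    f = spec.frequency_hz[m]
    return float(f[int(np.argmax(spec.power[m]))])
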