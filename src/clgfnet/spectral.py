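"""Complex Morlet time-frequency analysis and band powers.

The transform convolves each channel with complex Morlet wavelets

    w_f(t) = c * exp(i 2 pi f t) * exp(-t^2 / (2 sigma_t^2)),
    sigma_t = width / (2 pi f),

one per frequency on a 13-80 Hz grid (1 Hz steps by default, resolving
the 30/31 Hz beta/gamma boundary), with width = 7 cycles.  Wavelets are
discretely L2-normalised (unit energy), the convention shared by the
common M/EEG toolboxes; only magnitudes |W| are used downstream and all
comparisons are relative, so the normalisation constant is a fixed,
documented choice rather than a physical one.

"Power" throughout this package means the wavelet magnitude |W| —
channel-averaged as mean over channels of |W| (never |mean W|).  The
first and last 3 wavelet standard deviations of the slowest wavelet are
flagged as edge-contaminated and excluded from scalar (time-averaged)
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .signals import SignalSet

__all__ = [
    "TimeFrequencyMap",
    "BandPowerSeries",
    "morlet_tf",
    "band_power",
    "mean_spectrum",
    "BETA_BAND",
    "GAMMA_BAND",
]

#: beta band limits in Hz, inclusive on both ends
BETA_BAND = (13.0, 30.0)
#: gamma band limits in Hz: (30, 80], disjoint from beta by construction
GAMMA_BAND = (30.0, 80.0)


@dataclass
class TimeFrequencyMap:
    """|Morlet coefficient| over frequency x time.

    ``values`` has shape (n_freqs, n_times) when channel-averaged or for
    a single channel, and (n_channels, n_freqs, n_times) otherwise.
    ``edge_mask`` flags time columns contaminated by the convolution
    boundary (True = contaminated).
    """

    values: np.ndarray
    freqs: np.ndarray
    dt: float  # time step in ms
    edge_mask: np.ndarray
    width: float = 7.0

    @property
    def is_averaged(self) -> bool:
        return self.values.ndim == 2

    def channel_average(self) -> "TimeFrequencyMap":
        if self.is_averaged:
            return self
        return TimeFrequencyMap(self.values.mean(axis=0), self.freqs,
                                self.dt, self.edge_mask, self.width)

    def channel_sum(self) -> "TimeFrequencyMap":
        """Sum of per-channel magnitudes (e.g. total circuit power)."""
        if self.is_averaged:
            return self
        return TimeFrequencyMap(self.values.sum(axis=0), self.freqs,
                                self.dt, self.edge_mask, self.width)

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("tf", data=self.values)
            f.create_dataset("freqs", data=self.freqs)
            f.create_dataset("dt", data=self.dt)
            f.create_dataset("edge_mask", data=self.edge_mask)
            f.create_dataset("width", data=self.width)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "TimeFrequencyMap":
        with h5py.File(path, "r") as f:
            return cls(f["tf"][()], f["freqs"][()], float(f["dt"][()]),
                       f["edge_mask"][()].astype(bool), float(f["width"][()]))


@dataclass
class BandPowerSeries:
    """Beta and gamma band power (band-mean |W|) versus time."""

    beta: np.ndarray
    gamma: np.ndarray
    dt: float  # ms per step
    edge_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.beta.shape != self.gamma.shape:
            raise ValueError("beta and gamma series must be the same length")

    @property
    def beta_scalar(self) -> float:
        """Time-averaged beta power, edge-contaminated samples excluded."""
        return float(self.beta[~self.edge_mask].mean())

    @property
    def gamma_scalar(self) -> float:
        return float(self.gamma[~self.edge_mask].mean())


def _morlet_kernel(freq: float, fs: float, width: float) -> np.ndarray:
    sigma_t = width / (2.0 * np.pi * freq)  # seconds
    half = int(np.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kern = np.exp(2j * np.pi * freq * t) * np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    return kern / np.linalg.norm(kern)


def morlet_tf(
    signals: SignalSet,
    freqs: np.ndarray | None = None,
    width: float = 7.0,
    average_channels: bool = True,
) -> TimeFrequencyMap:
    """Magnitude Morlet transform of every channel.

    Parameters
    ----------
    freqs
        Frequency grid in Hz; default 13..80 in 1 Hz steps.
    width
        Wavelet width in cycles (sigma_t = width / 2 pi f); must be >= 1.
    average_channels
        If True return the channel mean of |W| (2-D map); otherwise the
        full (channels, freqs, times) array.
    """
    if width < 1:
        raise ValueError(f"wavelet width must be >= 1, got {width}")
    freqs = np.arange(13.0, 81.0) if freqs is None else np.asarray(freqs, dtype=float)
    if freqs.size == 0 or np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be non-empty and strictly increasing")
    nyq = signals.fs / 2.0
    if freqs.max() >= nyq:
        raise ValueError(f"max frequency {freqs.max()} Hz >= Nyquist {nyq} Hz")
    if freqs.min() <= 0:
        raise ValueError("frequencies must be positive")

    n_ch, n_t = signals.n_channels, signals.n_samples
    out = np.empty((n_ch, freqs.size, n_t))
    for fi, f in enumerate(freqs):
        kern = _morlet_kernel(f, signals.fs, width)
        for ci in range(n_ch):
            out[ci, fi] = np.abs(fftconvolve(signals.data[ci], kern, mode="same"))

    # edge contamination: 3 sigma_t of the slowest (widest) wavelet
    n_edge = int(np.ceil(3.0 * width / (2.0 * np.pi * freqs.min()) * signals.fs))
    edge = np.zeros(n_t, dtype=bool)
    edge[:min(n_edge, n_t)] = True
    edge[max(n_t - n_edge, 0):] = True

    dt = 1000.0 / signals.fs
    if average_channels:
        return TimeFrequencyMap(out.mean(axis=0), freqs, dt, edge, width)
    return TimeFrequencyMap(out, freqs, dt, edge, width)


def _band_rows(freqs: np.ndarray, band: tuple[float, float], *,
               include_low: bool) -> np.ndarray:
    low, high = band
    if include_low:
        sel = (freqs >= low) & (freqs <= high)
    else:
        sel = (freqs > low) & (freqs <= high)
    if not sel.any():
        raise ValueError(f"band {band} contains no grid frequencies")
    return sel


def band_power(
    tf: TimeFrequencyMap,
    beta: tuple[float, float] = BETA_BAND,
    gamma: tuple[float, float] = GAMMA_BAND,
) -> BandPowerSeries:
    """Per-time band means of the map over the beta and gamma rows.

    Beta includes both band edges; gamma is open at its lower edge so the
    two bands partition the 13-80 Hz grid.  Requires a 2-D (averaged or
    single-channel) map.
    """
    if not tf.is_averaged:
        raise ValueError("band_power needs a 2-D map; average or sum channels first")
    b = _band_rows(tf.freqs, beta, include_low=True)
    g = _band_rows(tf.freqs, gamma, include_low=False)
    return BandPowerSeries(tf.values[b].mean(axis=0), tf.values[g].mean(axis=0),
                           tf.dt, tf.edge_mask)


def mean_spectrum(tf: TimeFrequencyMap) -> pd.DataFrame:
    """Time-averaged power per frequency (edge columns excluded).

    Returns a DataFrame with columns ``freq_hz, power``.
    """
    m = tf.channel_average() if not tf.is_averaged else tf
    keep = ~m.edge_mask
    if not keep.any():  # record shorter than twice the edge margin
        keep = np.ones_like(m.edge_mask)
    return pd.DataFrame({"freq_hz": m.freqs, "power": m.values[:, keep].mean(axis=1)})
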