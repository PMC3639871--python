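"""Multichannel signal container and on-disk formats.

A :class:`SignalSet` is the package's in-memory representation of a
multichannel recording: a ``(n_channels, n_samples)`` float array with a
sampling rate and channel labels, emulating e.g. the 102 magnetometers of
an Elekta MEG system sampled at 1000 Hz.  Persistence goes through HDF5
(``/data``, ``/fs``, ``/channel_names``) or plain delimited text with one
row per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SignalSet",
    "read_region_map",
    "write_region_map",
]


@dataclass
class SignalSet:
    """Channels x samples matrix with sampling metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    channel_names
        One label per channel; defaults to ``ch000, ch001, ...``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "SignalSet":
        return SignalSet(self.data.copy(), self.fs, list(self.channel_names))

    # ------------------------------------------------------------------ IO
    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("fs", data=float(self.fs))
            f.create_dataset(
                "channel_names",
                data=np.array(self.channel_names, dtype=h5py.string_dtype()),
            )

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "SignalSet":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            fs = float(f["fs"][()])
            names = [n.decode() if isinstance(n, bytes) else str(n) for n in f["channel_names"][()]]
        return cls(data, fs, names)

    def to_text(self, path: str | Path, sep: str = "\t") -> None:
        """One row per channel, channel name in the first column."""
        df = pd.DataFrame(self.data, index=self.channel_names)
        df.insert(0, "fs", self.fs)
        df.to_csv(path, sep=sep, header=False)

    @classmethod
    def from_text(cls, path: str | Path, sep: str = "\t") -> "SignalSet":
        df = pd.read_csv(path, sep=sep, header=None, index_col=0)
        fs = float(df.iloc[0, 0])
        data = df.iloc[:, 1:].to_numpy(dtype=np.float64)
        return cls(data, fs, [str(i) for i in df.index])


def read_region_map(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Read a two-column ``channel, region`` table into a dict."""
    df = pd.read_csv(path, sep=sep, header=None, names=["channel", "region"])
    return dict(zip(df["channel"].astype(str), df["region"].astype(str)))


def write_region_map(rmap: dict[str, str], path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(sorted(rmap.items())).to_csv(path, sep=sep, header=False, index=False)
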