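"""In-memory containers and HDF5 serialisation for epoched EEG.

Conventions
-----------
* Voltages are microvolts throughout.
* The epoch time axis is half-open: ``[tmin, tmax)`` sampled at ``srate``,
  so an epoch from −1000 to +1200 ms at 512 Hz holds
  ``floor(2.2 * 512) = 1126`` samples.
* Millisecond windows map to sample indices by flooring both endpoints,
  yielding half-open index ranges ``[lo, hi)``.
* Trials from all subjects share one trial axis; the ``design`` table
  carries the subject id of each row, so per-subject trial counts may
  differ (e.g. after artifact rejection).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .montage import CHANNELS_64

SRATE_DEFAULT = 512.0
TMIN_MS_DEFAULT = -1000.0
TMAX_MS_DEFAULT = 1200.0


def n_samples_for(tmin_ms: float, tmax_ms: float, srate: float) -> int:
    """Sample count of the half-open epoch ``[tmin, tmax)``."""
    return int(np.floor((tmax_ms - tmin_ms) / 1000.0 * srate))


def ms_to_sample(t_ms: float, tmin_ms: float, srate: float) -> int:
    """Floor-mapping of a millisecond instant to a sample index."""
    return int(np.floor((t_ms - tmin_ms) / 1000.0 * srate))


def window_slice(window_ms, tmin_ms: float, srate: float,
                 n_samples: int | None = None) -> slice:
    """Half-open sample slice for the ms window ``[w0, w1)``.

    Both endpoints are floored, so e.g. [−500, −260) ms at 512 Hz in an
    epoch starting at −1000 ms becomes samples [256, 378) — 122 samples.
    """
    w0, w1 = window_ms
    if w1 <= w0:
        raise ValueError(f"empty window {window_ms}")
    lo = ms_to_sample(w0, tmin_ms, srate)
    hi = ms_to_sample(w1, tmin_ms, srate)
    if lo < 0 or (n_samples is not None and hi > n_samples):
        raise ValueError(f"window {window_ms} ms outside epoch")
    return slice(lo, hi)


@dataclass
class EpochSet:
    """Epoched multi-channel EEG with aligned trial metadata.

    Attributes
    ----------
    data
        ``(n_trials, n_channels, n_samples)`` float array, µV.
    srate
        Sampling rate in Hz.
    tmin_ms
        Time of the first sample relative to face onset, ms.
    channels
        Channel names matching the channel axis.
    design
        One row per trial (same order as the trial axis); must at least
        carry ``subject``; typically also ``emotion``, ``fnmes``, ``choice``.
    log
        Provenance: ordered records of the operations applied.
    """

    data: np.ndarray
    design: pd.DataFrame
    srate: float = SRATE_DEFAULT
    tmin_ms: float = TMIN_MS_DEFAULT
    channels: list[str] = field(default_factory=lambda: list(CHANNELS_64))
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if len(self.design) != self.data.shape[0]:
            raise ValueError("design row count does not match trial axis")

    # -- axes ------------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.n_samples) * 1000.0 / self.srate

    def window_slice(self, window_ms) -> slice:
        return window_slice(window_ms, self.tmin_ms, self.srate, self.n_samples)

    def channel_index(self, subset) -> np.ndarray:
        from .montage import channel_index
        return channel_index(self.channels, subset)

    # -- bookkeeping -----------------------------------------------------
    def with_data(self, data: np.ndarray, entry: dict | None = None,
                  design: pd.DataFrame | None = None) -> "EpochSet":
        """Copy with new data (and optionally subset design), appending a
        log entry."""
        log = list(self.log) + ([entry] if entry else [])
        return EpochSet(
            data=data,
            design=(self.design if design is None else design).reset_index(drop=True),
            srate=self.srate,
            tmin_ms=self.tmin_ms,
            channels=list(self.channels),
            log=log,
        )

    def copy(self) -> "EpochSet":
        return self.with_data(self.data.copy())

    # -- IO ---------------------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip",
                             compression_opts=1)
            f.create_dataset("time", data=self.times_ms)
            f.create_dataset(
                "channels",
                data=np.array(self.channels, dtype=h5py.string_dtype()))
            f.attrs["srate"] = self.srate
            f.attrs["tmin_ms"] = self.tmin_ms
            f.create_dataset(
                "design",
                data=np.frombuffer(
                    self.design.to_json(orient="table").encode(), dtype="u1"))
            f.create_dataset(
                "log", data=np.frombuffer(json.dumps(self.log).encode(),
                                          dtype="u1"))

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            data = f["data"][...]
            channels = [c.decode() if isinstance(c, bytes) else str(c)
                        for c in f["channels"][...]]
            design = pd.read_json(
                __import__("io").StringIO(bytes(f["design"][...]).decode()),
                orient="table")
            log = json.loads(bytes(f["log"][...]).decode())
            return cls(data=data, design=design, srate=float(f.attrs["srate"]),
                       tmin_ms=float(f.attrs["tmin_ms"]), channels=channels,
                       log=log)
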