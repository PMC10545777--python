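"""Dual-channel fiber-photometry files, recordings and normalization.

A raw file holds three columns sampled on one clock: time (s), the
sensor-dependent fluorescence channel and the isosbestic control channel
(excited at a wavelength where the sensor is calcium-independent, so it
carries the shared motion/bleaching artifacts but not the biological
transients).  Acquisition is frequently paused between behavioral periods,
so one file can hold several discontinuous recordings; these are split at
time gaps and processed independently, because bleaching levels differ
between segments.

Two normalizations are provided:

* ``"F"`` -- fractional change dF/F0.  The control channel is scaled onto the
  signal channel with an ordinary least-squares fit ``signal ~ a*iso + b``
  (the channels are strongly correlated outside transients), and
  ``dF/F0 = (signal - fitted) / fitted``.
* ``"Z"`` -- Z-difference: each channel standardized by its own
  recording-wide mean and sample SD, then subtracted,
  ``z(signal) - z(isosbestic)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "RawFiberFile",
    "Recording",
    "NormalizedSignal",
    "read_fiber_csv",
    "read_fiber_hdf5",
    "split_recordings",
    "compute_dff",
    "compute_zdiff",
    "normalize",
    "write_normalized_csv",
]


@dataclass
class RawFiberFile:
    """One photometry file: time (s), signal and isosbestic vectors."""

    source: str
    time: np.ndarray
    signal: np.ndarray
    isosbestic: np.ndarray
    dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.isosbestic = np.asarray(self.isosbestic, dtype=float)
        n = self.time.size
        if n < 2 or self.signal.size != n or self.isosbestic.size != n:
            raise ValueError(f"{self.source}: need >= 2 rows with equal-length columns")
        if np.any(np.diff(self.time) < 0):
            raise ValueError(f"{self.source}: time vector must be monotone non-decreasing")


@dataclass
class Recording:
    """One contiguous segment of a photometry file (1-based index)."""

    index: int
    time: np.ndarray
    signal: np.ndarray
    isosbestic: np.ndarray

    @property
    def sampling_rate(self) -> float:
        """Estimated rate in Hz: (n - 1) / timespan."""
        return (self.time.size - 1) / (self.time[-1] - self.time[0])

    @property
    def start(self) -> float:
        return float(self.time[0])

    @property
    def end(self) -> float:
        return float(self.time[-1])

    def contains(self, t: float) -> bool:
        return self.start <= t <= self.end


@dataclass
class NormalizedSignal:
    """A recording's normalized trace with its method tag.

    ``method`` is ``"F"`` (dF/F0) or ``"Z"`` (Z-difference); for ``"F"`` the
    least-squares coefficients ``(a, b)`` of the control fit are kept.
    """

    recording: Recording
    method: str
    values: np.ndarray
    coefficients: tuple[float, float] | None = None

    @property
    def time(self) -> np.ndarray:
        return self.recording.time


def _finite_rows(source, time, signal, iso):
    mask = np.isfinite(time) & np.isfinite(signal) & np.isfinite(iso)
    dropped = int((~mask).sum())
    if dropped:
        warnings.warn(f"{source}: {dropped} non-finite rows dropped", stacklevel=3)
    return time[mask], signal[mask], iso[mask], dropped


def read_fiber_csv(path, config) -> RawFiberFile:
    """Read a photometry CSV using the configured column mapping."""
    cols = config.fiber.columns
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [cols[k] for k in ("time", "signal", "isosbestic") if cols[k] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mapped columns {missing}; found {list(df.columns)}")
    time = pd.to_numeric(df[cols["time"]], errors="coerce").to_numpy(float)
    sig = pd.to_numeric(df[cols["signal"]], errors="coerce").to_numpy(float)
    iso = pd.to_numeric(df[cols["isosbestic"]], errors="coerce").to_numpy(float)
    time, sig, iso, dropped = _finite_rows(path, time, sig, iso)
    if time.size < 2:
        raise ValueError(f"{path}: fewer than 2 valid rows")
    return RawFiberFile(str(path), time, sig, iso, dropped)


def read_fiber_hdf5(path, config) -> RawFiberFile:
    """Read a photometry HDF5 container using configured dataset paths."""
    paths = config.fiber.hdf5_paths
    arrays = {}
    with h5py.File(path, "r") as f:
        for key in ("time", "signal", "isosbestic"):
            dset = f.get(paths[key])
            if dset is None:
                raise ValueError(f"{path}: missing HDF5 dataset {paths[key]!r}")
            arr = np.asarray(dset[()], dtype=float).ravel()
            if arr.size == 0:
                raise ValueError(f"{path}: empty HDF5 dataset {paths[key]!r}")
            arrays[key] = arr
    time, sig, iso, dropped = _finite_rows(path, arrays["time"], arrays["signal"], arrays["isosbestic"])
    if time.size < 2:
        raise ValueError(f"{path}: fewer than 2 valid rows")
    return RawFiberFile(str(path), time, sig, iso, dropped)


def split_recordings(raw: RawFiberFile, gap_threshold_s: float = 1.0, min_length_s: float = 5.0) -> list[Recording]:
    """Split a file into contiguous recordings at time gaps.

    A new recording starts wherever the inter-sample interval is strictly
    greater than ``gap_threshold_s``.  Segments spanning less than
    ``min_length_s`` (or with fewer than 2 samples) are discarded with a
    warning.  Kept recordings are numbered 1..K in temporal order.
    """
    cuts = np.flatnonzero(np.diff(raw.time) > gap_threshold_s) + 1
    bounds = np.concatenate(([0], cuts, [raw.time.size]))
    recordings: list[Recording] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s < 2 or raw.time[e - 1] - raw.time[s] < min_length_s:
            warnings.warn(
                f"{raw.source}: segment of {e - s} samples "
                f"({raw.time[e - 1] - raw.time[s]:.3f} s) below minimum length, discarded",
                stacklevel=2,
            )
            continue
        recordings.append(
            Recording(
                index=len(recordings) + 1,
                time=raw.time[s:e].copy(),
                signal=raw.signal[s:e].copy(),
                isosbestic=raw.isosbestic[s:e].copy(),
            )
        )
    return recordings


def compute_dff(rec: Recording) -> NormalizedSignal:
    """dF/F0 by least-squares scaling of the isosbestic control.

    Fits ``signal ~ a*iso + b`` on this recording only and returns
    ``(signal - fitted) / fitted`` with the coefficients stored.  A
    zero-variance control channel or a non-positive fitted baseline is fatal.
    """
    iso = rec.isosbestic
    sig = rec.signal
    if np.ptp(iso) == 0:
        raise ValueError("degenerate control channel: isosbestic has zero variance")
    a, b = np.polyfit(iso, sig, 1)
    fitted = a * iso + b
    bad = np.flatnonzero(fitted <= 0)
    if bad.size:
        raise ValueError(f"fitted isosbestic non-positive at sample {int(bad[0])}")
    return NormalizedSignal(rec, "F", (sig - fitted) / fitted, coefficients=(float(a), float(b)))


def compute_zdiff(rec: Recording) -> NormalizedSignal:
    """Z-difference: z(signal) - z(isosbestic), recording-wide sample SD."""
    sd_s = rec.signal.std(ddof=1)
    sd_i = rec.isosbestic.std(ddof=1)
    if sd_s == 0 or sd_i == 0:
        raise ValueError("zero standard deviation in signal or isosbestic channel")
    z_s = (rec.signal - rec.signal.mean()) / sd_s
    z_i = (rec.isosbestic - rec.isosbestic.mean()) / sd_i
    return NormalizedSignal(rec, "Z", z_s - z_i)


def normalize(rec: Recording, method: str) -> NormalizedSignal:
    """Dispatch on the method tag: ``"F"`` -> dF/F0, ``"Z"`` -> Z-difference."""
    if method == "F":
        return compute_dff(rec)
    if method == "Z":
        return compute_zdiff(rec)
    raise ValueError(f"unknown normalization method {method!r}; expected 'F' or 'Z'")


def write_normalized_csv(ns: NormalizedSignal, path) -> None:
    pd.DataFrame({"time_s": ns.time, "value": ns.values, "method": ns.method}).to_csv(path, index=False)
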