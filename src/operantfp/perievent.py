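"""Event-aligned epochs: extraction, baseline renormalization, summaries.

An epoch is the excerpt of a normalized trace inside a window
``[-pre, +post]`` around one behavioral event, expressed on a relative time
grid (0 = the event).  The pre-event span serves as the baseline for two
renormalizations:

* perievent Z-score: ``(x - mean(baseline)) / SD(baseline)``;
* robust Z-score:   ``(x - median(baseline)) / MAD(baseline)``, insensitive
  to baseline outliers such as spontaneous transients.

Epochs whose window does not fit inside a recording, or whose baseline has
zero spread, are *rejected* with a reason (they surface in the exclusion
report of a batch run, never silently dropped).

For group averaging, epochs recorded at slightly different rates are
linearly interpolated onto one uniform grid spanning the common window with
the maximum sample count among the epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .transients import PeakParams, PeakStats, detect_peaks, mad, peak_stats

__all__ = [
    "EpochRejected",
    "Epoch",
    "PerieventSummary",
    "EpochRow",
    "Exclusion",
    "PerieventResult",
    "extract_epoch",
    "zscore_epoch",
    "robust_zscore_epoch",
    "interpolate_epochs",
    "summarize_epoch",
]


class EpochRejected(Exception):
    """Raised when an epoch cannot be analyzed; carries the reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class Epoch:
    """One event-aligned excerpt of a normalized signal."""

    event_time: float
    rel_time: np.ndarray  # strictly increasing, spans [-pre, +post]
    values: np.ndarray
    method: str  # normalization tag inherited from the trace ("F" | "Z")
    window: tuple[float, float]  # (pre_s, post_s), both positive
    sample_slice: tuple[int, int] | None = None  # index range in the recording

    @property
    def baseline(self) -> np.ndarray:
        """Values strictly before the event (relative time < 0)."""
        return self.values[self.rel_time < 0]


def extract_epoch(trace, event_time: float, window: tuple[float, float]) -> Epoch:
    """Cut the window ``[event - pre, event + post]`` out of a trace.

    ``trace`` is a :class:`~operantfp.fiber.NormalizedSignal`.  The window
    must lie entirely inside the trace's recording, otherwise the epoch is
    rejected (:class:`EpochRejected`, reason ``"window outside recording"``).
    """
    pre, post = float(window[0]), float(window[1])
    if pre <= 0 or post <= 0:
        raise ValueError("window spans must be positive")
    t = trace.time
    if event_time - pre < t[0] or event_time + post > t[-1]:
        raise EpochRejected("window outside recording")
    i0 = int(np.searchsorted(t, event_time - pre, side="left"))
    i1 = int(np.searchsorted(t, event_time + post, side="right"))
    rel = t[i0:i1] - event_time
    values = trace.values[i0:i1]
    if not np.any(rel < 0):
        raise EpochRejected("empty baseline")
    return Epoch(
        event_time=float(event_time),
        rel_time=rel.copy(),
        values=np.asarray(values, dtype=float).copy(),
        method=trace.method,
        window=(pre, post),
        sample_slice=(i0, i1),
    )


def zscore_epoch(e: Epoch) -> np.ndarray:
    """Perievent Z-scores against the pre-event baseline (sample SD)."""
    base = e.baseline
    sd = base.std(ddof=1) if base.size > 1 else 0.0
    if sd == 0:
        raise EpochRejected("zero baseline standard deviation")
    return (e.values - base.mean()) / sd


def robust_zscore_epoch(e: Epoch) -> np.ndarray:
    """Robust perievent Z-scores: median/MAD of the pre-event baseline."""
    base = e.baseline
    m = mad(base)
    if m == 0:
        raise EpochRejected("zero baseline MAD")
    return (e.values - np.median(base)) / m


def interpolate_epochs(epochs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Put epochs on one uniform grid and average them.

    All epochs must share the same window.  The grid spans ``[-pre, +post]``
    uniformly with the maximum sample count among the epochs; each epoch is
    linearly interpolated onto it.

    Returns ``(grid, signals, mean_trace)`` where ``signals`` has one row
    per epoch and ``mean_trace`` is their pointwise mean.
    """
    epochs = list(epochs)
    if not epochs:
        raise ValueError("need at least one epoch")
    window = epochs[0].window
    if any(e.window != window for e in epochs):
        raise ValueError("epochs have mixed windows; cannot share a grid")
    n = max(e.values.size for e in epochs)
    grid = np.linspace(-window[0], window[1], n)
    signals = np.vstack([np.interp(grid, e.rel_time, e.values) for e in epochs])
    return grid, signals, signals.mean(axis=0)


@dataclass(frozen=True)
class PerieventSummary:
    """Per-epoch pre/post metrics.

    AUCs are trapezoid integrals over relative time in value*s (not
    time-normalized); averages are reported for the epoch's native
    normalization (``dF``), the baseline Z-scores and the robust Z-scores.
    Peak statistics come from the transient detector run on the epoch.
    Fields are NaN where undefined (degenerate baseline, no peaks).
    """

    preAUC: float
    postAUC: float
    preAVG_dF: float
    postAVG_dF: float
    preAVG_Z: float
    postAVG_Z: float
    preAVG_RZ: float
    postAVG_RZ: float
    pre_peak_frequency: float
    post_peak_frequency: float
    pre_peak_amplitude: float
    post_peak_amplitude: float


def summarize_epoch(e: Epoch, peak_params: PeakParams | None = None) -> PerieventSummary:
    """Compute the pre/post summary of one epoch.

    The split point is the event (relative time 0; the sample at 0 belongs
    to the post side, both integrals include it as shared boundary).
    """
    params = peak_params or PeakParams()
    rel = e.rel_time
    v = e.values
    pre_m, post_m = rel < 0, rel >= 0
    ipre, ipost = rel <= 0, rel >= 0

    def _avg(values: np.ndarray, mask: np.ndarray) -> float:
        return float(values[mask].mean()) if mask.any() else math.nan

    try:
        z = zscore_epoch(e)
        pre_z, post_z = _avg(z, pre_m), _avg(z, post_m)
    except EpochRejected:
        pre_z = post_z = math.nan
    try:
        rz = robust_zscore_epoch(e)
        pre_rz, post_rz = _avg(rz, pre_m), _avg(rz, post_m)
    except EpochRejected:
        pre_rz = post_rz = math.nan

    peaks = detect_peaks(rel, v, params)
    pre_stats: PeakStats = peak_stats(peaks, (-e.window[0], 0.0))
    post_stats: PeakStats = peak_stats(peaks, (0.0, e.window[1] + np.finfo(float).eps))

    return PerieventSummary(
        preAUC=float(np.trapezoid(v[ipre], rel[ipre])) if ipre.sum() > 1 else math.nan,
        postAUC=float(np.trapezoid(v[ipost], rel[ipost])) if ipost.sum() > 1 else math.nan,
        preAVG_dF=_avg(v, pre_m),
        postAVG_dF=_avg(v, post_m),
        preAVG_Z=pre_z,
        postAVG_Z=post_z,
        preAVG_RZ=pre_rz,
        postAVG_RZ=post_rz,
        pre_peak_frequency=pre_stats.frequency,
        post_peak_frequency=post_stats.frequency,
        pre_peak_amplitude=pre_stats.mean_amplitude,
        post_peak_amplitude=post_stats.mean_amplitude,
    )


@dataclass
class EpochRow:
    """One analyzed epoch of a batch run, with raw and processed arrays."""

    session_id: str
    behavior_file: str
    fiber_file: str
    event_time: float  # behavior clock
    rec_number: int
    sampling_rate: float
    epoch: Epoch
    zscores: np.ndarray
    rob_zscores: np.ndarray
    raw_signal: np.ndarray
    raw_control: np.ndarray
    summary: PerieventSummary


@dataclass(frozen=True)
class Exclusion:
    """One selected event that could not be analyzed, with the reason."""

    session_id: str
    behavior_file: str
    event_time: float
    reason: str


@dataclass
class PerieventResult:
    """Epochs collected across sessions plus the exclusion report."""

    rows: list[EpochRow]
    exclusions: list[Exclusion]
    window: tuple[float, float]
    norm: str
    _interp: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def epochs(self) -> list[Epoch]:
        return [r.epoch for r in self.rows]

    def interpolated(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(common grid, per-epoch interpolated signals, mean trace)."""
        if self._interp is None:
            self._interp = interpolate_epochs(self.epochs())
        return self._interp
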