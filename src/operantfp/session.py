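"""Single- and multi-session orchestration.

A *session* is a folder holding exactly one behavior file (``.dat``) and one
fiber file (``.csv`` or HDF5).  ``analyze`` runs the full chain on a batch of
sessions: parse the behavior log, derive intervals, select event times,
shift them onto the fiber clock, find the containing recording, normalize,
extract and renormalize the epoch, and summarize.  Every selected event is
accounted for exactly once -- either as an epoch row or as an entry in the
exclusion report (no containing recording, window crossing a recording edge,
degenerate baseline).

Behavior and fiber timestamps are assumed to share one clock unless a
per-session ``clock_offset`` (fiber minus behavior, seconds) is set on the
pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .behavior import BehaviorSession, derive_intervals, parse_generic_csv, parse_imetronic, select_events
from .config import AnalysisConfig, load_config
from .fiber import normalize, read_fiber_csv, read_fiber_hdf5, split_recordings
from .perievent import (
    EpochRejected,
    EpochRow,
    Exclusion,
    PerieventResult,
    extract_epoch,
    robust_zscore_epoch,
    summarize_epoch,
    zscore_epoch,
)

__all__ = [
    "SessionPair",
    "BatchRequest",
    "discover_sessions",
    "analyze",
    "result_table",
    "full_table",
    "write_full_data",
    "read_full_data",
    "export_result",
    "plot_perievent",
    "multibehavior_summary",
]

_FIBER_SUFFIXES = {".csv", ".h5", ".hdf5", ".doric"}


@dataclass
class SessionPair:
    """One session folder: its behavior file, fiber file and clock offset."""

    folder: str
    behavior_file: str
    fiber_file: str
    filetype: str = "imetronic"  # or "generic"
    clock_offset: float = 0.0  # fiber clock minus behavior clock, s

    @property
    def session_id(self) -> str:
        return Path(self.folder).name


@dataclass
class BatchRequest:
    """What to analyze: events, optional interval, window and normalization."""

    events: str | tuple[str, ...]
    within: str | None = None
    window: tuple[float, float] = (5.0, 5.0)
    norm: str = "F"
    selector: str = "all"
    k: int | None = None
    series_size: int | None = None
    reset_event: str | None = None

    def __post_init__(self) -> None:
        if not (self.window[0] > 0 and self.window[1] > 0):
            raise ValueError("window spans must be positive")
        if isinstance(self.events, str):
            self.events = (self.events,)
        else:
            self.events = tuple(self.events)


def discover_sessions(root, filetype: str = "imetronic") -> list[SessionPair]:
    """Find session folders under ``root``.

    A valid subfolder holds exactly one behavior ``.dat`` file and exactly
    one fiber file; anything else is skipped with a warning.  No valid
    subfolder at all is fatal.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"session root not found: {root}")
    pairs: list[SessionPair] = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        behavior = sorted(sub.glob("*.dat"))
        fiber = sorted(p for p in sub.iterdir() if p.suffix.lower() in _FIBER_SUFFIXES)
        if len(behavior) != 1 or len(fiber) != 1:
            warnings.warn(
                f"{sub}: expected exactly one behavior (.dat) and one fiber file, "
                f"found {len(behavior)} and {len(fiber)}; skipped",
                stacklevel=2,
            )
            continue
        pairs.append(SessionPair(str(sub), str(behavior[0]), str(fiber[0]), filetype=filetype))
    if not pairs:
        raise ValueError(f"{root}: no valid session subfolders")
    return pairs


def _parse_behavior(pair: SessionPair, config: AnalysisConfig) -> BehaviorSession:
    if pair.filetype == "imetronic":
        return parse_imetronic(pair.behavior_file, config)
    if pair.filetype == "generic":
        return parse_generic_csv(pair.behavior_file, config)
    raise ValueError(f"unknown filetype {pair.filetype!r}")


def _read_fiber(path: str, config: AnalysisConfig):
    if Path(path).suffix.lower() == ".csv":
        return read_fiber_csv(path, config)
    return read_fiber_hdf5(path, config)


def analyze(
    pairs: SessionPair | Iterable[SessionPair],
    req: BatchRequest,
    config: AnalysisConfig | None = None,
) -> PerieventResult:
    """Run perievent analysis for the requested events over session pairs.

    Only events occurring during fiber recordings are analyzed; the rest go
    to the exclusion report.  Requesting an event that occurs in no pair at
    all is fatal (the error reports per-pair counts).
    """
    config = config or load_config()
    if isinstance(pairs, SessionPair):
        pairs = [pairs]
    pairs = list(pairs)

    rows: list[EpochRow] = []
    exclusions: list[Exclusion] = []
    counts: dict[str, int] = {}
    for pair in pairs:
        sess = _parse_behavior(pair, config)
        sess = derive_intervals(sess, config.behavior.intervals.values())
        times: list[float] = []
        for name in req.events:
            times.extend(
                select_events(
                    sess,
                    name,
                    within=req.within,
                    selector=req.selector,
                    k=req.k,
                    series_size=req.series_size,
                    reset_event=req.reset_event,
                )
            )
        times = sorted(times)
        counts[pair.session_id] = len(times)
        if not times:
            continue

        raw = _read_fiber(pair.fiber_file, config)
        recordings = split_recordings(raw, config.fiber.gap_threshold_s, config.fiber.min_length_s)
        norm_cache: dict[int, object] = {}
        for t_beh in times:
            t_fib = t_beh + pair.clock_offset
            rec = next((r for r in recordings if r.contains(t_fib)), None)
            if rec is None:
                exclusions.append(
                    Exclusion(pair.session_id, pair.behavior_file, t_beh, "no containing recording")
                )
                continue
            if rec.index not in norm_cache:
                norm_cache[rec.index] = normalize(rec, req.norm)
            trace = norm_cache[rec.index]
            try:
                epoch = extract_epoch(trace, t_fib, req.window)
                z = zscore_epoch(epoch)
                rz = robust_zscore_epoch(epoch)
            except EpochRejected as err:
                exclusions.append(Exclusion(pair.session_id, pair.behavior_file, t_beh, err.reason))
                continue
            i0, i1 = epoch.sample_slice
            rows.append(
                EpochRow(
                    session_id=pair.session_id,
                    behavior_file=pair.behavior_file,
                    fiber_file=pair.fiber_file,
                    event_time=float(t_beh),
                    rec_number=rec.index,
                    sampling_rate=float(rec.sampling_rate),
                    epoch=epoch,
                    zscores=z,
                    rob_zscores=rz,
                    raw_signal=rec.signal[i0:i1].copy(),
                    raw_control=rec.isosbestic[i0:i1].copy(),
                    summary=summarize_epoch(epoch, config.transients),
                )
            )
    if sum(counts.values()) == 0:
        raise ValueError(
            f"no event of type {req.events} found in any pair (per-session counts: {counts})"
        )
    return PerieventResult(rows=rows, exclusions=exclusions, window=req.window, norm=req.norm)


def result_table(res: PerieventResult) -> pd.DataFrame:
    """One summary row per epoch (the ``.data``-style table)."""
    if not res.rows:
        raise ValueError("empty perievent result")
    records = []
    for r in res.rows:
        s = r.summary
        records.append(
            {
                "behavior_file": r.behavior_file,
                "event_time": r.event_time,
                "fiber_file": r.fiber_file,
                "normalization": res.norm,
                "preAUC": s.preAUC,
                "postAUC": s.postAUC,
                "PreAVG_RZ": s.preAVG_RZ,
                "PostAVG_RZ": s.postAVG_RZ,
                "PreAVG_Z": s.preAVG_Z,
                "PostAVG_Z": s.postAVG_Z,
                "preAVG_dF": s.preAVG_dF,
                "postAVG_dF": s.postAVG_dF,
                "pre_peak_frequency": s.pre_peak_frequency,
                "post_peak_frequency": s.post_peak_frequency,
                "pre_peak_amplitude": s.pre_peak_amplitude,
                "post_peak_amplitude": s.post_peak_amplitude,
            }
        )
    return pd.DataFrame.from_records(records)


def full_table(res: PerieventResult) -> pd.DataFrame:
    """Per-epoch container of raw and processed arrays (``.full_data``)."""
    records = []
    for r in res.rows:
        records.append(
            {
                "raw_control": r.raw_control,
                "raw_signal": r.raw_signal,
                "rec_number": r.rec_number,
                "rel_time": r.epoch.rel_time,
                "values": r.epoch.values,
                "zscores": r.zscores,
                "rob_zscores": r.rob_zscores,
                "sampling_rate": r.sampling_rate,
            }
        )
    return pd.DataFrame.from_records(records)


def write_full_data(res: PerieventResult, path) -> None:
    """Serialize the per-epoch arrays to HDF5 (bit-exact round trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["norm"] = res.norm
        f.attrs["pre_s"] = res.window[0]
        f.attrs["post_s"] = res.window[1]
        for i, r in enumerate(res.rows):
            g = f.create_group(f"epoch_{i:04d}")
            g.attrs.update(
                {
                    "session_id": r.session_id,
                    "behavior_file": r.behavior_file,
                    "fiber_file": r.fiber_file,
                    "event_time": r.event_time,
                    "rec_number": r.rec_number,
                    "sampling_rate": r.sampling_rate,
                }
            )
            for name, arr in (
                ("rel_time", r.epoch.rel_time),
                ("values", r.epoch.values),
                ("zscores", r.zscores),
                ("rob_zscores", r.rob_zscores),
                ("raw_signal", r.raw_signal),
                ("raw_control", r.raw_control),
            ):
                g.create_dataset(name, data=arr)


def read_full_data(path) -> list[dict]:
    """Load epochs written by :func:`write_full_data` as a list of dicts."""
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(k for k in f.keys() if k.startswith("epoch_")):
            g = f[key]
            d = {name: np.asarray(g[name][()]) for name in g.keys()}
            d.update({k: g.attrs[k] for k in g.attrs})
            out.append(d)
    return out


def export_result(res: PerieventResult, outdir) -> dict[str, Path]:
    """Write summary, interpolated traces and exclusions as CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    summary = outdir / "summary.csv"
    result_table(res).to_csv(summary, index=False)
    paths["summary"] = summary

    grid, signals, mean = res.interpolated()
    interp = pd.DataFrame(signals.T, columns=[f"epoch_{i}" for i in range(signals.shape[0])])
    interp.insert(0, "rel_time", grid)
    interp["mean"] = mean
    ipath = outdir / "interpolated.csv"
    interp.to_csv(ipath, index=False)
    paths["interpolated"] = ipath

    epath = outdir / "exclusions.csv"
    pd.DataFrame(
        [
            {
                "session_id": e.session_id,
                "behavior_file": e.behavior_file,
                "event_time": e.event_time,
                "reason": e.reason,
            }
            for e in res.exclusions
        ],
        columns=["session_id", "behavior_file", "event_time", "reason"],
    ).to_csv(epath, index=False)
    paths["exclusions"] = epath
    return paths


def plot_perievent(res: PerieventResult, out) -> None:
    """Render individual interpolated traces (light) and the mean (black).

    A dashed vertical marker indicates the event at relative time 0.
    """
    if not res.rows:
        raise ValueError("cannot plot an empty perievent result")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    grid, signals, mean = res.interpolated()
    fig, ax = plt.subplots(figsize=(7.0, 4.0))
    for sig in signals:
        ax.plot(grid, sig, linewidth=0.8, alpha=0.6)
    ax.plot(grid, mean, color="black", linewidth=2.0, label="mean")
    ax.axvline(0.0, color="grey", linestyle="--", linewidth=1.0)
    ax.set_xlabel("time from event (s)")
    ax.set_ylabel({"F": "dF/F0", "Z": "Z-difference"}.get(res.norm, res.norm))
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def multibehavior_summary(
    files: Sequence[str],
    config: AnalysisConfig | None = None,
    filetype: str = "imetronic",
) -> pd.DataFrame:
    """Per-session event counts and total interval durations.

    One row per file, with a ``n_<event>`` column for every configured (or
    observed) event name and a ``dur_<interval>`` column per derived
    interval name (total seconds).
    """
    config = config or load_config()
    records = []
    for path in files:
        pair = SessionPair(str(Path(path).parent), str(path), fiber_file="", filetype=filetype)
        sess = _parse_behavior(pair, config)
        sess = derive_intervals(sess, config.behavior.intervals.values())
        names = sorted(set(config.behavior.events) | set(sess.event_names()))
        row: dict = {"file": str(path)}
        for name in names:
            row[f"n_{name}"] = int(sess.event_times(name).size)
        for iv_name in sess.interval_names():
            row[f"dur_{iv_name}"] = float(sum(iv.duration for iv in sess.intervals_named(iv_name)))
        records.append(row)
    return pd.DataFrame.from_records(records).fillna(0.0)
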