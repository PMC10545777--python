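"""Ground-truth generators for operant sessions and photometry recordings.

Every pipeline stage can be exercised without any real data: the behavior
generator emulates a fixed-ratio self-administration session (default: the
cocaine protocol -- three 40 min drug periods signaled by LED2, alternating
with two 15 min no-drug periods signaled by the house light; FR5; cue light
1 s after the completing nose-poke for 4 s; injection 1 s after cue onset; a
40 s post-injection time-out during which pokes are recorded but have no
consequences).  The photometry generator emulates the statistical
assumptions of the normalization and detection steps: a bleaching baseline,
calcium-like transients on the signal channel only, a shared additive
artifact on both channels, and independent channel noise.

All randomness flows from one seeded generator per template; the emitted
files and the returned ground truth are consistent by construction, and the
parsers reproduce the truth tables exactly (event times are quantized to
1 ms before being written).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .behavior import diff_spans

__all__ = [
    "SessionTemplate",
    "PhotometryTemplate",
    "GroundTruth",
    "simulate_behavior",
    "simulate_photometry",
    "write_imetronic",
    "write_generic",
    "write_fiber_csv",
    "write_fiber_hdf5",
    "make_session_dir",
    "kernel_time_to_peak",
]

#: (family, code) per event name, consistent with the default configuration's
#: integer-row patterns.
_CODE_MAP = {
    "np1": (2, 1),
    "np2": (2, 2),
    "lk1": (3, 1),
    "inj1": (6, 1),
    "led1_on": (4, 11),
    "led1_off": (4, 10),
    "led2_on": (4, 21),
    "led2_off": (4, 20),
    "hled_on": (4, 31),
    "hled_off": (4, 30),
}

_DEFAULT_COLUMNS = {
    "time": "Time(s)",
    "signal": "AIn-1 - Dem (AOut-1)",
    "isosbestic": "AIn-1 - Dem (AOut-2)",
}
_DEFAULT_H5_PATHS = {"time": "time", "signal": "signal", "isosbestic": "isosbestic"}


def _q(t: float) -> float:
    """Quantize a time to the 1 ms grid (exactly representable round trip)."""
    return round(t * 1000.0) / 1000.0


@dataclass(frozen=True)
class SessionTemplate:
    """Parameters of a simulated operant session.

    The defaults reproduce the cocaine self-administration protocol:
    D(40 min) N(15 min) D(40 min) N(15 min) D(40 min) period structure, FR5,
    40 s time-out, cue 1 s after series completion for 4 s, injection 1 s
    after cue onset.  Response rates are homogeneous Poisson rates per
    period type (responses/s); the drug-period rate of 0.02/s yields on the
    order of ten injections per 40 min period, a typical maintenance level.
    """

    periods: tuple[tuple[str, float], ...] = (
        ("drug", 2400.0),
        ("nodrug", 900.0),
        ("drug", 2400.0),
        ("nodrug", 900.0),
        ("drug", 2400.0),
    )
    ratio: int = 5
    timeout_s: float = 40.0
    cue_latency_s: float = 1.0
    cue_duration_s: float = 4.0
    pump_latency_s: float = 1.0  # injection onset after cue onset
    np1_rate_drug: float = 0.02
    np1_rate_nodrug: float = 0.005
    np2_rate: float = 0.003
    lk1_rate: float = 0.0
    led2_off_during_timeout: bool = False
    seed: int = 0


@dataclass(frozen=True)
class PhotometryTemplate:
    """Parameters of a simulated dual-channel recording.

    Transients are difference-of-exponentials kernels (rise/decay time
    constants sized for a fast calcium indicator: ~50 ms time-to-peak) whose
    additive height is ``amplitude * local baseline``, so ``amplitude`` is
    expressed in dF/F units.  Spontaneous transient amplitudes are
    log-normal (heavy tail, exercising the robust statistics); event-locked
    transients place their *peak* at ``event_time + latency``.
    """

    sampling_rate: float = 1000.0
    blocks: tuple[tuple[float, float], ...] = ((0.0, 60.0),)  # (start, duration)
    baseline: float = 0.15  # a.u., demodulated detector output scale
    bleach_tau_s: float = 2000.0
    iso_scale: float = 0.85
    iso_offset: float = 0.01
    rise_tau_s: float = 0.02
    decay_tau_s: float = 0.2
    spont_rate: float = 0.1  # transients/s
    amp_median: float = 0.03  # dF/F units
    amp_sigma: float = 0.4  # log-normal shape
    event_locked: tuple[tuple[str, float, float], ...] = ()  # (event, latency_s, amplitude)
    transient_times: tuple[float, ...] | None = None  # explicit onsets override spont_rate
    transient_amps: tuple[float, ...] | None = None
    artifact_sd: float = 0.002
    artifact_tau_s: float = 0.5
    noise_sd_signal: float = 0.001
    noise_sd_iso: float = 0.001
    seed: int = 0


@dataclass
class GroundTruth:
    """Truth tables matching the emitted files by construction."""

    events: pd.DataFrame  # columns: name, time
    intervals: pd.DataFrame  # columns: name, start, end
    session_end: float
    seed: int
    transients: pd.DataFrame | None = None  # onset, peak_time, amplitude, kind
    blocks: tuple[tuple[float, float], ...] | None = None
    iso_coefficients: tuple[float, float] | None = None  # true (a, b) of signal ~ a*iso + b

    def event_times(self, name: str) -> np.ndarray:
        return self.events.loc[self.events["name"] == name, "time"].to_numpy(float)

    def interval_spans(self, name: str) -> list[tuple[float, float]]:
        sub = self.intervals[self.intervals["name"] == name]
        return list(zip(sub["start"].tolist(), sub["end"].tolist()))

    def save(self, path) -> None:
        """Persist the truth as one JSON file."""
        payload = {
            "seed": self.seed,
            "session_end": self.session_end,
            "events": self.events.to_dict(orient="list"),
            "intervals": self.intervals.to_dict(orient="list"),
            "transients": None if self.transients is None else self.transients.to_dict(orient="list"),
            "blocks": None if self.blocks is None else [list(b) for b in self.blocks],
            "iso_coefficients": None if self.iso_coefficients is None else list(self.iso_coefficients),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            events=pd.DataFrame(d["events"]),
            intervals=pd.DataFrame(d["intervals"]),
            session_end=d["session_end"],
            seed=d["seed"],
            transients=None if d["transients"] is None else pd.DataFrame(d["transients"]),
            blocks=None if d["blocks"] is None else tuple(tuple(b) for b in d["blocks"]),
            iso_coefficients=None if d["iso_coefficients"] is None else tuple(d["iso_coefficients"]),
        )


# --------------------------------------------------------------------------
# Behavior
# --------------------------------------------------------------------------


def simulate_behavior(tmpl: SessionTemplate) -> GroundTruth:
    """Draw one operant session from a template (deterministic given seed)."""
    rng = np.random.default_rng(tmpl.seed)

    periods = []
    t0 = 0.0
    for kind, dur in tmpl.periods:
        if dur <= 0:
            raise ValueError("period durations must be positive")
        periods.append((kind, t0, t0 + dur))
        t0 += dur
    scheduled_end = t0
    drug_spans = [(s, e) for kind, s, e in periods if kind == "drug"]
    nodrug_spans = [(s, e) for kind, s, e in periods if kind == "nodrug"]

    events: list[tuple[str, float]] = []
    for s, e in nodrug_spans:
        events += [("hled_on", _q(s)), ("hled_off", _q(e))]

    def _poisson_times(rate: float, s: float, e: float) -> list[float]:
        n = rng.poisson(rate * (e - s))
        return sorted(_q(t) for t in rng.uniform(s, e, n))

    np1: list[float] = []
    for kind, s, e in periods:
        rate = tmpl.np1_rate_drug if kind == "drug" else tmpl.np1_rate_nodrug
        np1 += _poisson_times(rate, s, e)
    np1.sort()
    np2 = _poisson_times(tmpl.np2_rate, 0.0, scheduled_end)
    lk1 = _poisson_times(tmpl.lk1_rate, 0.0, scheduled_end) if tmpl.lk1_rate > 0 else []

    counter = 0
    timeout_end = -math.inf
    inj_times: list[float] = []
    timeouts: list[tuple[float, float]] = []
    for t in np1:
        events.append(("np1", t))
        if not any(s <= t < e for s, e in drug_spans):
            continue
        if t < timeout_end:
            continue  # recorded but without consequence
        counter += 1
        if counter == tmpl.ratio:
            counter = 0
            cue_on = _q(t + tmpl.cue_latency_s)
            cue_off = _q(cue_on + tmpl.cue_duration_s)
            inj = _q(cue_on + tmpl.pump_latency_s)
            events += [("led1_on", cue_on), ("led1_off", cue_off), ("inj1", inj)]
            inj_times.append(inj)
            timeout_end = inj + tmpl.timeout_s
            timeouts.append((inj, _q(inj + tmpl.timeout_s)))
    events += [("np2", t) for t in np2]
    events += [("lk1", t) for t in lk1]

    # LED2 marks the scheduled drug periods; optionally the light is switched
    # off during post-injection time-outs (darkness-switch scenario).
    led2_spans = list(drug_spans)
    if tmpl.led2_off_during_timeout:
        led2_spans = diff_spans(drug_spans, timeouts)
    led2_spans = [(_q(s), _q(e)) for s, e in led2_spans if _q(e) > _q(s)]
    for s, e in led2_spans:
        events += [("led2_on", s), ("led2_off", e)]

    ev_df = pd.DataFrame(sorted(events, key=lambda x: (x[1], x[0])), columns=["name", "time"])
    iv_rows = (
        [("DRUG", _q(s), _q(e)) for s, e in drug_spans]
        + [("NODRUG", _q(s), _q(e)) for s, e in nodrug_spans]
        + [("HLED_ON", _q(s), _q(e)) for s, e in nodrug_spans]
        + [("LED2_ON", s, e) for s, e in led2_spans]
        + [("TIMEOUT", s, e) for s, e in timeouts]
    )
    iv_df = pd.DataFrame(iv_rows, columns=["name", "start", "end"])
    end = max(
        [scheduled_end]
        + ([float(ev_df["time"].max())] if len(ev_df) else [])
        + ([float(iv_df["end"].max())] if len(iv_df) else [])
    )
    return GroundTruth(events=ev_df, intervals=iv_df, session_end=end, seed=tmpl.seed)


def write_imetronic(truth: GroundTruth, path) -> None:
    """Emit the integer-coded tab-separated dialect for a simulated session.

    A few rig housekeeping rows (family 9) are included at the top; they
    match no configured event pattern and exercise the parser's unmatched-row
    accounting.
    """
    lines = ["0\t9\t1\t0\t0", "0\t9\t2\t0\t0"]
    for i, (name, t) in enumerate(truth.events.itertuples(index=False), start=1):
        fam, code = _CODE_MAP[name]
        lines.append(f"{int(round(t * 1000.0))}\t{fam}\t{code}\t0\t{i}")
    lines.append(f"{int(round(truth.session_end * 1000.0))}\t9\t3\t0\t0")
    Path(path).write_text("\n".join(lines) + "\n")


def write_generic(truth: GroundTruth, path) -> None:
    """Emit the generic comma-separated event table (.dat) for a session."""
    names = sorted(truth.events["name"].unique())
    columns = {n: [f"{t:.3f}" for t in truth.event_times(n)] for n in names}
    depth = max((len(v) for v in columns.values()), default=0)
    lines = [",".join(names)]
    for i in range(depth):
        lines.append(",".join(columns[n][i] if i < len(columns[n]) else "" for n in names))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Photometry
# --------------------------------------------------------------------------


def kernel_time_to_peak(rise_tau_s: float, decay_tau_s: float) -> float:
    """Time-to-peak of the difference-of-exponentials transient kernel."""
    r, d = rise_tau_s, decay_tau_s
    if not 0 < r < d:
        raise ValueError("need 0 < rise_tau < decay_tau")
    return math.log(d / r) * r * d / (d - r)


def _kernel(dt: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Peak-normalized difference-of-exponentials kernel, zero for dt < 0."""
    k = np.where(dt >= 0, np.exp(-np.maximum(dt, 0) / decay) - np.exp(-np.maximum(dt, 0) / rise), 0.0)
    tp = kernel_time_to_peak(rise, decay)
    kmax = math.exp(-tp / decay) - math.exp(-tp / rise)
    return k / kmax


def simulate_photometry(
    truth: GroundTruth, tmpl: PhotometryTemplate
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Simulate the dual-channel recording for a session's truth.

    Returns ``(time, signal, isosbestic, truth)`` with the truth extended by
    the transient table, the recording blocks and the true linear relation
    between the channels' baselines.  The signal channel is::

        baseline * exp(-t / tau_bleach) + transients + artifact + noise

    and the isosbestic channel is the same bleaching baseline scaled and
    offset, plus the *same* artifact and its own noise -- but no transients,
    matching the assumption that outside depolarization events the two
    channels are strongly correlated.
    """
    rng = np.random.default_rng(tmpl.seed)
    fs = tmpl.sampling_rate
    tp = kernel_time_to_peak(tmpl.rise_tau_s, tmpl.decay_tau_s)

    # Transient onsets and amplitudes (dF/F units).
    onsets: list[float] = []
    amps: list[float] = []
    kinds: list[str] = []
    if tmpl.transient_times is not None:
        onsets = [float(t) for t in tmpl.transient_times]
        if tmpl.transient_amps is not None:
            amps = [float(a) for a in tmpl.transient_amps]
        else:
            amps = list(rng.lognormal(math.log(tmpl.amp_median), tmpl.amp_sigma, len(onsets)))
        kinds = ["spontaneous"] * len(onsets)
    elif tmpl.spont_rate > 0:
        for b0, dur in tmpl.blocks:
            n = rng.poisson(tmpl.spont_rate * dur)
            ts = np.sort(rng.uniform(b0, b0 + dur, n))
            onsets += ts.tolist()
            amps += rng.lognormal(math.log(tmpl.amp_median), tmpl.amp_sigma, n).tolist()
            kinds += ["spontaneous"] * n
    for name, latency, amp in tmpl.event_locked:
        for t_ev in truth.event_times(name):
            onset = float(t_ev) + latency - tp  # kernel peak lands at latency
            onsets.append(onset)
            amps.append(float(amp))
            kinds.append(f"locked:{name}")

    times, signals, isos = [], [], []
    for b0, dur in tmpl.blocks:
        n = int(round(dur * fs)) + 1
        t = b0 + np.arange(n) / fs
        base = tmpl.baseline * np.exp(-t / tmpl.bleach_tau_s)
        trans = np.zeros(n)
        horizon = 8.0 * tmpl.decay_tau_s
        for onset, amp in zip(onsets, amps):
            if onset > t[-1] or onset + horizon < t[0]:
                continue
            i0 = int(np.searchsorted(t, onset))
            i1 = int(np.searchsorted(t, onset + horizon))
            local_base = tmpl.baseline * math.exp(-max(onset, t[0]) / tmpl.bleach_tau_s)
            trans[i0:i1] += amp * local_base * _kernel(t[i0:i1] - onset, tmpl.rise_tau_s, tmpl.decay_tau_s)
        if tmpl.artifact_sd > 0:
            rho = math.exp(-1.0 / (fs * tmpl.artifact_tau_s))
            eps = rng.normal(0.0, tmpl.artifact_sd * math.sqrt(1 - rho**2), n)
            artifact = lfilter([1.0], [1.0, -rho], eps)
        else:
            artifact = np.zeros(n)
        noise_s = rng.normal(0.0, tmpl.noise_sd_signal, n) if tmpl.noise_sd_signal > 0 else 0.0
        noise_i = rng.normal(0.0, tmpl.noise_sd_iso, n) if tmpl.noise_sd_iso > 0 else 0.0
        times.append(t)
        signals.append(base + trans + artifact + noise_s)
        isos.append(tmpl.iso_scale * base + tmpl.iso_offset + artifact + noise_i)

    tr_df = pd.DataFrame(
        {
            "onset": onsets,
            "peak_time": [o + tp for o in onsets],
            "amplitude": amps,
            "kind": kinds,
        }
    ).sort_values("onset", ignore_index=True)
    out = dataclasses.replace(
        truth,
        transients=tr_df,
        blocks=tuple((float(b0), float(d)) for b0, d in tmpl.blocks),
        iso_coefficients=(1.0 / tmpl.iso_scale, -tmpl.iso_offset / tmpl.iso_scale),
    )
    return np.concatenate(times), np.concatenate(signals), np.concatenate(isos), out


def write_fiber_csv(time, signal, isosbestic, path, columns: dict | None = None) -> None:
    """Write the three channels as CSV (default column names match the
    default configuration's mapping; full float precision is preserved)."""
    cols = columns or _DEFAULT_COLUMNS
    pd.DataFrame({cols["time"]: time, cols["signal"]: signal, cols["isosbestic"]: isosbestic}).to_csv(
        path, index=False
    )


def write_fiber_hdf5(time, signal, isosbestic, path, paths: dict | None = None) -> None:
    import h5py

    p = paths or _DEFAULT_H5_PATHS
    with h5py.File(path, "w") as f:
        f.create_dataset(p["time"], data=np.asarray(time, float))
        f.create_dataset(p["signal"], data=np.asarray(signal, float))
        f.create_dataset(p["isosbestic"], data=np.asarray(isosbestic, float))


def make_session_dir(
    folder,
    session_template: SessionTemplate,
    photometry_template: PhotometryTemplate,
    dialect: str = "imetronic",
    fiber_format: str = "csv",
) -> GroundTruth:
    """Create one session folder (behavior .dat + fiber file + truth.json).

    The layout matches what session discovery expects: exactly one behavior
    file and one fiber file per folder.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    truth = simulate_behavior(session_template)
    if dialect == "imetronic":
        write_imetronic(truth, folder / "behavior.dat")
    elif dialect == "generic":
        write_generic(truth, folder / "behavior.dat")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    t, s, i, truth = simulate_photometry(truth, photometry_template)
    if fiber_format == "csv":
        write_fiber_csv(t, s, i, folder / "fiber.csv")
    elif fiber_format == "hdf5":
        write_fiber_hdf5(t, s, i, folder / "fiber.h5")
    else:
        raise ValueError(f"unknown fiber format {fiber_format!r}")
    truth.save(folder / "truth.json")
    return truth
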