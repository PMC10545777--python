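"""Operant-behavior session logs: parsing, intervals, event selection.

Two on-disk dialects are supported:

* **Integer-coded logs** ("imetronic" style): tab-separated text, one row per
  rig message, every column an integer.  The message grammar is proprietary,
  so decoding is fully configuration-driven: an event definition is a set of
  ``column -> required value`` constraints plus the index of the column that
  holds the timestamp (raw unit declared in the config, milliseconds by
  default).
* **Generic event tables**: comma-separated text whose first row holds unique
  ASCII event names and whose subsequent rows hold timestamps (seconds);
  columns may have unequal lengths.  By convention these files keep a
  ``.dat`` extension.

On top of the parsed events, named intervals are derived from declarative
rules (light on/off pairing, fixed offsets after a trigger such as the 40 s
post-injection time-out, set algebra over named intervals, and guarded
switches that label an onset by the state that preceded it).  Intervals use
the closed-open convention ``[start, end)`` for membership, so an event
falling exactly on a period switch belongs to the next period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "EventRecord",
    "IntervalRecord",
    "EventPattern",
    "PairedOnOff",
    "EventOffset",
    "SetOp",
    "GuardedSwitch",
    "IntervalRule",
    "BehaviorSession",
    "parse_imetronic",
    "parse_generic_csv",
    "derive_intervals",
    "select_events",
    "rule_from_dict",
    "rule_to_dict",
]

_UNIT_FACTORS = {"ms": 1e-3, "s": 1.0}


def _unit_factor(unit: str) -> float:
    try:
        return _UNIT_FACTORS[unit]
    except KeyError:
        raise ValueError(f"unknown time unit {unit!r}; expected one of {sorted(_UNIT_FACTORS)}") from None


@dataclass(frozen=True)
class EventRecord:
    """One named, timestamped behavioral event (time in seconds)."""

    name: str
    time: float


@dataclass(frozen=True)
class IntervalRecord:
    """One named interval ``[start, end)`` in seconds."""

    name: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass(frozen=True)
class EventPattern:
    """Matcher for one integer-coded row: ``column -> required value``.

    ``time_column`` is the column holding the raw timestamp.
    """

    match: tuple[tuple[int, int], ...]
    time_column: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "EventPattern":
        return cls(
            match=tuple(sorted((int(c), int(v)) for c, v in dict(d["match"]).items())),
            time_column=int(d.get("time_column", 0)),
        )

    def to_dict(self) -> dict:
        return {"match": {c: v for c, v in self.match}, "time_column": self.time_column}

    def matches(self, row: Sequence[int]) -> bool:
        return all(c < len(row) and row[c] == v for c, v in self.match) and self.time_column < len(row)


# --------------------------------------------------------------------------
# Interval rules
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedOnOff:
    """Interval between an onset event and the next offset event.

    Repeated onsets while an interval is open are ignored with a warning, as
    are offsets with no preceding onset; an onset never closed is closed at
    the session end.
    """

    name: str
    on_event: str
    off_event: str


@dataclass(frozen=True)
class EventOffset:
    """Fixed-duration interval ``[t, t + duration_s)`` after each trigger.

    The canonical use is the 40 s post-injection time-out.  Overlapping
    instances are merged so same-name intervals never overlap.
    """

    name: str
    trigger_event: str
    duration_s: float


@dataclass(frozen=True)
class SetOp:
    """Set algebra over named intervals: OR (union), AND (intersection),
    DIFF (first operand minus the union of the rest)."""

    name: str
    op: str  # "AND" | "OR" | "DIFF"
    operands: tuple[str, ...]


@dataclass(frozen=True)
class GuardedSwitch:
    """Label each onset event by the state active just before it.

    For every occurrence of ``onset_event`` at time ``t``, emits a derived
    event named ``{onset_event}_from_{label}``, where the label is
    ``label_prior`` if the named interval covers the whole lookback window
    ``[t - lookback_s, t)`` and ``label_other`` otherwise.  This encodes the
    distinction between a house-light switch arriving from the drug-period
    light and one arriving from time-out darkness.
    """

    name: str
    onset_event: str
    prior_interval: str
    label_prior: str
    label_other: str = "dark"
    lookback_s: float = 1.0


IntervalRule = Union[PairedOnOff, EventOffset, SetOp, GuardedSwitch]


def rule_from_dict(name: str, d: dict) -> IntervalRule:
    kind = d.get("kind")
    if kind == "paired_on_off":
        return PairedOnOff(name, d["on"], d["off"])
    if kind == "event_offset":
        dur = float(d["duration_s"])
        return EventOffset(name, d["trigger"], dur)
    if kind == "set_op":
        op = d["op"].upper()
        if op not in ("AND", "OR", "DIFF"):
            raise ValueError(f"interval rule {name!r}: unknown set op {op!r}")
        return SetOp(name, op, tuple(d["operands"]))
    if kind == "guarded_switch":
        return GuardedSwitch(
            name,
            d["onset"],
            d["prior"],
            d.get("label_prior", d["prior"].lower()),
            d.get("label_other", "dark"),
            float(d.get("lookback_s", 1.0)),
        )
    raise ValueError(f"interval rule {name!r}: unknown kind {kind!r}")


def rule_to_dict(rule: IntervalRule) -> dict:
    if isinstance(rule, PairedOnOff):
        return {"kind": "paired_on_off", "on": rule.on_event, "off": rule.off_event}
    if isinstance(rule, EventOffset):
        return {"kind": "event_offset", "trigger": rule.trigger_event, "duration_s": rule.duration_s}
    if isinstance(rule, SetOp):
        return {"kind": "set_op", "op": rule.op, "operands": list(rule.operands)}
    if isinstance(rule, GuardedSwitch):
        return {
            "kind": "guarded_switch",
            "onset": rule.onset_event,
            "prior": rule.prior_interval,
            "label_prior": rule.label_prior,
            "label_other": rule.label_other,
            "lookback_s": rule.lookback_s,
        }
    raise TypeError(f"not an interval rule: {rule!r}")


def rule_event_references(rule: IntervalRule) -> tuple[str, ...]:
    """Event names a rule refers to (for config validation)."""
    if isinstance(rule, PairedOnOff):
        return (rule.on_event, rule.off_event)
    if isinstance(rule, EventOffset):
        return (rule.trigger_event,)
    if isinstance(rule, GuardedSwitch):
        return (rule.onset_event,)
    return ()


# --------------------------------------------------------------------------
# Session container
# --------------------------------------------------------------------------


@dataclass
class BehaviorSession:
    """All named events and named intervals of one operant session."""

    source: str
    events: list[EventRecord]
    intervals: list[IntervalRecord] = field(default_factory=list)
    unmatched_rows: int = 0

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.time, e.name))
        self.intervals = sorted(self.intervals, key=lambda i: (i.name, i.start))

    @property
    def end(self) -> float:
        """Session end: latest event time or interval end seen."""
        last_ev = self.events[-1].time if self.events else 0.0
        last_iv = max((iv.end for iv in self.intervals), default=0.0)
        return max(last_ev, last_iv)

    def event_names(self) -> list[str]:
        return sorted({e.name for e in self.events})

    def interval_names(self) -> list[str]:
        return sorted({iv.name for iv in self.intervals})

    def event_times(self, name: str) -> np.ndarray:
        return np.array([e.time for e in self.events if e.name == name], dtype=float)

    def intervals_named(self, name: str) -> list[IntervalRecord]:
        return [iv for iv in self.intervals if iv.name == name]

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"name": [e.name for e in self.events], "time_s": [e.time for e in self.events]})

    def intervals_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [iv.name for iv in self.intervals],
                "start_s": [iv.start for iv in self.intervals],
                "end_s": [iv.end for iv in self.intervals],
            }
        )

    def write_events_csv(self, path) -> None:
        """Canonical event table: ``name,time_s`` CSV."""
        self.events_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# Parsers
# --------------------------------------------------------------------------


def parse_imetronic(path, config) -> BehaviorSession:
    """Parse an integer-coded, tab-separated session log.

    Every row matching a configured :class:`EventPattern` yields one
    :class:`EventRecord`, with the raw timestamp converted to seconds using
    the configured unit.  Rows matching no pattern (or rows that are not
    integer-coded) are counted in ``unmatched_rows`` and reported with a
    warning, never fatal.
    """
    beh = config.behavior
    factor = _unit_factor(beh.time_unit)
    patterns = [(name, pat) for name, pat in beh.events.items() if isinstance(pat, EventPattern)]

    events: list[EventRecord] = []
    unmatched = 0
    text = Path(path).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        try:
            row = [int(cell) for cell in line.split("\t")]
        except ValueError:
            unmatched += 1
            continue
        hit = False
        for name, pat in patterns:
            if pat.matches(row):
                events.append(EventRecord(name, row[pat.time_column] * factor))
                hit = True
        if not hit:
            unmatched += 1
    if unmatched:
        warnings.warn(f"{path}: {unmatched} rows matched no configured event pattern", stacklevel=2)
    if not events:
        warnings.warn(f"{path}: no configured events found (empty session)", stacklevel=2)
    return BehaviorSession(source=str(path), events=events, unmatched_rows=unmatched)


def parse_generic_csv(path, config) -> BehaviorSession:
    """Parse a generic event table (headers = event names, rows = timestamps).

    Columns may be ragged; blank cells are skipped.  Duplicate or non-ASCII
    headers and non-numeric cells are fatal (the offending row/column is
    reported).  Timestamps are interpreted in the configured generic unit
    (seconds by default).
    """
    factor = _unit_factor(config.behavior.generic_time_unit)
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    names = [h.strip() for h in lines[0].split(",")]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"{path}: duplicate column headers {dupes}")
    for n in names:
        if not n or not n.isascii():
            raise ValueError(f"{path}: event names must be non-empty ASCII, got {n!r}")

    events: list[EventRecord] = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) > len(names):
            raise ValueError(f"{path}: row {i} has {len(cells)} cells but only {len(names)} headers")
        for j, cell in enumerate(cells):
            cell = cell.strip()
            if not cell:
                continue
            try:
                t = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {i}, column {names[j]!r}"
                ) from None
            events.append(EventRecord(names[j], t * factor))
    return BehaviorSession(source=str(path), events=events)


# --------------------------------------------------------------------------
# Interval algebra on (start, end) span lists -- closed-open convention
# --------------------------------------------------------------------------

Span = tuple[float, float]


def merge_spans(spans: Iterable[Span]) -> list[Span]:
    """Sort and merge overlapping or touching spans; drop empty spans."""
    out: list[Span] = []
    for s, e in sorted((s, e) for s, e in spans if e > s):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def union_spans(*span_lists: Iterable[Span]) -> list[Span]:
    all_spans: list[Span] = []
    for lst in span_lists:
        all_spans.extend(lst)
    return merge_spans(all_spans)


def intersect_spans(a: Iterable[Span], b: Iterable[Span]) -> list[Span]:
    a = merge_spans(a)
    b = merge_spans(b)
    out: list[Span] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def diff_spans(a: Iterable[Span], b: Iterable[Span]) -> list[Span]:
    """Spans of ``a`` with every span of ``b`` removed."""
    a = merge_spans(a)
    b = merge_spans(b)
    out: list[Span] = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _spans_cover(spans: Sequence[Span], start: float, end: float) -> bool:
    """True if one merged span covers [start, end) entirely."""
    return any(s <= start and e >= end for s, e in merge_spans(spans))


# --------------------------------------------------------------------------
# Interval derivation
# --------------------------------------------------------------------------


def _pair_on_off(session: BehaviorSession, rule: PairedOnOff, fallback_end: float) -> list[Span]:
    marks = [(t, 1) for t in session.event_times(rule.on_event)]
    marks += [(t, 0) for t in session.event_times(rule.off_event)]
    # At equal times an offset is processed before an onset (closes first).
    marks.sort(key=lambda m: (m[0], m[1]))
    spans: list[Span] = []
    open_t: float | None = None
    for t, kind in marks:
        if kind == 1:
            if open_t is not None:
                warnings.warn(
                    f"rule {rule.name!r}: repeated onset {rule.on_event!r} at {t} s ignored",
                    stacklevel=3,
                )
            else:
                open_t = t
        else:
            if open_t is None:
                warnings.warn(
                    f"rule {rule.name!r}: offset {rule.off_event!r} at {t} s before any onset, ignored",
                    stacklevel=3,
                )
            else:
                if t > open_t:
                    spans.append((open_t, t))
                open_t = None
    if open_t is not None:
        if fallback_end > open_t:
            spans.append((open_t, fallback_end))
        else:
            warnings.warn(
                f"rule {rule.name!r}: unclosed onset at {open_t} s coincides with session end, dropped",
                stacklevel=3,
            )
    return merge_spans(spans)


def derive_intervals(session: BehaviorSession, rules: Iterable[IntervalRule]) -> BehaviorSession:
    """Apply interval rules and return a new session with derived intervals.

    Rules are resolved in dependency order: on/off pairing and event-offset
    rules first, then set-algebra rules (iteratively, so they may reference
    each other), then guarded switches, which need intervals and add derived
    *events* rather than intervals.
    """
    rules = list(rules)
    last_event = session.events[-1].time if session.events else 0.0

    spans_by_name: dict[str, list[Span]] = {}
    for iv in session.intervals:  # pre-existing intervals participate in set ops
        spans_by_name.setdefault(iv.name, []).append((iv.start, iv.end))

    for rule in rules:
        if isinstance(rule, PairedOnOff):
            spans_by_name[rule.name] = _pair_on_off(session, rule, last_event)
        elif isinstance(rule, EventOffset):
            spans = [(t, t + rule.duration_s) for t in session.event_times(rule.trigger_event)]
            spans_by_name[rule.name] = merge_spans(spans)

    pending = [r for r in rules if isinstance(r, SetOp)]
    while pending:
        progressed = False
        for rule in list(pending):
            if all(op in spans_by_name for op in rule.operands):
                ops = [spans_by_name[name] for name in rule.operands]
                if rule.op == "OR":
                    spans_by_name[rule.name] = union_spans(*ops)
                elif rule.op == "AND":
                    acc = ops[0]
                    for other in ops[1:]:
                        acc = intersect_spans(acc, other)
                    spans_by_name[rule.name] = acc
                else:  # DIFF
                    spans_by_name[rule.name] = diff_spans(ops[0], union_spans(*ops[1:]))
                pending.remove(rule)
                progressed = True
        if not progressed:
            missing = sorted({op for r in pending for op in r.operands if op not in spans_by_name})
            raise ValueError(f"unresolvable set_op rules; missing or cyclic operands: {missing}")

    new_events: list[EventRecord] = []
    for rule in rules:
        if not isinstance(rule, GuardedSwitch):
            continue
        prior = spans_by_name.get(rule.prior_interval, [])
        for t in session.event_times(rule.onset_event):
            covered = _spans_cover(prior, t - rule.lookback_s, t)
            label = rule.label_prior if covered else rule.label_other
            new_events.append(EventRecord(f"{rule.onset_event}_from_{label}", float(t)))

    intervals = [
        IntervalRecord(name, float(s), float(e))
        for name, spans in spans_by_name.items()
        for s, e in spans
    ]
    return BehaviorSession(
        source=session.source,
        events=list(session.events) + new_events,
        intervals=intervals,
        unmatched_rows=session.unmatched_rows,
    )


# --------------------------------------------------------------------------
# Event selection
# --------------------------------------------------------------------------


def select_events(
    session: BehaviorSession,
    event: str,
    within: str | None = None,
    selector: str = "all",
    k: int | None = None,
    series_size: int | None = None,
    reset_event: str | None = None,
    exclude: Sequence[str] = ("TIMEOUT",),
) -> np.ndarray:
    """Select event times for perievent analysis.

    selector
        ``"all"`` -- every occurrence (optionally restricted to ``within``
        intervals); ``"first_in_interval"`` -- the earliest occurrence inside
        each instance of the ``within`` interval; ``"ordinal_in_series"`` --
        the ``k``-th response of each complete fixed-ratio series of
        ``series_size`` responses.  Series are delimited by occurrences of
        ``reset_event`` (e.g. the injection), and responses falling inside
        intervals named in ``exclude`` (time-outs by default) are recorded
        but do not advance the series count.
    """
    times = session.event_times(event)

    if selector == "all":
        selected = times
    elif selector == "first_in_interval":
        if within is None:
            raise ValueError("first_in_interval requires `within`")
        ivs = session.intervals_named(within)
        if not ivs:
            raise ValueError(f"no intervals named {within!r} in session")
        selected = np.array(
            [min(t for t in times if iv.contains(t)) for iv in ivs if any(iv.contains(t) for t in times)]
        )
        return np.sort(selected)
    elif selector == "ordinal_in_series":
        if k is None or series_size is None:
            raise ValueError("ordinal_in_series requires `k` and `series_size`")
        if k < 1 or k > series_size:
            raise ValueError(f"k={k} outside 1..series_size={series_size}")
        counted = times
        for name in exclude:
            ivs = session.intervals_named(name)
            if ivs:
                counted = np.array([t for t in counted if not any(iv.contains(t) for iv in ivs)])
        resets = np.sort(session.event_times(reset_event)) if reset_event else np.array([])
        edges = np.concatenate(([-np.inf], resets, [np.inf]))
        picked = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            seg = counted[(counted >= lo) & (counted < hi)]
            for start in range(0, len(seg) - series_size + 1, series_size):
                picked.append(seg[start + k - 1])
        selected = np.array(picked)
    else:
        raise ValueError(f"unknown selector {selector!r}")

    if within is not None:
        ivs = session.intervals_named(within)
        if not ivs:
            raise ValueError(f"no intervals named {within!r} in session")
        selected = np.array([t for t in selected if any(iv.contains(t) for iv in ivs)])
    return np.sort(np.asarray(selected, dtype=float))
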