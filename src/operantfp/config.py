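"""Analysis configuration: defaults, YAML loading, validation.

One YAML file with four sections drives the whole pipeline::

    behavior:
      time_unit: ms              # raw unit of integer-coded logs
      generic_time_unit: s       # unit of generic event tables
      events:                    # integer-coded row patterns
        np1: {match: {1: 2, 2: 1}, time_column: 0}
      csv_events: [lick, cue]    # extra event names allowed in generic files
      intervals:                 # named interval rules
        TIMEOUT: {kind: event_offset, trigger: inj1, duration_s: 40}
    fiber:
      columns: {time: "Time(s)", signal: "...", isosbestic: "..."}
      hdf5_paths: {time: time, signal: signal, isosbestic: isosbestic}
      gap_threshold_s: 1.0
      min_length_s: 5.0
    transients:
      window_s: 10.0
      bmad_k: 2.5
      pmad_k: 3.5
      spacing_ms: 50.0
      scope: per-window
    perievent:
      norm: F
      pre_s: 5.0
      post_s: 5.0

Built-in defaults are shipped in code so the package works with no file at
all; any key absent from a user file falls back to the default, and explicit
``overrides`` take highest precedence.  Unknown keys warn and are ignored
(so one file can be reused across protocol variants); non-positive numeric
parameters are fatal.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .behavior import (
    EventPattern,
    GuardedSwitch,
    IntervalRule,
    SetOp,
    rule_event_references,
    rule_from_dict,
    rule_to_dict,
)
from .transients import PeakParams

__all__ = [
    "AnalysisConfig",
    "BehaviorConfig",
    "FiberConfig",
    "PerieventConfig",
    "load_config",
    "save_config",
    "DEFAULTS",
]


#: Default integer-row patterns for the events of the self-administration
#: protocol: nose-pokes in the active/inactive hole, licks, the intravenous
#: injection, the cue light (LED1), the drug-period light (LED2) and the
#: house light (HLED).  Column 0 holds the timestamp; columns 1-2 hold the
#: message family and code.
_DEFAULT_EVENTS: dict[str, dict] = {
    "np1": {"match": {1: 2, 2: 1}, "time_column": 0},
    "np2": {"match": {1: 2, 2: 2}, "time_column": 0},
    "lk1": {"match": {1: 3, 2: 1}, "time_column": 0},
    "inj1": {"match": {1: 6, 2: 1}, "time_column": 0},
    "led1_on": {"match": {1: 4, 2: 11}, "time_column": 0},
    "led1_off": {"match": {1: 4, 2: 10}, "time_column": 0},
    "led2_on": {"match": {1: 4, 2: 21}, "time_column": 0},
    "led2_off": {"match": {1: 4, 2: 20}, "time_column": 0},
    "hled_on": {"match": {1: 4, 2: 31}, "time_column": 0},
    "hled_off": {"match": {1: 4, 2: 30}, "time_column": 0},
}

#: Default interval rules: light-driven periods, the 40 s post-injection
#: time-out, and the two house-light switch variants (from the drug-period
#: light vs from time-out darkness).
_DEFAULT_INTERVALS: dict[str, dict] = {
    "HLED_ON": {"kind": "paired_on_off", "on": "hled_on", "off": "hled_off"},
    "LED1_ON": {"kind": "paired_on_off", "on": "led1_on", "off": "led1_off"},
    "LED2_ON": {"kind": "paired_on_off", "on": "led2_on", "off": "led2_off"},
    "TIMEOUT": {"kind": "event_offset", "trigger": "inj1", "duration_s": 40.0},
    "DRUG": {"kind": "paired_on_off", "on": "led2_on", "off": "led2_off"},
    "NODRUG": {"kind": "paired_on_off", "on": "hled_on", "off": "hled_off"},
    "hled_switch": {
        "kind": "guarded_switch",
        "onset": "hled_on",
        "prior": "LED2_ON",
        "label_prior": "led2",
        "label_other": "dark",
        "lookback_s": 1.0,
    },
}

DEFAULTS: dict[str, Any] = {
    "behavior": {
        "time_unit": "ms",
        "generic_time_unit": "s",
        "events": _DEFAULT_EVENTS,
        "csv_events": [],
        "intervals": _DEFAULT_INTERVALS,
    },
    "fiber": {
        "columns": {
            "time": "Time(s)",
            "signal": "AIn-1 - Dem (AOut-1)",
            "isosbestic": "AIn-1 - Dem (AOut-2)",
        },
        "hdf5_paths": {"time": "time", "signal": "signal", "isosbestic": "isosbestic"},
        "gap_threshold_s": 1.0,
        "min_length_s": 5.0,
    },
    "transients": {
        "window_s": 10.0,
        "bmad_k": 2.5,
        "pmad_k": 3.5,
        "spacing_ms": 50.0,
        "scope": "per-window",
    },
    "perievent": {"norm": "F", "pre_s": 5.0, "post_s": 5.0},
}


@dataclass
class BehaviorConfig:
    time_unit: str = "ms"
    generic_time_unit: str = "s"
    events: dict[str, EventPattern] = field(default_factory=dict)
    csv_events: list[str] = field(default_factory=list)
    intervals: dict[str, IntervalRule] = field(default_factory=dict)

    def known_event_names(self) -> set[str]:
        return set(self.events) | set(self.csv_events)


@dataclass
class FiberConfig:
    columns: dict[str, str] = field(default_factory=dict)
    hdf5_paths: dict[str, str] = field(default_factory=dict)
    gap_threshold_s: float = 1.0
    min_length_s: float = 5.0


@dataclass
class PerieventConfig:
    norm: str = "F"
    pre_s: float = 5.0
    post_s: float = 5.0

    @property
    def window(self) -> tuple[float, float]:
        return (self.pre_s, self.post_s)


@dataclass
class AnalysisConfig:
    """Fully-populated configuration accepted by every downstream operation."""

    behavior: BehaviorConfig
    fiber: FiberConfig
    transients: PeakParams
    perievent: PerieventConfig

    def to_dict(self) -> dict:
        return {
            "behavior": {
                "time_unit": self.behavior.time_unit,
                "generic_time_unit": self.behavior.generic_time_unit,
                "events": {n: p.to_dict() for n, p in self.behavior.events.items()},
                "csv_events": list(self.behavior.csv_events),
                "intervals": {n: rule_to_dict(r) for n, r in self.behavior.intervals.items()},
            },
            "fiber": {
                "columns": dict(self.fiber.columns),
                "hdf5_paths": dict(self.fiber.hdf5_paths),
                "gap_threshold_s": self.fiber.gap_threshold_s,
                "min_length_s": self.fiber.min_length_s,
            },
            "transients": {
                "window_s": self.transients.window_s,
                "bmad_k": self.transients.bmad_k,
                "pmad_k": self.transients.pmad_k,
                "spacing_ms": self.transients.spacing_ms,
                "scope": self.transients.scope,
            },
            "perievent": {
                "norm": self.perievent.norm,
                "pre_s": self.perievent.pre_s,
                "post_s": self.perievent.post_s,
            },
        }


def _deep_merge(base: dict, user: Mapping, path: str = "") -> None:
    """Merge ``user`` into ``base`` in place, warning on unknown scalar keys.

    The ``events``, ``intervals``, ``columns``, ``hdf5_paths`` and
    ``csv_events`` containers are open (user entries extend/replace the
    defaults); every other key must already exist in the defaults.
    """
    open_containers = {"events", "intervals", "columns", "hdf5_paths"}
    for key, value in user.items():
        if key not in base:
            warnings.warn(f"unknown configuration key {path + key!r} ignored", stacklevel=4)
            continue
        if key in open_containers and isinstance(value, Mapping):
            base[key] = {**base[key], **{k: v for k, v in value.items()}}
        elif isinstance(base[key], dict) and isinstance(value, Mapping):
            _deep_merge(base[key], value, path=f"{path}{key}.")
        else:
            base[key] = value


def _apply_overrides(data: dict, overrides: Mapping[str, Any]) -> None:
    for dotted, value in overrides.items():
        parts = dotted.split(".")
        node = data
        for p in parts[:-1]:
            if p not in node or not isinstance(node[p], dict):
                raise KeyError(f"override {dotted!r}: no such configuration section")
            node = node[p]
        node[parts[-1]] = value


def _positive(name: str, value) -> float:
    value = float(value)
    if not value > 0:
        raise ValueError(f"configuration parameter {name} must be strictly positive, got {value}")
    return value


def _build(data: dict) -> AnalysisConfig:
    beh = data["behavior"]
    events = {}
    for name, spec in beh["events"].items():
        if not name.isascii():
            raise ValueError(f"event name {name!r} is not ASCII")
        events[name] = spec if isinstance(spec, EventPattern) else EventPattern.from_dict(spec)
    csv_events = [str(n) for n in beh["csv_events"]]
    for name in csv_events:
        if not name.isascii():
            raise ValueError(f"event name {name!r} is not ASCII")
    rules = {}
    for name, spec in beh["intervals"].items():
        rules[name] = spec if not isinstance(spec, Mapping) else rule_from_dict(name, spec)

    behavior = BehaviorConfig(
        time_unit=str(beh["time_unit"]),
        generic_time_unit=str(beh["generic_time_unit"]),
        events=events,
        csv_events=csv_events,
        intervals=rules,
    )

    known = behavior.known_event_names()
    for name, rule in rules.items():
        for ev in rule_event_references(rule):
            if ev not in known:
                raise ValueError(f"interval rule {name!r} references undefined event {ev!r}")
        if isinstance(rule, SetOp):
            for op in rule.operands:
                if op not in rules:
                    raise ValueError(f"interval rule {name!r} references undefined interval {op!r}")
        if isinstance(rule, GuardedSwitch) and rule.prior_interval not in rules:
            raise ValueError(f"interval rule {name!r} references undefined interval {rule.prior_interval!r}")

    fib = data["fiber"]
    fiber = FiberConfig(
        columns=dict(fib["columns"]),
        hdf5_paths=dict(fib["hdf5_paths"]),
        gap_threshold_s=_positive("fiber.gap_threshold_s", fib["gap_threshold_s"]),
        min_length_s=_positive("fiber.min_length_s", fib["min_length_s"]),
    )

    tr = data["transients"]
    transients = PeakParams(  # PeakParams validates positivity itself
        window_s=float(tr["window_s"]),
        bmad_k=float(tr["bmad_k"]),
        pmad_k=float(tr["pmad_k"]),
        spacing_ms=float(tr["spacing_ms"]),
        scope=str(tr["scope"]),
    )

    per = data["perievent"]
    if per["norm"] not in ("F", "Z"):
        raise ValueError(f"perievent.norm must be 'F' or 'Z', got {per['norm']!r}")
    perievent = PerieventConfig(
        norm=str(per["norm"]),
        pre_s=_positive("perievent.pre_s", per["pre_s"]),
        post_s=_positive("perievent.post_s", per["post_s"]),
    )
    return AnalysisConfig(behavior=behavior, fiber=fiber, transients=transients, perievent=perievent)


def load_config(path=None, overrides: Mapping[str, Any] | None = None) -> AnalysisConfig:
    """Load the analysis configuration.

    Parameters
    ----------
    path
        Optional YAML file.  Missing file is fatal; keys absent from the
        file take the built-in defaults.
    overrides
        Optional mapping of dotted keys (e.g. ``"transients.bmad_k"``) to
        values; highest precedence.
    """
    data = copy.deepcopy(DEFAULTS)
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"configuration file not found: {p}")
        user = yaml.safe_load(p.read_text())
        if user is None:
            user = {}
        if not isinstance(user, Mapping):
            raise ValueError(f"{p}: configuration must be a mapping")
        _deep_merge(data, user)
    if overrides:
        _apply_overrides(data, overrides)
    return _build(data)


def save_config(config: AnalysisConfig, path) -> None:
    """Serialize a configuration to YAML (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
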