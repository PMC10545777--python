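"""Derive intervals and select events of interest.

Runs the default interval rules over a simulated session: drug/no-drug
periods from the period lights, 40 s time-outs after every injection, and
the two house-light switch variants (arriving from the drug-period light vs
from darkness).  Then selects nose-pokes with the three selectors.  Interval
durations print the protocol constants; the ordinal selector returns the
first poke of each completed FR5 series.
"""

import tempfile
import warnings
from pathlib import Path

import operantfp as ofp

cfg = ofp.load_config()
truth = ofp.simulate_behavior(ofp.SessionTemplate(seed=1))

with tempfile.TemporaryDirectory() as td, warnings.catch_warnings():
    warnings.simplefilter("ignore")
    path = Path(td) / "behavior.dat"
    ofp.write_imetronic(truth, path)
    sess = ofp.derive_intervals(ofp.parse_imetronic(path, cfg), cfg.behavior.intervals.values())

for name in ("DRUG", "NODRUG", "TIMEOUT"):
    ivs = sess.intervals_named(name)
    durs = sorted({round(iv.duration, 3) for iv in ivs})
    print(f"{name:>8}: {len(ivs)} interval(s), duration(s) {durs} s")

switches = [e.name for e in sess.events if e.name.startswith("hled_on_from")]
print("house-light switch labels:", switches)

all_np1 = ofp.select_events(sess, "np1")
in_drug = ofp.select_events(sess, "np1", within="DRUG")
first_of_series = ofp.select_events(
    sess, "np1", selector="ordinal_in_series", k=1, series_size=5, reset_event="inj1"
)
print(f"np1: {all_np1.size} total, {in_drug.size} during drug periods, "
      f"{first_of_series.size} first-of-series")
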