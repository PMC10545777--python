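"""Simulate a self-administration session and parse it back.

Generates one session of the default cocaine protocol (three 40 min drug
periods alternating with two 15 min no-drug periods, FR5, 40 s time-out),
writes it in both supported dialects and parses each file.  The printed
counts should be identical across the generator truth and the two parsers:
the on-disk representation is lossless.
"""

import tempfile
import warnings
from pathlib import Path

import operantfp as ofp

cfg = ofp.load_config()
truth = ofp.simulate_behavior(ofp.SessionTemplate(seed=1))
print(f"simulated events: {len(truth.events)}   injections: {truth.event_times('inj1').size}")

with tempfile.TemporaryDirectory() as td, warnings.catch_warnings():
    warnings.simplefilter("ignore")
    td = Path(td)
    ofp.write_imetronic(truth, td / "imetronic.dat")
    ofp.write_generic(truth, td / "generic.dat")
    for name, parser in [("imetronic", ofp.parse_imetronic), ("generic", ofp.parse_generic_csv)]:
        sess = parser(td / f"{name}.dat", cfg)
        np1 = sess.event_times("np1").size
        inj = sess.event_times("inj1").size
        print(f"{name:>9} dialect -> {len(sess.events)} events ({np1} np1, {inj} inj1)")
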