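"""Detect calcium-like transients with the windowed double-MAD detector.

Plants five transients of known amplitude (about 15x the noise MAD of the
normalized trace) in a simulated recording and runs the detector with the
default parameters (10 s windows, bMAD x2.5, pMAD x3.5, 50 ms spacing).
The detector should report exactly the five planted peaks; the frequency is
peaks per second over the recording.
"""

import operantfp as ofp

truth = ofp.simulate_behavior(ofp.SessionTemplate(periods=(("drug", 60.0),), seed=1))
tmpl = ofp.PhotometryTemplate(
    blocks=((0.0, 60.0),),
    transient_times=(5.0, 15.0, 25.0, 35.0, 45.0),
    transient_amps=(0.12,) * 5,
    spont_rate=0.0,
    seed=3,
)
t, s, i, truth = ofp.simulate_photometry(truth, tmpl)
(rec,) = ofp.split_recordings(ofp.RawFiberFile("<memory>", t, s, i))
dff = ofp.compute_dff(rec)

peaks = ofp.detect_peaks(dff.time, dff.values)
print(f"planted transient peaks at: {[round(x, 3) for x in truth.transients['peak_time']]}")
print(f"detected {len(peaks)} peaks:")
for p in peaks:
    print(f"  t = {p.time:7.3f} s   amplitude = {p.amplitude:.4f} dF/F")
stats = ofp.peak_stats(peaks, (0.0, 60.0))
print(f"frequency: {stats.frequency:.4f} peaks/s   mean amplitude: {stats.mean_amplitude:.4f}")
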