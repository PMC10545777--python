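"""Normalize a dual-channel photometry recording.

Simulates a 60 s recording with bleaching, spontaneous transients, a shared
motion artifact and channel noise, then computes both normalizations.  The
printed regression coefficients scale the isosbestic control onto the signal
channel; dF/F0 values are fractional changes around 0, and the Z-difference
is a dimensionless score with mean ~0.
"""

import numpy as np

import operantfp as ofp

truth = ofp.simulate_behavior(ofp.SessionTemplate(periods=(("drug", 60.0),), seed=1))
t, s, i, truth = ofp.simulate_photometry(truth, ofp.PhotometryTemplate(blocks=((0.0, 60.0),), seed=2))

raw = ofp.RawFiberFile("<memory>", t, s, i)
(rec,) = ofp.split_recordings(raw)
print(f"recording 1: {rec.time.size} samples at {rec.sampling_rate:.1f} Hz")

dff = ofp.compute_dff(rec)
a, b = dff.coefficients
print(f"dF/F0 fit: signal ~ {a:.4f} * isosbestic + {b:.4f} "
      f"(true relation: a={truth.iso_coefficients[0]:.4f}, b={truth.iso_coefficients[1]:.4f})")
print(f"dF/F0 range: [{dff.values.min():.4f}, {dff.values.max():.4f}]")

z = ofp.compute_zdiff(rec)
print(f"Z-difference mean: {z.values.mean():+.2e} (zero by construction), SD: {z.values.std():.3f}")
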