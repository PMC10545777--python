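# operantfp

Joint analysis of **operant-behavior event logs** and **fiber-photometry
recordings** for behavioral neuroscience.

Operant protocols (e.g. intravenous drug or sucrose self-administration)
mix experimenter-scheduled events (period lights, cues) with unpredictable
animal-produced responses (nose-pokes, licks, earned injections).  Relating
these events to bulk fluorescence from a genetically encoded sensor
(GCaMP, dLight, ...) requires parsing the rig's event log, deriving the
intervals that give events their meaning (drug-availability periods,
post-injection time-outs), processing the dual-channel photometry signal,
and aligning signal excerpts to the event times — across many sessions and
animals.  `operantfp` is a Python library that does all of this, plus a
synthetic-data generator with known ground truth so the whole pipeline is
testable without any recording.

## What it computes

**Signal normalization** (per contiguous recording). With `signal` the
sensor channel and `iso` the isosbestic control channel (which shares
motion/bleaching artifacts but not sensor transients):

- ΔF/F₀: fit `signal ≈ a·iso + b` by ordinary least squares, then
  `ΔF/F₀ = (signal − (a·iso + b)) / (a·iso + b)`;
- Z-difference: `z(signal) − z(iso)`, each channel standardized by its own
  recording-wide mean and sample SD.

**Transient detection** (windowed double-MAD thresholding). Within
consecutive 10 s windows: threshold₁ = median + 2.5·MAD; samples above it
form the candidate tail; threshold₂ = median + 3.5·MAD of that tail
(deviations taken from the same baseline median); samples above threshold₂
are transients, and runs of candidates closer than 50 ms collapse to the
single largest sample (the sensor rise time exceeds the sampling interval).
`MAD(x) = median(|xᵢ − median(x)|)`, with no consistency constant.

**Perievent analysis.** Epochs `[−pre, +post]` around selected event times,
renormalized against the pre-event baseline as Z-scores
`(x − mean(baseline))/SD(baseline)` or robust Z-scores
`(x − median(baseline))/MAD(baseline)`; per-epoch pre/post AUC (trapezoid),
averages, and peak frequency/amplitude; linear interpolation of all epochs
onto one common grid for group averaging.

**Batching.** A session folder holds one behavior file and one fiber file;
`analyze` runs the chain over many folders and collects one summary row per
epoch plus a machine-readable exclusion report (every selected event is
accounted for exactly once).

## Worked example

`examples/05_perievent_batch.py` simulates three sessions in which every
earned injection is followed 0.2 s later by a transient of amplitude
0.05 ΔF/F, then analyzes them:

```
discovered 3 sessions
epochs: 11   exclusions: 3
 event_time normalization  preAUC  postAUC  PostAVG_Z  postAVG_dF
     30.882             F  0.0068   0.0270     0.3972      0.0054
    104.289             F  0.0051   0.0219     0.3053      0.0044
    ...
batch mean trace peak: 0.0542 dF/F at +0.232 s (planted: 0.0500 at +0.200 s)
```

Each row is one injection epoch: its event time (s, behavior clock), the
normalization tag, the pre/post area under the ΔF/F curve (value·s), the
post-event average baseline Z-score and average ΔF/F.  Three injections sat
too close to a recording edge for a full ±5 s window and appear in
`exclusions.csv` instead.  Averaging the interpolated epochs recovers the
planted transient: 0.054 ΔF/F near +0.23 s, within the noise of the
simulation.  The other example scripts demonstrate log parsing
(`01`), interval rules and event selectors (`02`), normalization (`03`) and
transient detection (`04`), each printing what the numbers mean.

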