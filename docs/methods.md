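# Methods

This note documents the models, conventions and numerical choices behind
`operantfp`, in the spirit of the methods documentation of mature analysis
libraries: what each stage assumes, which parameters matter, and what the
synthetic data does and does not emulate.

## Behavior logs and interval derivation

Integer-coded logs are decoded entirely by configuration: an event
definition is a set of `column -> required integer` constraints plus a time
column, because the rig's message grammar is proprietary and varies across
installations.  Raw timestamps are converted to seconds at parse time
(milliseconds by default for integer-coded logs, seconds for generic event
tables).  Rows that match no pattern are counted and reported, never fatal:
real logs contain housekeeping messages.

Intervals follow the closed-open convention `[start, end)`, so an event
exactly at a period switch belongs to the next period and nothing is double
counted.  Four rule kinds cover the protocols we target:

- **paired_on_off** — a state light: each onset pairs with the next offset;
  repeated onsets and orphan offsets warn and are ignored; an unclosed
  onset closes at the session end.  *Session end* is the latest event time
  or derived interval end; fixed-offset intervals are never clipped to it,
  so a time-out that outlives the last logged event keeps its full length.
- **event_offset** — `[t, t + d)` per trigger (the 40 s post-injection
  time-out); overlapping instances merge, keeping same-name intervals
  disjoint.
- **set_op** — union/intersection/difference over named intervals,
  resolved iteratively so rules may reference each other (cycles are
  fatal).
- **guarded_switch** — labels each onset of an event by the state active
  throughout the 1 s lookback window before it (`hled_on_from_led2` vs
  `hled_on_from_dark`).  The 1 s default is our choice; the distinction
  itself is protocol-mandated (a house-light switch arriving from time-out
  darkness is not comparable to one arriving from the drug-period light).

Event selectors: `all` (optionally restricted to an interval), `first_in_interval`
(one per interval instance), and `ordinal_in_series` (the k-th response of
each complete fixed-ratio series).  Series are delimited by the
reinforcement event, and responses inside time-outs are recorded but do not
advance the count — the protocol states they have no consequences, so we
exclude them from series arithmetic by default.

## Photometry processing

Files split into contiguous recordings wherever the inter-sample gap
strictly exceeds 1 s (acquisition is ~1 kHz, so 1 s dwarfs any jitter);
segments spanning under 5 s are discarded with a warning.  All regression
and standardization is per recording, never across gaps, because bleaching
levels differ between segments.  The sampling rate is estimated as
`(n − 1) / timespan`; no resampling is performed at this stage.

ΔF/F₀ assumes the two channels are strongly correlated outside transients;
the OLS fit of signal on control is therefore slightly biased by whatever
transients are present (visible in the simulation, where the fitted slope
deviates from the generative one when transients are dense).  A
zero-variance control channel and a non-positive fitted baseline are fatal
rather than silently produced.  SDs use the sample convention (ddof = 1)
everywhere; the formulas do not dictate a choice and we prefer one
consistent convention.

## Transient detection

Detection operates on consecutive, non-overlapping windows (10 s default,
last window possibly short; slivers of fewer than 4 samples are skipped).
Windows limit the reach of slow drift: a single recording-wide threshold
would under-detect late transients on a bleaching trace.  Within a window
with median m:

1. threshold₁ = m + 2.5·MAD(window); samples ≤ threshold₁ are removed;
2. threshold₂ = m + 3.5·median(|remaining − m|); samples > threshold₂ are
   transient candidates;
3. candidate runs with spacing under 50 ms collapse to their largest
   sample (reported at that sample's time; no sub-sample interpolation).

The deviations in step 2 are measured from the *window* median, not from
the remaining data's own median.  This choice is deliberate: the surviving
samples all sit in the upper tail, so their median distance from the
baseline is large and threshold₂ escalates sharply when a window contains
nothing but noise (on unit Gaussian noise it lands near 7 sigma, giving a
near-zero false-positive rate per window), while windows containing real
transients keep them comfortably above it.  Anchoring the second threshold
at the survivors' own median instead would park it around 2.7 sigma on
Gaussian noise and admit hundreds of false positives per minute at 1 kHz,
which contradicts the intended behavior of a two-stage escalating detector.
Both thresholds are median-anchored, so detection is invariant to adding a
constant and equivariant under positive scaling — which also means the
"per-window vs whole-recording" standardization scope cannot change which
samples are detected; the option is honored for interface compatibility and
its inertness is documented here and asserted in the tests.  Peak
amplitudes are always reported in the input trace's units.

A refractory chain can in principle span more than 50 ms (candidates every
20 ms for 200 ms yield one peak); the guarantee is that *reported* peaks
are never closer than the spacing.  Raising either multiplier shrinks the
candidate set monotonically; the final peak count is monotone in practice
(a removed candidate could in principle split a chain in two, but this
requires adversarial geometry that never arises in the tested regimes).

## Perievent analysis

The baseline is the entire pre-event span (relative time < 0) by default —
the natural reading of "the time preceding the event" — and the sample at
exactly 0 belongs to the post side.  Epochs are rejected, with a reason
that propagates to the exclusion report, when the window crosses a
recording edge or the baseline has zero spread; batch bookkeeping
guarantees `|epochs| + |exclusions| = |selected events|`.  AUCs are plain
trapezoid integrals over seconds (a constant c over span L gives c·L).
The common interpolation grid uses the *maximum* sample count among epochs
(configurable in principle; max loses no resolution and linear
interpolation preserves linear signals exactly).  Renormalization can start
from either ΔF/F or Z-difference values; the method tag travels with every
epoch and appears in the output tables.

Clock convention: behavior and fiber timestamps are assumed to share one
clock; a per-session `clock_offset` (fiber minus behavior, seconds) covers
rigs that start clocks independently.

## Synthetic data

The behavior generator draws nose-pokes as homogeneous Poisson processes
per period type and runs the schedule machine over them (FR counter, cue
1 s after completion for 4 s, injection 1 s after cue onset, 40 s time-out
during which pokes are emitted but inert).  Defaults encode the cocaine
protocol: three 40 min drug periods alternating with two 15 min no-drug
periods, FR5, and a drug-period poke rate of 0.02/s, which yields on the
order of twenty injections per session — a typical maintenance level.  All
times are quantized to 1 ms before writing, so parsing either dialect
reproduces the truth tables exactly.  LED2 on/off marks the scheduled drug
periods; the `led2_off_during_timeout` option darkens the drug light during
time-outs, producing the darkness-to-house-light switch scenario for the
guarded-switch rule.

The photometry generator is
`baseline·exp(−t/τ_bleach) + transients + artifact + noise` on the signal
channel and `scale·baseline·exp(−t/τ_bleach) + offset + artifact + noise`
on the control channel: transients appear on the signal only, the additive
artifact (an AR(1) process with 0.5 s correlation time) is shared, matching
the correlated-channels assumption behind the ΔF/F fit.  Transients are
peak-normalized difference-of-exponentials kernels (rise τ 20 ms, decay τ
200 ms, ~51 ms time-to-peak — fast-indicator kinetics) with log-normal
amplitudes expressed in ΔF/F units (the additive height is scaled by the
local baseline).  Event-locked transients place their *peak*, not their
onset, at `event + latency`.  What the generator does **not** emulate:
hemodynamic or wavelength-specific optics, nonstationary noise, movement
spikes that differ between channels, or multi-site recording — so passing
tests demonstrate correctness of the algorithms under the model's
assumptions, not robustness to every artifact of real rigs.

## Problem sizes

Tests and examples run at desk scale by choice: full-length sessions
(2.5 h) for behavior-only checks, which are cheap, and short recordings
(60–300 s at 1 kHz, three sessions) for end-to-end photometry checks —
enough epochs (~10–15) for the batch mean to recover a planted 0.05 ΔF/F
transient within 15% and 50 ms.  The acceptance script's protocol-constant
checks use the full default session.

## Known limitations

- Single fiber site, single signal/control channel pair per file.
- Only the two implemented normalizations; no exponential detrending.
- The integer-log grammar is a configurable reconstruction, not a decoder
  for any specific commercial format.
- The detector reports sample-resolution peak times; with kernels that are
  flat near their maximum, noise can shift the reported time by tens of
  milliseconds at 1 kHz.
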