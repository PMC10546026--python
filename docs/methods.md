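# Methods

## Problem and measurement model

A presentation computer issues a trigger at the moment it *requests* a
stimulus; the stimulus becomes physically visible one graphics-pipeline plus
panel-response delay later.  `clet` estimates that delay per event by
comparing the trigger timestamps recorded in the EEG marker stream (`tS`)
with display onsets measured optically (`tD`) on a photodiode channel
sampled by the same amplifier, so both time bases share one clock.  The
per-event latency is `(tD − tS)·1000` ms; a session is summarised by the
per-stimulus-type mean, sample standard deviation (n−1 denominator) and a
histogram (default 1-ms bins, edges aligned to multiples of the bin width).
The ± value is dispersion over events, not a standard error.

## Detection algorithms

**Time convention.** Samples are 0-based; sample `i` of a trace with start
offset `t0` sits at `t0 + i/fs`.  BrainVision marker positions are 1-based
and convert as `(pos − 1)/fs`; this matches the behaviour of the
independent reader (mne) used as a cross-check in the tests.  When start
("S7") and end ("S8") markers exist, detection is restricted to
`[tS7, tS8]`.

**LED screen.** White: binarise the trace with `sample ≥ ThD1`; compute the
first difference of the mask padded with a leading zero; every `+1`
position is a rising edge (an edge can therefore never fall on sample 0,
and generated traces always begin in the neutral regime); group edges by
keeping the first and then every edge that exceeds *the immediately
preceding edge* by more than `indxGap = round(fs · Lisi)` samples.  Black:
identical pipeline on `sample ≤ ThD2`.  Two deliberate choices:

* *Black-mask polarity.*  `ThD2` is defined as the level **below** which
  the black-stimulus drop falls, so the default comparator is `≤`.  The
  opposite (`≥`) comparator is selectable via `led_black_polarity="above"`;
  as the tests demonstrate, it marks everything except the dip and its only
  rising edge is the dip's end, i.e. it reports the stimulus *offset* — the
  `≤` form is the physically meaningful one.
* *Grouping comparator.*  The previous-edge comparison is the literal rule;
  `group_policy="last_onset"` compares against the last retained onset
  instead.  The two coincide whenever each stimulus contributes a single
  edge and consecutive onsets are more than `Lisi` apart, and differ on
  edge bursts (see HMD below).  No rounding rule for `indxGap` being
  implied by `fs·Lisi`, nearest-integer rounding is used.

**HMD.** White stimuli reuse the LED pipeline with the HMD `ThD1`.  Black
stimuli cannot cross a low threshold on a display that is mostly dark
between refreshes, so they are detected structurally: find every strict
local maximum of the trace (plateaus count once, at their first sample; no
prominence or width filtering), then mark every peak belonging to a run of
`hmd_run_window = 11` consecutive peaks whose heights are all strictly
below `ThD2`.  The marked positions form a binary mask fed through the same
edge/grouping tail, so the reported onset is the first small peak of each
run.  The run condition has a second, looser reading that checks only the
run's 1st, 2nd, 3rd and 11th peaks (`hmd_run_rule="literal"`); both rules
agree on traces whose 11-peak windows are homogeneous, which the tests
assert, and the all-of-window rule is the default as the strictest
consistent interpretation.  No back-correction of the run-detection delay
is applied: on a free-running refresh train the black onset lands on the
first refresh peak at/after the true onset, a constant delay bounded by one
refresh period (regression-tested).

**Thresholds** are mandatory user inputs, mirroring the visual-inspection
step of the protocol; `suggest_thresholds` (midpoints between the trace
median and its 0.1/99.9 percentiles) is a convenience starting point and is
never applied silently.

## Pairing

The protocol guarantees one display onset per sent trigger, so the default
pairing is strict index alignment, which fails loudly (with both counts) on
any mismatch and rejects negative implied latencies.  The
`nearest_following` policy pairs each trigger with the earliest unconsumed
detection within `(tS, tS + max_lag]` (default `Lisi`) and reports
unmatched events, for noisy traces where strictness is wrong.

## Synthetic-data generator

The generator emulates the study protocol: ~100 white + ~100 black
full-screen stimuli, trigger-to-trigger ISI uniform in 1.0–1.5 s, stimulus
duration 0.3 s, `fs` = 500 Hz by default (the amplifier rate is a free
parameter; real files carry theirs in the header), markers S7 / S1 / S2 /
S8, and per-event latency `latency_ms + N(0, jitter)` truncated at 0, with
independent white/black values available because the two can genuinely
differ on an HMD.  Default levels place white/neutral/black at
70000/40000/10000 (LED) and 200000/100000/5000 (HMD peak heights), so the
reference thresholds 60000/20000 and 180000/8000 separate the regimes with
wide margins; configurations whose noise SD reaches 10 % of the smallest
level gap, or whose levels do not bracket the reference thresholds, are
rejected before generation.

Morphology choices:

* *LED*: square pulse at the stimulus level for the stimulus duration, with
  a 2-sample half-cosine ramp whose mid-level sample precedes the quantised
  onset sample — detection consumes the threshold crossing, not the shape,
  and this places the crossing exactly on the onset sample for any
  threshold between the mid and full levels.
* *HMD*: single-sample peaks over a zero valley floor, spaced
  `round(fs/refresh_hz)` samples (6 at 500 Hz / 90 Hz — the train is
  quantised to the sample grid, so the effective rate aliases to ~83 Hz).
  The train is re-phased so a peak falls exactly on each quantised stimulus
  onset.  A physical panel free-runs instead; the re-phasing removes up to
  one refresh period of onset quantisation that would otherwise fold into
  every synthetic latency, letting tests assert sample-exact recovery.  The
  free-running case is covered separately by a regression test of the
  constant detection delay.
* *Presentation order* defaults to strict white/black alternation (the
  ON/OFF scheme).  This also keeps consecutive same-type events ≥ 2 ISIs
  apart, which the literal previous-edge grouping comparator *requires*
  whenever one stimulus yields a burst of edges — on an HMD every stimulus
  does, and under random interleaving two same-type neighbours sit only
  `ISI − 0.3 s < Lisi` apart in edge space and the second would be dropped.
  `order="random"` exists for stress-testing that exact behaviour.

Markers are quantised to the sample grid (that is where an amplifier
records them), so a generated session written as a BrainVision triplet and
read back reproduces the in-memory analysis bit for bit; ground truth keeps
the continuous send/onset times.

What the generator does *not* model: photodiode physics (dark current,
nonlinearity, panel rise time), amplifier filtering, marker-transmission
jitter on the trigger line, or drift between software and amplifier clocks.
Passing tests therefore demonstrate the correctness of the detection
algebra and the end-to-end plumbing under the stated protocol, not
robustness to every real-world artefact; on real recordings the thresholds
remain a per-session judgement call.

## Numerical and format choices

* BrainVision reader: INT_16 / INT_32 / IEEE_FLOAT_32, multiplexed or
  vectorised, samples scaled by the per-channel resolution and kept in raw
  ADC units (thresholds are defined on that scale); non-finite samples are
  rejected at load rather than interpolated.  Fixtures are written as
  IEEE_FLOAT_32, making the write→read round trip exact.
* Problem sizes: the test suite and acceptance script use 100 events per
  stimulus type for calibrated runs (the study's scale), 25 per type across
  the 20-seed count-conservation sweep, and 1000 random masks (lengths up
  to 10 000) for the oracle-equivalence sweep; one full acceptance run
  completes in a couple of seconds.
* Latency tables render times and latencies with 6 decimals; the summary
  (n, mean, SD) rides in a trailing `#` comment block so the CSV body stays
  machine-readable.

## Known limitations

* Sub-sample onset interpolation is out of scope; resolution is one sample
  period (2 ms at 500 Hz).
* The HMD black-onset delay of a free-running panel (≤ one refresh period)
  is reported uncorrected.
* Per-eyepiece analysis of dual-display headsets is not implemented.
* Adaptive/learned threshold selection is deliberately absent; thresholds
  are part of the experimental record and should be chosen by inspection.
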