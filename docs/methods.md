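# Methods

This note documents the models, numerical choices and open design
decisions behind `qrstress`, and what its synthetic-data tests do and do
not demonstrate about real recordings.

## SNR definition and mixing

The contaminated signal is `clean + a·noise`. Power `P` is defined as
**variance** (mean removed). The literature on noise-stress protocols
rarely states whether `P` is a raw mean square or a variance; variance
was chosen because it makes the SNR invariant to DC offsets in either
component, which matters when the baseline-wander surrogate or a real
noise record carries an offset. Powers are computed over the full
analyzed segment (not beat-wise windows), on exactly the aligned noise
segment that gets added, so back-substituting into the SNR formula
recovers the target to floating-point precision (the test suite checks
1 µdB; the achieved error is ~1e-15 dB).

Noise shorter than the signal is tiled end-to-end without crossfade —
a documented surrogate for the unstated alignment practice in published
stress tests. The alignment offset defaults to 0; `"random"` alignment
(seeded) is used for replicate sweeps, since any fixed alignment is
arbitrary.

## Synthetic ECG

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with default
amplitudes 0.15, −0.10, 1.00, −0.25, 0.30 mV, centers −200, −28, 0,
+28, +300 ms relative to R, and widths (SD) 25, 10, 12, 10, 60 ms —
an R peak of 1 mV, a QRS spanning roughly 80 ms, a 0.3 mV T wave.
A dynamical-system morphology model was deliberately avoided: the
Gaussian construction has analytically known beat locations, which is
the property the evaluation layer needs.

Beats sit on an RR sequence with mean `60/heart_rate` seconds and
multiplicative jitter `rr = mean·(1 + jitter·z)`, `z` standard normal
clipped at ±3 (default jitter 0.05, a realistic short-term heart-rate
variability). The first beat is placed half an RR interval into the
record and the last at least 0.4 s before the end, so every annotated
beat's QRS (and most of its T wave) lies fully inside the record.
Annotations are snapped to the sample-level R maximum (the continuous
R center can fall between samples). All randomness comes from one
`numpy.random.Generator` seeded per spec, so outputs are bit-identical
across runs.

## Noise surrogates

The three generators match the *spectral bands* of the classical
ambulatory noise classes, not the amplitude statistics or
non-stationarity of measured noise records:

* **BW** — 8 sinusoids with random frequencies in [0.05, 0.8] Hz,
  random phases and amplitudes; everything below 1 Hz.
* **MA** — white Gaussian noise band-limited (4th-order zero-phase
  Butterworth) to 20 Hz up to min(1000, fs/2); at 360 Hz the nominal
  1000 Hz upper edge is capped at the 180 Hz Nyquist limit, so the
  filter degenerates to a 20 Hz high-pass.
* **EM** — band-limited noise in 1–15 Hz plus a Poisson train of
  smoothed baseline steps (default 6 events/min, ±2 mV, ~50 ms logistic
  rise) emulating abrupt electrode displacement. The step train is
  broadband by design and excluded from the spectral containment check.

The spectral containment property (≥ 90 % of power inside the declared
band, periodogram estimate) holds for every seed tested. Because the
surrogates match bands only, per-record agreement with stress tests run
on measured noise records is not expected; qualitative orderings
(degradation with falling SNR, EM worse than BW) are the reproducible
content.

## Detectors

All filters are 2nd-order Butterworth sections applied causally at the
record's native rate, with the filter state initialized to the DC steady
state of the first sample (suppressing the start-up transient a DC
offset would inject). The classical integer-coefficient filters designed
for 200 Hz data were not reproduced: using native-rate IIR sections
avoids a resampling stage, and the band edges are configuration values.
Published descriptions of these detectors give band edges and window
lengths but not the threshold bookkeeping; those constants are taken
from the classical formulations and are all exposed in
`DetectorConfig`:

* running-estimate mix-in 1/8 (1/4 on search-back acceptance),
  primary threshold coefficient 0.25 (Pan–Tompkins) / 0.3125 (Hamilton),
  search-back at half threshold when the gap since the last beat exceeds
  1.66× (Pan–Tompkins) / 1.5× (Hamilton) the mean of the last 8 RR
  intervals, 300 ms refractory, and T-wave rejection for candidates
  within 360 ms whose maximal filtered slope is under half the previous
  beat's.
* The 2 s learning phase initializes the signal-peak estimate from the
  maximum and the noise-peak estimate from the mean of the transformed
  trace; detection then runs from the start of the record, so beats
  inside the learning window are not forfeited.
* Candidate peaks are local maxima of the transformed trace at least
  200 ms apart; candidates within one integration-window length of
  either record edge are suppressed. Amplitude decisions are left
  entirely to the adaptive thresholds, which makes Pan–Tompkins and
  Hamilton invariant to input gain (WQRS is not, see below).

**WQRS.** The curve-length transform is
`L(t) = Σ_{window} sqrt(c² + Δy²)` with `Δy` successive differences of
the 16 Hz low-passed signal and window 130 ms; the reported signal is
the length *excess* over the flat-line baseline `w·c`. The length-scale
constant `c` (default 5 µV per sample, about one quantization step of a
standard 200 adu/mV 12-bit recorder) sets the slope scale below which
the trace counts as flat — this fixed constant is why WQRS is not
gain-invariant. Onsets are rising threshold crossings followed by a
300 ms eye-closing period; the threshold tracks signal and noise levels
of the length signal (same 1/8 mix-ins) and relaxes halfway toward the
noise level whenever no onset occurs within 1.66× the mean RR, which
substitutes for an explicit search-back. Each onset maps to a fiducial
at the largest absolute filtered deflection (relative to the local
window mean — the low-pass filter does not remove baseline) within
150 ms after the onset, so all three detectors report comparable
R-positions and one matching tolerance serves all of them.

Degenerate inputs: a record shorter than the learning phase raises; a
flat record yields an empty result. After mapping, fiducials are kept
strictly ascending and (Pan–Tompkins, Hamilton) at least 300 ms apart.

## Beat matching

Matching is one-to-one with a 150 ms tolerance (standard beat-by-beat
comparison practice; protocols in this literature rarely print their
window). References are scanned in ascending order and each takes the
*earliest* still-unmatched detection within tolerance. For sorted event
trains each reference's admissible detections form a contiguous run
that shifts right with the reference, so this greedy attains the
maximum-cardinality matching — the test suite verifies equality with an
exhaustive bipartite-matching oracle. TP/FP/FN counts depend only on the
matching cardinality, so any maximum matching yields the same metrics.
Beats of all five AAMI classes count as reference beats; the task is
location detection, not classification.

Aggregation over records defaults to the unweighted per-record mean of
SE and PP; a `gross` mode (pool TP/FP/FN, then apply the formulas) is
provided because published summaries are often gross totals and the two
differ when record difficulty varies.

## Annotation class mapping

Native WFDB beat mnemonics are grouped into the five AAMI classes:

| class | native codes |
|-------|--------------|
| N | N L R B e j |
| S | A a J S n |
| V | V E r |
| F | F |
| Q | / f Q ? |

Non-beat codes (rhythm `+`, quality `~`, artifact `|`, waveform
boundaries, ventricular-flutter waves `!`, …) are dropped; an unknown
beat code warns and maps to Q. Paced (`/`) and paced-fusion (`f`) beats
fall under Q per the AAMI convention; database summary tables that
count `f` under "fusion" will differ in the F/Q split but not in totals.
Channel selection defaults to channel 0 (the modified lead in the
ambulatory databases); all indices are 0-based.

## Problem sizes and limitations

The packaged experiments use 60 s synthetic records (one-record sweeps:
3 noise types × 9 SNR levels × 3 detectors), with medians over 5–10
random noise alignments for stochastic endpoints; these sizes make the
full suite and the acceptance run complete in seconds while leaving
every pipeline stage exercised end-to-end. Longer records or the full
48-record ambulatory database run through the same `SweepConfig`
without code changes.

Known limitations: the synthetic ECG has a single normal morphology —
no arrhythmic beats, no respiration-coupled baseline modulation — so
perfect clean-signal scores here do not predict performance on
pathological rhythms; the noise surrogates match bands, not amplitude
dynamics; WFDB reading covers signal formats 212 and 16 in a single
`.dat` file (the layout of the target databases), and WFDB writing is
out of scope. With these surrogates the broadband muscle artefact, not
electrode motion, is the worst case for the WQRS detector specifically
(its curve length accumulates all high-frequency energy); the
EM-worst-overall ordering holds for the two band-pass-based detectors
and for the pooled worst cell of the band-passed pair.
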