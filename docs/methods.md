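# Methods

## Problem and signal model

A phonocardiogram (PCG) is a digitized acoustic recording of heart sounds.
Each cardiac cycle contains two dominant transients: S1 (closure of the
mitral/tricuspid valves, onset of systole) and S2 (closure of the
aortic/pulmonary valves, onset of diastole).  Detecting the S1/S2 instants
is the first step of any heart-sound analysis.  Two structural facts drive
every algorithm in this package:

1. Most S1/S2 energy lies below 60 Hz.  At the 4000 Hz analysis rate the
   level-6 detail branch (D6) of a Daubechies discrete wavelet transform
   has the ideal dyadic band 31.25–62.5 Hz, making it the natural S1/S2
   feature; the level-5 branch (62.5–125 Hz) catches the upper tail.
2. Systole (S1→S2) is shorter than diastole (S2→S1) in the target
   population, which is what allows S1 and S2 to be told apart from event
   times alone.

All detectors operate on records resampled to 4000 Hz and normalized to
unit peak amplitude; several thresholds (0.2/0.1 in Method IV, the
envelope means) are only meaningful on a normalized signal.

## Wavelet branch decomposition

Branch D_a (resp. A_a) is obtained by discrete wavelet decomposition to
level *a* with half-sample-symmetric extension, zeroing every coefficient
band except the level-a detail (resp. approximation), and reconstructing
to the input length.  Branches telescope, A_{a-1} = A_a + D_a, so
x = A_6 + D_6 + … + D_1 holds to floating-point accuracy (verified to
1e-8 relative in the tests).  The boundary mode is a documented choice;
the branch identities are insensitive to it, band selectivity only weakly
so.

An important numerical property that shaped the design: the single-branch
projection is **shift-variant** (period 2^a samples) and its effective
kernel is not phase-flat.  The reconstructed D6 of a 40–55 Hz burst
preserves the burst's position on average (zero lag against the input
tone) but its pointwise extremum can sit one carrier half-period
(10–13 ms) away from the raw waveform's extremum, depending on where the
burst center falls on the dyadic grid.  This is why event *localization*
is not done on the D6 branch (see below).

## The five detectors

**Method I** — D5 (db6) → unit peak normalization → framewise 2nd-order
Shannon energy E = −(1/N) Σ x̂²·ln x̂² over 20 ms frames with 10 ms hop →
standardization Ê = (E−μ)/σ → candidate regions where Ê exceeds its mean.

**Method II** — 2nd-order Shannon envelopes of D6 and of the A5 branch;
the D6 envelope minus λ·mean (λ = 3) acts as a pointwise *signal*
threshold on the A5 envelope.  Candidate regions closer than 50 ms are
merged; regions shorter than 30 ms or longer than 250 ms are discarded.
Because the standardized D6 envelope has zero mean, the threshold signal
nearly equals Ê(D6) itself and is rarely exceeded — the method detects
very little, which reproduces its known weakness.

**Method III** — summed details D3+D4+D5 (db6), 3rd-order Shannon energy
(the log operand is |x̂|³ — the printed cube is undefined for negative
samples), standardized and mean-thresholded.

**Method IV** — db5: binarize the unit-normalized |D3+D4+D5+D6| at 0.2,
take the full-length A6 branch of the binary signal, binarize at 0.1;
runs of the result are the candidate regions.

**Method V (dual moving averages)** — x = D6 (db6); y = x²; two centered
moving means, MA_peak (window W1, default 130 ms ≈ one S1/S2 duration)
and MA_wave (window W2, default 270 ms ≈ one whole heart-sound span);
dynamic threshold THR1 = MA_wave + β·ȳ with β = 0.03; *blocks of
interest* are maximal runs with MA_peak > THR1; blocks narrower than
BlockSize (default 60 ms) are rejected as noise.  Window lengths in
samples are rounded to the nearest odd integer (half-integer ties round
up); at the record edges the means shrink to the available samples so
edge events are not suppressed by zero padding.

### Shared post-processing

Each surviving region/block contributes one event: the extremum of the
**raw waveform's absolute value** inside it.  Reference annotations mark
the raw-signal extremum of each sound, so detector and annotation use the
same convention; localizing on the D6 branch instead (configurable via
``detect_from_feature(localize_on=...)``) shifts roughly two thirds of
events by one carrier half-period — beyond a ±5 ms tolerance — for the
phase reasons above.

S1/S2 labels come from the systole-shorter-than-diastole rule applied
*pairwise-locally*: consecutive event pairs (stepping by two) are labeled
(S1, S2) when their connecting interval is shorter than the following
interval, (S2, S1) otherwise; trailing elements are decided against the
preceding interval.  On a complete event sequence the output alternates
strictly.  Local decisions were chosen over propagating a single global
alternation parity because one missed event otherwise flips every
subsequent label (~50% of a record lost for one dropped beat); with local
decisions the damage stays confined to the affected neighbourhood.

## Evaluation

A detection matches a reference event when |Δt| ≤ 5 ms and labels agree
(both configurable).  Matching is one-to-one greedy by increasing |Δt| so
one detection cannot absorb two references; for events separated by more
than twice the tolerance this equals optimal assignment (property-tested
against brute-force matching).  SE = 100·TP/(TP+FN),
+P = 100·TP/(TP+FP), overall accuracy = (SE + +P)/2.  Corpus results pool
TP/FP/FN counts before computing percentages (not averages of per-record
percentages).

## Synthetic phonocardiograms

Each burst is a Gaussian-windowed cosine: envelope sd = duration/6, so
the nominal duration spans ±3 sd.  Defaults: S1 at 40 Hz / 130 ms /
amplitude 1.0, S2 at 55 Hz / 110 ms / amplitude 0.8; per-beat durations
jitter ±20 ms (staying inside the observed 120 ± 30 ms range), amplitudes
jitter ±10%, RR intervals jitter ±3% around 60/HR.  The S1 burst starts
at the beat onset and the S2 burst starts at systole_fraction·RR
(default 0.35), so the S1→S2 interval is always the shorter one.  A beat
is rejected as infeasible when the ±2 sd burst cores would overlap or S2
would spill past the beat.  Background white noise at 25 dB SNR is added
before unit-peak normalization.  Annotations are placed at the realized
extremum of |signal| inside each burst, so an ideal detector can reach
100% at ±5 ms.

A default corpus draws heart rates uniformly from 65–134 bpm and cycles
three amplitude morphologies — balanced (1.0, 0.8), low-S1 (0.3, 1.0),
low-S2 (1.0, 0.3) — one third each.

What the generator does **not** model: S2 splitting, S3/S4 sounds,
murmurs, respiration artifacts, sensor coloration, or amplitude
non-stationarity beyond per-beat jitter.  Passing tests therefore
demonstrate correct mechanics of the detectors and protocol on signals
with the right durations, band, rhythm and amplitude asymmetries — not
clinical-grade performance.

## Noise robustness and parameter search

The robustness experiment adds zero-mean white Gaussian noise calibrated
against the empirical signal power (measured SNR accurate to < 0.1 dB on
20 s records) over the grid {30, 25, 20, 15, 10, 5, 0} dB, with one
independent, counter-derived noise stream per (level, record) so all
methods see identical corrupted records.  Per (method, level) the pooled
overall accuracy is computed; the headline quantity is the lowest grid
SNR at which the dual-moving-average method strictly outscores every
baseline (both "lowest strict win" and "bottom of an unbroken winning
streak" semantics are implemented; the former is reported, the latter is
sensitive to statistical ties between Methods IV and V near 10–15 dB).

The brute-force search evaluates every admissible grid point (W1 < W2,
BlockSize ≤ W1) on defaults W1 ∈ 20–200 ms, W2 ∈ 30–400 ms,
BlockSize ∈ 10–100 ms, β ∈ 0–10%, steps 10 ms / 1 point.  The D6 branch
of each record is decomposed once and shared across all points, making
the search linear in grid size.  Ties on overall accuracy are broken
lexicographically by (W1, W2, BlockSize, β) ascending.

## Known limitations and measured behaviour

* With the default parameters (W1 = 130 ms, BlockSize = 60 ms) and
  systolic fraction 0.35, records above ≈ 115 bpm occasionally lose a
  weak sound: the strong neighbouring sound raises MA_wave locally, the
  weak sound's excursion above THR1 narrows below 60 ms, and the width
  filter rejects it.  On the default 20-record corpus this caps Method V
  at pooled SE ≈ 94%, +P ≈ 97% (clean, ±5 ms, label-strict); with
  label-blind matching SE is ≈ 96%.  This is a property of the method's
  fixed windows at high heart rates, not of the implementation — block
  extraction matches a brute-force scan exactly.
* Method II is faithful to its published form and, as published, detects
  almost nothing (pooled SE ≈ 15%); its threshold signal construction is
  the cause.
* Sample-domain regions for Methods I–III derive from 10 ms-hop envelope
  frames, so region edges are only hop-accurate; event times are not
  affected (they come from the raw waveform inside the region).
* Problem sizes used throughout the test-suite experiments: 20-record
  corpora of 20 s records for detection/robustness, 200 shorter (10 s)
  records for labeling, coarsened grids containing the default parameter
  point for search dominance.
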