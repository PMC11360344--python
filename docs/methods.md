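# Methods

## The processing model

actikit reproduces the classical actigraphy pipeline used by waist-worn
ActiGraph devices and the ActiLife software. The underlying signal model:
human trunk movement during locomotion and daily activity concentrates in
roughly 0.25–2.5 Hz, while gravity appears as a quasi-DC offset on the
vertical (y) axis and sensor noise as broadband low-amplitude fluctuation.
The counts algorithm turns band-limited acceleration energy into a
dimensionless, device-comparable "counts" currency:

down-sample to 30 Hz → band-pass → ×17.127404 (counts per g) → rectify →
clip at 128 / zero below 4 → down-sample to 10 Hz → floor → sum per 60 s
epoch.

Each axis is processed independently. The clip ceiling bounds any epoch
count by 128 × 10 × 60 = 76,800; the dead-band suppresses noise that would
otherwise accumulate over 600 samples/minute. Counts are integers by
construction (floor before summation).

The step path shares the first three (linear) stages but keeps the signed
signal; a step is one full excursion: descent of the scaled signal to ≤ −4
after having been ≥ 0, then ascent to ≥ +4 after having been ≤ 0. Since
arming leaves the signal ≤ −4 and counting leaves it ≥ +4, detection
reduces to alternately seeking the two thresholds, starting with the
descent.

Wear detection is the Troiano (2007) rule on y-axis CPM; intensity
classification is Freedson Adult (1998). Both ship as named, overridable
configuration objects. All totals (axis counts, vector magnitudes,
category minutes, percentages) are computed over wear minutes only.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| sampling rate | 60 | Hz | of the raw input; any rate ≥ 30 Hz works |
| filter rate | 30 | Hz | rate at which the band-pass is defined |
| output rate | 10 | Hz | post-threshold decimation target |
| epoch length | 60 | s | CPM = counts per 60 s epoch |
| scale factor | 17.127404 | counts/g | fixed rescaling of filtered acceleration |
| clip ceiling | 128 | scaled units | strict: exactly 128 passes unclipped |
| dead-band | 4 | scaled units | strict: exactly 4 passes unzeroed |
| step thresholds | ±4 | scaled units | inclusive (≤ −4, ≥ +4) |
| non-wear window | 60 | min | minimum zero-count interval |
| interruption allowance | 2 | min | consecutive minutes with 0 < CPM < 100 |
| interruption ceiling | 100 | CPM | ≥ 100 terminates a candidate interval |
| cut points | Freedson Adult 1998 | CPM | sedentary ≤ 99 … very vigorous ≥ 9499 |

## Filter choice

The default band-pass is the order-8 IIR coefficient set from the public
disclosure of the counts algorithm (`ACTIGRAPH_BANDPASS`): zero DC gain
(~6e-11), stable (max pole modulus 0.963), passband ≈ 0.25–2.5 Hz peaking
near 0.76 Hz at gain ≈ 3.45. Because the passband gain exceeds 1, count
magnitudes depend strongly on the filter: the alternative unit-gain
Butterworth 0.25–2.5 Hz design (order 3, selectable via
`--filter butterworth`) produces roughly half the counts on mid-band
movement. The Butterworth path exists for users who want a fully
self-contained textbook filter; comparability with ActiLife-style outputs
requires the default.

Filter state: the `bandpass` operation defaults to zero initial state (the
plain LTI contract), but the pipeline initialises the filter to the steady
state for the recording's first sample — as if that value had been applied
forever. Rationale: with zero state, switching a recording on under 1 g
gravity injects a start-up transient worth ~273 counts into the first
epoch, which a still device should not produce (and which, counted as a
≥ 100 CPM minute, would break the Troiano rule's view of a leading
off-body block). The steady-state initialisation is proportional to the
first sample, so linearity is preserved and an all-zero signal still
starts from zero state. `CountsConfig.discard_warmup_epochs` additionally
drops leading epochs if desired.

## Resampling

Integer rate ratios (60→30, 30→10 Hz) use plain decimation — keep every
k-th sample from sample 0 — matching the literal description of the chain.
Non-integer ratios use anti-aliased polyphase resampling
(`scipy.signal.resample_poly`); the mode is selectable
(`CountsConfig.resampler`) because resampler choice is a known source of
residual disagreement between reimplementations. Output length is
floor(n·fs_out/fs_in) in all modes.

## Rule interpretations (fixed, shared with the test oracles)

- Thresholds are strict: "greater than 128" clips, "between 0 and 4"
  zeroes; the boundary values 128 and 4 pass unchanged.
- Troiano "counts between 0 and 100" is strict (a 100-CPM minute
  terminates); interruption minutes inside a qualifying interval are
  themselves non-wear; interruptions are strictly interior (intervals
  start and end on zero minutes); separate interruptions are each allowed
  when a zero minute separates them; intervals touching the recording
  boundary qualify on length alone.
- Step thresholds are inclusive; the "having been ≥ 0 / ≤ 0" preconditions
  are declared satisfied at the start of a recording.
- Epochs anchor at the first sample; a trailing partial epoch is dropped
  and logged. Non-finite raw samples are a hard error, never imputed.
- Vector magnitude: the headline total is the norm of the axis totals; the
  per-epoch aggregate (sum of per-epoch norms) is reported separately
  because the two differ whenever activity is spread across epochs, and
  published tables do not always say which is meant.
- Method-comparison reports support both "error of the means" and "mean of
  per-recording errors": the two disagree when recordings vary, and
  published comparison tables have used the latter at higher precision
  than their printed means support.

## The synthetic generator

`synth` renders segment protocols into 60 Hz recordings with gravity
(+1 g) on y:

- `nonwear_still`: exactly (0, 1, 0) g — an idealised off-body device;
- `sedentary`: gravity + Gaussian noise (default sd 0.02 g), below the
  dead-band after filtering, so CPM ≈ 0 while the wearer is "inactive";
- `walk`: a single sinusoid at the step frequency (default 2 Hz, 0.35 g,
  noise 0.01 g) — one cycle per step makes the true step count exact, and
  0.35 g lands the resulting CPM (≈ 3.9k) mid-moderate so the segment's
  intent label matches its classification;
- `vigorous`: multi-harmonic oscillation (default 1.0 g at 2.5 Hz + second
  harmonic, CPM ≈ 7.8k, vigorous band), with smaller x/z components.

True steps sum `round(step_frequency × duration)` over walk segments only;
a vigorous bout's cycles register on the step detector (as running would)
but are deliberately not ground-truth steps, so step-recovery checks use
walk-only protocols. Amplitudes are realistic hip-worn magnitudes but the
generator makes no claim of biomechanical fidelity: no harmonics-rich gait
spectra, posture transitions, device rotation, or autocorrelated noise.
Passing tests therefore demonstrate algorithmic correctness (the chain
computes what it should on signals with known structure), not field
validity on human data.

Known consequence of the idealisation: sedentary segments produce zero
CPM, so a sedentary block adjacent to a ≥ 60-min still block is absorbed
into the detected non-wear interval — real Troiano behaviour on genuinely
quiet wear time. End-to-end mask checks therefore bracket still blocks
with walk bouts.

## Problem sizes and tolerances

Randomised checks use: 100 recordings (1–3 min) for exact oracle
equivalence of the counts chain; 500 recordings for the count ceiling;
1,000 CPM vectors (length ≤ 300) for Troiano-vs-brute-force equality; 500
±10 pulse trains for the step state machine; boundary tolerance of one
minute per edge for non-wear localisation; ±2% for step recovery on walk
bouts; 1e-9 for percentage partitions. Published seven-day comparison
arithmetic is checked at its 2-decimal display precision; the vigorous-
minutes row is excluded because its printed means (17.0 vs 17.0) cannot
reproduce its printed error (0.24%), which reflects per-participant
averaging at higher precision than the table shows.

## Limitations

- The disclosed coefficient set is transcribed from the public algorithm
  disclosure; agreement with proprietary software is validated here only
  through the published comparison's arithmetic, not re-run against
  ActiLife.
- Whether the proprietary chain floors, rounds or truncates at the
  threshold stage, and whether its 60→30 Hz stage decimates or
  interpolates, is not public; floor + decimation are used and both knobs
  are configurable.
- The step algorithm replicates an unpublished draft; its axis choice and
  interaction with clipping are interpretations (vertical axis; no
  clipping before detection — clipping at ±128 cannot change ±4
  crossings).
- Binary .gt3x containers are out of scope; input is RAW CSV.
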