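# Methods

This note records the scientific and numerical choices behind `gaitfluct`:
what the pipeline computes, what the synthetic data emulate, where the
published procedure left details open and how we resolved them.

## Signal model and units

All acceleration is in g (1 g = 9.81 m/s²); conversions happen only at
I/O boundaries. Recordings are nominally 200 Hz from a ±6 g waist sensor;
timestamps must agree with the nominal rate to within a 1% median
deviation, and samples beyond ±6 g are flagged (counted on the recording)
but not silently rejected. Axis semantics are explicit per recording: a
bijective mapping of {vertical, forward, lateral} onto the three sensor
columns, each with a sign. The default convention puts the +1 g gravity
bias on `ax` (vertical), forward on `ay`, lateral on `az`; the stride
stage depends on the declared forward axis, which is why the mapping is
part of the data model rather than an implicit assumption.

## Downsampling to the 40 Hz analysis rate

40 Hz retains essentially all gait power, so every analysis stage runs at
that rate. Downsampling without anti-aliasing would fold high-frequency
content into the [0.1, 10] Hz band that the whole method is built on, so
the resampler applies a linear-phase Kaiser-window FIR low-pass (cutoff at
0.8 × target Nyquist = 16 Hz, 60 dB design attenuation, odd length for an
integer group delay) inside polyphase resampling
(`scipy.signal.resample_poly`, line-extension padding to suppress edge
transients). The binding contract, enforced by test, is ≥ 40 dB
suppression of content above the target Nyquist; the unit tests verify a
25 Hz tone leaves less than 1% of its power anywhere in the output
spectrum and a 2 Hz tone keeps its amplitude within 1%. Resampling a
40 Hz recording to 40 Hz is the identity.

## Windowing and spectral band power

Windows are non-overlapping, 3.2 s (128 samples at 40 Hz), tiling the
recording left to right with the trailing remainder discarded. Band power
of a segment is computed as a mean-removed rectangular-window periodogram:
per axis, subtract the mean, take the DFT, sum |X_k|² over the bins whose
centre frequency lies in the closed band [b₁, b₂] (mirrored bins counted
twice, DC and Nyquist once), scale by 1/m², and add the three axes. The
scaling makes the value a *mean-square* power in g², invariant to segment
duration for stationary signals — so stride fluencies are comparable
across cadences and episode lengths. Two consequences are used as test
oracles: band powers over a disjoint partition of (0, Nyquist] sum
exactly to the segment's mean-removed mean-square power (Parseval), and
scaling the signal by k scales every band power by k². Band membership is
decided on bin centres with a 1e-9 Hz tolerance; the 0 Hz bin is excluded
whenever b₁ > 0 (and is zero anyway after mean removal). Gravity and slow
posture drift are handled purely by the 0.1 Hz lower band edge — no
explicit gravity removal is applied before feature extraction; this
mirrors the band-restriction-only design and is a known sensitivity of
the method.

## Walking detection

Features are the band powers in [0.1, 3] Hz and [0.1, 10] Hz. The
classifier is an SVC with RBF kernel; C and γ are selected by stratified
10-fold cross-validated accuracy over logarithmic grids C ∈ 2⁻⁵…2¹⁵,
γ ∈ 2⁻¹⁵…2³ (step ×4). Classes are weighted inversely to frequency
because rest dominates daily recordings. A window on the decision
boundary counts as not-walking — the conservative choice, since a false
walking window manufactures spurious strides. Prediction evaluates the
RBF decision function directly from the stored support vectors, so a
model serialized to JSON (with a SHA-256 checksum) reproduces its
predictions exactly after reload.

The band-selection procedure that justified the two fixed bands is
reproduced as an offline tool: all 19,900 ordered band pairs on the
0.1-Hz grid up to 20 Hz, ranked by a deterministic ReliefF (k = 10
neighbours, every instance an anchor, min–max-scaled features, Manhattan
distances, stable tie-breaks). It is not in the runtime path; the
shipped classifier uses the two fixed bands.

## Strides and fluency

Within each maximal run of walking windows, the first and last window are
dropped (gait initiation/termination). Initial contacts are relative
maxima of the forward acceleration with a minimum separation of 0.35 s
(max cadence ≈ 2.9 steps/s) and minimum prominence 0.05 g — both exposed
in `PeakParams`. A waist sensor sees one contact per *step* (both feet),
while the method counts *strides*; we therefore pair event i with event
i + 2, stepping i by two, so strides are non-overlapping and span two
steps. Strides outside 0.5–4.0 s are discarded. Stride fluency is the
3-axis band power in [0.1, 10] Hz of the stride's samples (the same
estimator as Phase 1, duration-normalised); whether the original
procedure used the forward axis only is not documented — we use the
3-axis sum for consistency with the walking features. The episode value
is the mean fluency after removing the first two and last two strides; an
episode needs ≥ 5 strides for the mean to be defined (otherwise the 2+2
exclusion leaves nothing), while the reported stride count is the
pre-exclusion count used by the ≥ 10-stride filter. The AUROC band
search over stride powers (average-rank Mann–Whitney statistic,
lexicographic tie-break) is likewise provided as an offline reproduction
tool.

## Patient-specific threshold

Episode fluency is scalar, so the linear-kernel maximum-margin SVM's
separating hyperplane is a scalar threshold θ (the zero-crossing of the
decision function; whether the published threshold was prior-shifted is
unknown — we take the raw zero). C is selected by cross-validated
accuracy with 10 folds when both classes have ≥ 10 patterns, else 2
folds; when a class has a single pattern no cross-validation is possible
and the separator is fitted at C = 1 (recorded as 0 folds). Balanced
class weights compensate the typical OFF minority. The decision rule is
fixed: mean fluency strictly above θ ⇒ ON; equal or below ⇒ OFF.
Calibration uses a stratified random 20% per class (ceiling), repeated 30
times with seeds base + r; "consecutively recorded" in the protocol could
also be read as a consecutive block, but the same description calls the
selection random and motivates the 30 repeats by selection arbitrariness,
so stratified random draws are used.

## Validation protocol

Decisions are timestamped at the episode midpoint and labeled by the
diary interval containing that instant. Exclusions, applied in a fixed
order so every dropped decision has exactly one reason code: undefined
fluency; no gold standard at the timestamp; within ±5 min of any
transition between differing states (synchronisation margin, intervals
merged when they overlap); the episode span straddles a transition;
INTERMEDIATE interval; UNDEFINED interval. The bookkeeping identity
`total = scored + Σ drops-by-reason` holds by construction and is
asserted on every run. Metrics use OFF as the positive class:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV
TN/(TN+FN); zero denominators yield an undefined metric, rendered as a
dash in tables and excluded pairwise from cohort summaries. Cohort
summaries report mean, median and IQR (linear-interpolation type-7
quantiles, recorded in the report metadata) over per-patient repeat
means; patients whose calibration split is infeasible (< 2 decisions in
either class) are listed as excluded. Both variants — all segments, and
segments with ≥ 10 strides — are always emitted. Diary minutes per state
are reported alongside the scored episode minutes, since the published
tables do not say which of the two their minute counts use.

## Synthetic data

The generator emulates the *validation sessions*, not whole days: a
200 Hz triaxial signal of alternating rest and walking bouts under an
ON/OFF phase schedule, with exact ground truth (walking mask, contact
times, per-bout state).

* **Gait waveform** — per axis, three harmonics of the step frequency
  with fixed per-patient phase offsets; the forward axis keeps all
  harmonics in cosine phase so its maxima are the initial contacts, which
  makes the ground-truth contact times exact by construction. Amplitude
  ramps (1 s half-cosine) emulate gait initiation/termination. Cadence
  varies by an AR(1)-smoothed 2% jitter (τ = 2 s).
* **ON/OFF signature** — OFF is the baseline (defaults: step frequency
  1.5 Hz; amplitudes ~0.08–0.18 g on the fundamental); ON scales all
  amplitudes by the fluency contrast (default 1.8, so ON/OFF band-power
  ratio ≈ 3.2) and walks at 1.9 Hz. INTERMEDIATE phases sit midway.
  Because fluency is duration-normalised mean-square power, setting the
  contrast to 1.0 makes ON and OFF spectrally indistinguishable even
  though cadences differ — the chance-control condition.
* **Schedule** — phases alternate ON/OFF with lognormal durations
  (median 1.5 h, matching the typical 1–3 h persistence of motor
  phases), occasionally interrupted by short INTERMEDIATE (10%) or
  UNDEFINED (5%) phases that exist to exercise the exclusion rules.
  Walking bouts have exponential inter-bout gaps (mean 60 s) and
  lognormal durations (median 30 s, clipped 8–120 s), calibrated to the
  *session-level* activity of the validation recordings (an algorithm
  output roughly every minute or two) rather than to whole-day walking
  frequency. The diary is the true timeline with interior boundaries
  delayed by a 20 s reporting latency — well inside the 5-min margin.
* **Noise** — white noise (σ = 0.03 g) everywhere, +1 g gravity on the
  vertical axis, and occasional sub-0.1 Hz posture drift (~0.015 g)
  during rest, deliberately below the analysis band.
* **Cohorts** — per-patient jitter of step frequency (±8%) and amplitude
  (±20%), drawn deterministically from the base seed; optionally the last
  k patients receive an all-ON schedule ("scarce-OFF") to exercise the
  exclusion path of the validation protocol.

What the simulator does **not** model: freezing of gait, festination,
dyskinesia, tremor, non-gait activities (stairs, carrying loads), sensor
artefacts, or realistic inter-stride biomechanics. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
it recovers a known spectral ON/OFF contrast under realistic noise and
scheduling — not that the published clinical accuracy transfers to real
patients.

## Problem sizes and determinism

The acceptance computations use a training cohort of 3 × 20 min synthetic
sessions (≤ 300 windows per class) for the walking classifier and a
validation cohort of 15 patients × 3 h at the default contrast, with 30
repeated splits — the study's patient count and session length — plus a
contrast-1.0 chance cohort and a 15-patient, 1.5 h cohort with four
scarce-OFF patients (shorter phases, so each patient still contributes
enough labeled decisions after the 5-min margins). Unit tests use
30-minute sessions with 5-min phase medians. All randomness flows from
explicit seeds: simulation from per-patient seeds spawned from a base
seed, cross-validation folds from estimator `random_state`, repeat r of
the split protocol from base_seed + r. Reported SDs are population SDs
over repeats.

## Known limitations

* The exact ReliefF variant, SVM grids and the rule for picking the final
  two bands from the ranking are not documented in the source procedure;
  the implementations here are canonical choices and the band-selection
  path is a reproduction tool, not the runtime path.
* Fluency uses the 3-axis sum; if the original used the forward axis
  only, absolute fluency values differ (the threshold calibration absorbs
  most of this).
* The method is silent while the patient is at rest; long gaps between
  outputs are expected and are reported as the mean output interval.
* Threshold drift with disease progression is out of scope; thresholds
  are fitted per session.
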