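# Methods

`weareeg` models the signal chain of a low-channel wearable EEG device —
a glasses-style acquisition front end with frontotemporal electrodes
(F7, T7, F8, T8 of the 10–20 system) — and the two applications such a
device targets: epileptic-seizure detection on bipolar derivations
(F7T7, F8T8) and cognitive-workload classification. This note documents
the models, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical decisions that were
genuinely open.

## Seizure-detection pipeline

**Pre-processing.** Recordings are band-pass filtered with a zero-phase
4th-order Butterworth design, [1, 20] Hz for detection ([1, 30] Hz for
acquisition-quality analysis). "Zero-phase 4th-order" is read as a
4th-order design applied forward and backward (`sosfiltfilt`), giving an
effective 8th-order magnitude response and no phase distortion; edge
transients are handled by scipy's reflect padding. Average removal
(across-channel or running-mean) is available but **off by default** in
the detection pipeline: with only two bipolar channels the across-channel
mean would mix the derivations, and the band-pass already removes DC and
baseline wander. The filtered signal is sliced into 4 s windows with a
0.5 s step (87.5 % overlap); window counts use
`floor((duration − win)/step) + 1` with second-valued start times as the
authority (sample indices are rounded per window, so non-integer steps
cannot drift).

**Artifact handling.** A deliberately lightweight threshold mask: a
window is flagged when any sample exceeds 400 µV or its RMS exceeds 8×
the per-channel median window RMS. The thresholds sit far above the
synthetic background (≈20 µV RMS) and above ictal amplitudes, so
seizures are never masked; flagged windows keep their indices but carry
NaN features and are excluded from training and inference. The interface
is pluggable because richer artifact-removal schemes exist; this policy
is the package's own documented choice.

**Features.** 56 features per window per channel, assembled from the
classic low-power EEG families:

* 8 time-domain: line length, mean |amplitude|, mean, variance (population,
  1/n — matching the signal-power semantics of Hjorth activity), standard
  deviation, Hjorth activity/mobility/complexity;
* 8 band powers: absolute + relative Welch power in delta [1,4), theta
  [4,8), alpha [8,12), beta [12,20) Hz;
* 10 entropies: Shannon (10 and 20 amplitude bins over mean ± 3σ),
  Tsallis (q = 2, 3), Rényi (α = 2, 0.5), sample entropy (m = 2 and 3,
  r = 0.2σ, Chebyshev matching; a no-match result is recorded as a large
  finite sentinel meaning "maximally irregular"), permutation entropy
  (order 3 and 5, delay 1, normalized by ln order!);
* 30 wavelet statistics: mean, SD, energy, mean |coefficient|, line
  length, max |coefficient| over the five subbands of a 4-level
  Daubechies-4 decomposition with periodization boundary.

No single canonical 56-feature list exists in the literature; this
composition honours the named families and the count while remaining
fully configurable — the registry manifest (names + parameters) is
written beside every feature matrix so the composition is auditable.
Windows are processed in chunks of 2048 so heavily overlapping window
lists are never materialized as one array (peak extraction memory stays
below ~100 MB regardless of record length).

**Inference.** A Random Forest on the per-window feature vectors.
Defaults: 100 trees for seizure detection (the workload configuration
uses 200, or 400 for a full-cap montage), balanced class weights, and a
deterministic per-class cap of 5000 training windows — background
windows vastly outnumber ictal ones and subsampling them keeps
hour-scale corpora tractable on one core without hurting a separable
problem.

**Posterior smoothing.** A causal log-odds accumulator: over a sliding
horizon of H past windows, posterior odds = prior odds ×
Π p_i/(1−p_i), clipped to [1e−6, 1−1e−6]. H = 1 with a flat prior is
the identity; the output at window t never depends on later windows
(asserted by a truncation-invariance test). Defaults: flat prior,
H = 8 (4 s of 0.5 s steps). The likelihood ratio p/(1−p) takes the
forest's class probability at face value; probability calibration is out
of scope.

**Alarm building.** Maximal runs of smoothed posterior ≥ threshold
become candidates; candidates closer than `merge_gap_s` merge, then
candidates shorter than `min_duration_s` are dropped (merge before
drop, so fragmented detections of one event survive the duration
filter). Defaults: threshold 0.8, min duration 2 s, merge gap 30 s —
a plausible operating point, all three config-exposed since no single
published operating point exists.

**Evaluation.** Time-slice cross-validation: candidate boundaries are
record ends (or fixed slices for continuous data); the warm-up boundary
is the first with ≥ 5 h of data and ≥ 1 seizure before it; fold k trains
on everything before boundary k and tests on the next slice, so test
spans tile the post-warm-up timeline exactly once and no test window
starts before its training boundary. Event scoring is any-overlap
matching (pre/post-ictal tolerances default to 0 s): each reference
event overlapped by ≥ 1 alarm is one Tp, else one Fn; each alarm
touching no reference event is one Fp. Sens = Tp/(Tp+Fn),
Prec = Tp/(Tp+Fp), F1 their harmonic mean, FAR = Fp·24/test-hours.
Subject scores pool fold confusion counts; cross-subject aggregation is
an unweighted macro-average in which undefined metrics (e.g.
sensitivity of a fold with no reference events) propagate as
not-applicable and are excluded, never coerced to 0.

**Workload scoring.** Window-level Acc, Sens, Spec, and Gmean =
√(Sens·Spec), in percent. The Gmean formula circulates in a variant
using precision instead of specificity; published value tables
(82.9, 66.1 → 74.0; 73.3, 87.7 → 80.2) are consistent only with the
specificity reading, which is what this package computes (the
discrepancy is noted in the `CWMScore` docstring). The RFECV harness
ranks features by forest importance, drops the weakest per iteration,
and selects the subset maximizing cross-validated Gmean (stratified
folds, 30 by default), or stops at a requested subset size.

## Acquisition-front-end characterization

With VREF the ADC reference (default 4.5 V, the reference of the
targeted 24-bit EEG front end; always overridable) and G the PGA gain:

    IRN_rms = sqrt(mean(v²))            IRN_pp = 6.6 · IRN_rms
    DR   = 20·log10(VREF / (√2·G·IRN_rms))        [dB]
    ENOB = log2(VREF / (√2·G·V_rms))              [bits]
    NFB  = log2(2·VREF / (G·IRN_pp))              [bits]
    CMRR = 20·log10(V_in,peak / V_residual,peak)  [dB]

Numerical decisions:

* **IRN and DC.** A shorted input may sit on an offset, and offset is
  not noise: the default subtracts the sample mean first; a flag
  computes the literal RMS of the raw stream. A warning is issued below
  10,000 samples, the guideline count for a stable estimate.
* **NFB dialect.** The √2 variant of NFB (reading it as ENOB with
  peak-to-peak noise substituted) does not reproduce standard front-end
  datasheet tables; the full-scale-range form above does, so it is the
  default and the variant is exposed as `formula="printed"`.
* **CMRR sign.** The ratio is reported input-over-residual so rejection
  is a positive dB number, the conventional sign.
* **Amplitude estimation.** The residual sinusoid amplitude is the
  peak-bin magnitude of a flat-top-windowed DFT — the flat-top main lobe
  is flat enough that scalloping loss is < 0.1 % wherever the tone falls
  between bins (a 3-bin energy sum was rejected: the wide main lobe
  makes it over-count by up to 70 %).
* The 6.6× peak factor is exact only for Gaussian noise observed long
  enough; measured peak-to-peak figures from other sources need not obey
  it and are taken as given.

The IFCN clinical-EEG check evaluates, inclusively: Fs ≥ 200 Hz,
resolution ≤ 0.5 µV/bit, input impedance ≥ 100 MΩ, CMRR ≥ 110 dB (at
the amplifier input), IRN ≤ 1.5 µV peak-to-peak over 0.5–100 Hz. A
missing measurement renders the overall verdict indeterminate rather
than pass/fail.

## Dual-device agreement

Two devices sampling the same physiology at different rates are
compared by (1) band-limited polyphase resampling of the second device
to the first one's rate, (2) dynamic time warping restricted to a
Sakoe–Chiba band of 0.25 s for the residual timing error, on z-scored
segments of a 60 s analysis window, (3) averaging warped samples per
reference index so each reference sample pairs with exactly one aligned
value, and (4) Pearson correlation on the aligned raw amplitudes.
Restricting the warping matters: an unconstrained DTW can align almost
anything and inflates r. Alignment is polarity-aware (the z-scored
query is warped at whichever polarity has lower DTW cost) because a
flipped electrode pair is anti-phase, and warping against the wrong
polarity would let DTW shift by half-periods and fake a positive
correlation; r(a, −a) = −1 as it should be.

Spectra are Welch periodograms over 4 s epochs (Hann taper, 50 %
overlap — epoch length is the stated parameter, the taper and overlap
are this package's standard choices), giving a 0.25 Hz grid; the
integrated density recovers the segment variance within 5 %.
Bland–Altman statistics are computed on raw per-bin PSD differences
(log-PSD as an option): MD ± 1.96·SD limits and the fraction of bins
inside them.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of their spec (seed included); the
same spec is bit-identical. Per-record seeds derive as master + index.

* **Background**: Gaussian noise shaped to a 1/f^slope spectrum
  (slope 1, 20 µV RMS default) plus optional fixed-frequency
  oscillations; the power-law shaping is held flat below 0.5 Hz to bound
  low-frequency energy.
* **Alpha sessions**: a 10 Hz oscillation gated inside annotated
  eye-closure intervals with 0.25 s smoothed edges.
* **Seizures**: amplitude-modulated sinusoids (default 4 Hz, 100 µV)
  with a mild downward chirp, a 0.4-weight second harmonic, a one-third
  rise ramp and one-sixth decay — this produces the line-length and
  low-band-power contrast ictal EEG shows (≥ 3× background RMS) without
  claiming physiological realism.
* **Artifacts**: biphasic < 4 Hz blink pulses on the first (frontal)
  channel at a Poisson rate.
* **Noise floors**: zero-mean Gaussian samples quantized at the
  front-end code width (2·VREF/(G·2²⁴)).
* **Dual-device views**: polyphase resampling, constant timing offset,
  gain mismatch, additive sensor noise.

The reference seizure corpus is 10 one-hour two-channel records at
128 Hz with 12 seizures (records 0 and 9 carry two each), 0.5
blinks/min at 120 µV. 128 Hz is a realistic wearable rate whose Nyquist
comfortably covers the [1, 20] Hz analysis band and keeps a desk-scale
run in minutes; clinical corpora at 256 Hz are handled identically
through the same reader path. Event geometry (duration 60 s, ≥ 300 s
separation, 120 s margins) scales down proportionally for shorter
records.

**What passing on this corpus shows — and does not.** The synthetic
ictal morphology is, by construction, separable from background in the
feature space the pipeline extracts. End-to-end perfect sensitivity at
near-zero FAR on it therefore validates the *plumbing* — causal fold
construction, feature extraction, smoothing, alarm building, event
scoring — not clinical detection performance. Real scalp EEG has
non-stationary backgrounds, electrographically diverse seizures, and
artifacts that mimic them; performance figures on the synthetic corpus
do not transfer.

## Problem sizes and determinism

Desk-scale defaults (the package's own choices): the reference corpus
above for the end-to-end check (~5 min on one core); 60 s noise floors
at 250 Hz (15,000 samples) for characterization round-trips; 150 s
common-mode streams; 70 s backgrounds for agreement (60 s analysis
window). Every stochastic component takes an explicit integer seed;
forests fix `random_state`; the rest of the pipeline is deterministic,
so identical configs reproduce identical outputs byte for byte.

## Known limitations

* EDF support is plain 16-bit EDF with one-second records and integer
  sampling rates; EDF+ embedded annotations, BDF, and streaming ingestion
  are out of scope (annotations travel in plain-text summary files).
* The event scorer implements any-overlap matching only; framework-grade
  scoring conventions with onset/offset tolerances are reduced to the
  configurable pre/post-ictal tolerance defaulting to 0 s.
* Sample entropy is O(n²) per window (numba-compiled); at much higher
  sampling rates than the defaults it dominates extraction time.
* The forest's probability output is used uncalibrated in the
  likelihood-ratio smoother.
* Electrode-impedance measurement, thermal/flicker noise decomposition
  and any on-device concerns (fixed-point inference, memory budgets,
  radio) are out of scope.
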