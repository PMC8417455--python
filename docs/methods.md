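# Methods

## Scientific problem

In drug-resistant focal epilepsy, intracranial EEG (iEEG) is used to locate
the epileptogenic zone before resective surgery. High-frequency oscillations
(HFOs) — brief 80–500 Hz transients — are an established interictal biomarker,
but the *background* high-frequency activity (HFA) that remains between
detected events also carries localising information. This package implements a
pipeline that quantifies that background: it redacts every detected HFO and
artifact from band-filtered interictal iEEG, describes what remains with 38
waveform-morphology features, and converts them into per-channel biomarkers of
the seizure-onset zone (SOZ) — a cross-validated pathological-HFA (pHFA) score
in [0, 1] and its product with the channel's HFO rate.

## Pipeline model and assumptions

1. **Preprocessing** (`phfa.preprocess`). Channels are re-referenced with a
   common average computed separately over depth and grid/strip electrodes
   (different reference groups see different noise). Only interictal data are
   analysed: every sample within 30 min of a seizure start (and inside the
   seizure interval when its end is documented — ictal data must never leak
   in, even though the exclusion rule is stated in terms of distance from
   onset) is excluded. The remaining record is tiled into consecutive 5-min
   epochs anchored at the recording start; an epoch is used only if fully
   interictal. All annotated HFO and artifact intervals are then redacted
   per channel — an event on one channel does not redact another, since
   events are detected per channel. Sample indexing is 0-based with
   half-open intervals.

2. **Band filtering** (`phfa.filters`). Two bands: 30–80 Hz (low gamma) and
   80–500 Hz (the HFO range). Each uses a 10th-order elliptic band-pass
   (0.5 dB passband ripple, 65 dB stopband attenuation) applied
   forward–backward for zero phase, realised in second-order sections (a
   10th-order elliptic filter in transfer-function form is numerically
   fragile at multi-kHz sampling rates). Filtering is applied to the full
   per-channel record *before* segments are cut, so redaction boundaries
   never create filter transients. A three-band variant (30–80, 80–250,
   250–500 Hz) is available through configuration.

3. **Morphology features** (`phfa.features`). Within each channel/epoch/band,
   the redacted segments are pooled and described by 19 features built from
   {identity, rectification, line length, curvature, Teager–Kaiser energy}
   × {mean, SD, skewness, kurtosis}, with derivative-based transforms scaled
   by the sampling rate in kHz (f_S) so units are per millisecond and
   features transfer across sampling rates. Nonnegative statistics are
   log-scaled to decibels (10·log10); skewness, which can be negative, is
   arctangent-scaled instead. All features except the amplitude feature f5
   operate on the normalised signal, so they are invariant to amplitude
   scaling. Finite differences are never taken across a redaction gap:
   transforms run per contiguous segment and the transformed samples are
   pooled afterwards.

4. **Time integration** (`phfa.integrate`). Per epoch, the across-channel
   median is subtracted from every channel (removing common temporal drift —
   state changes and technical shifts move all channels at once), then each
   channel's 75th percentile over epochs is taken, emphasising the epochs
   where a channel is most abnormal relative to its neighbours.

5. **Association analysis** (`phfa.association`). Each time-integrated
   feature is tested one at a time with logistic regression of a binary
   channel label (SOZ, resected volume, temporal lobe) on the feature divided
   by its scaled median absolute deviation (sMAD = MAD/Φ⁻¹(0.75)); the odds
   ratio reads "per one-sMAD increase" and is comparable across features.
   Observation weights give every patient equal total influence regardless of
   channel count. Wald CIs and p-values, Bonferroni-corrected over the
   family of tests (default family size 39: 38 features plus the HFO rate).

6. **pHFA score** (`phfa.scoring`). Hold-out-one-patient cross-validation:
   for each fold, training features are whitened (training mean/SD), reduced
   by PCA to the smallest component count capturing ≥ 95% of variance, and a
   logistic regression of SOZ membership is fitted on the component scores.
   Held-out channels are transformed with training parameters only and scored
   in [0, 1]. The product pHFA × HFO rate damps channels where either signal
   is low (a soft logical AND) and is insensitive to the two measures' units.

7. **Asymmetry** (`phfa.asymmetry`). Per patient and biomarker,
   A = (x_in − x_out)/(x_in + x_out) over mean values inside/outside a
   labelled channel set; scale-invariant, in [−1, 1] for nonnegative
   biomarkers. Cohorts are summarised by the median asymmetry with a 95%
   percentile-bootstrap CI (10,000 resamples, fixed seed), and biomarkers are
   compared via per-patient paired differences of asymmetries.

## Pinned numerical conventions

Several conventions are unstated in common usage and are pinned once,
package-wide:

- **Standard deviation**: sample (n−1) denominator everywhere (signal
  normalisation, f5–f9, whitening).
- **Skewness/kurtosis**: moment ratios m₃/m₂^1.5 and m₄/m₂² on pooled
  samples; kurtosis is non-excess by default (3 for a Gaussian), which keeps
  every logarithm argument positive for any sample. An excess-kurtosis
  variant (`kurtosis="excess"`) is provided; with it, platykurtic signals
  produce non-positive log arguments and the record is flagged invalid
  rather than emitting infinities.
- **f6/f16 operate on the signed first difference D(y)** (with the f_S
  factor, consistent with L = |D|); f19 is 10·log10 of the Teager kurtosis
  like its neighbours.
- **Percentile**: the k-th order statistic of n values sits at percentile
  100·(k−0.5)/n, with linear interpolation and clamping at the extremes
  (Hazen; Q75 of {1,2,3,4} = 3.5). The linear-interpolation variant is
  available via `method=`.
- **Moments are permutation-invariant** to ~1e-9 relative: two-pass centred
  computation with numpy pairwise summation, with the array forced into a
  canonical C layout before reductions so results cannot depend on a
  DataFrame's internal block layout.
- **Minimum usable data**: an epoch record is dropped when fewer than 25% of
  its nominal samples survive redaction (features on heavily redacted epochs
  are dominated by segment-boundary noise); invalid or degenerate records
  are flagged and excluded from integration rather than propagated.
- **Association weights** default to patient-equal weights normalised to
  *mean one* (sum = number of channels). This realises "each patient
  contributes equally" while reducing exactly to the ordinary, nominally
  calibrated logistic fit when all patients have equal channel counts; the
  package's calibration study (`phfa.calibration.null_type1_error`) confirms
  a type-I error near 0.05. A per-patient-sum-one scale
  (`weight_scale="patient_sum_one"`) is provided; note that with far more
  channels than patients it deflates the Wald information and makes the test
  conservative. The scale used is recorded in the results object.
- **Separation handling**: the predictive logistic fit is unpenalised; on
  complete separation it falls back to the smallest ridge penalty on an
  escalation ladder (1e-6, 1e-3, 1e-1) that converges, with a warning —
  deterministic and minimally invasive. The association fit flags separated
  features with an unbounded-OR marker instead of a number.
- The predictive logistic regression is unweighted across channels; patient
  weighting is used only in the association analysis (the two analyses make
  different claims, and the predictive procedure is kept as plain as
  possible). PCA after whitening makes the covariance/correlation choice
  moot.

## Synthetic cohorts: what they emulate and what they do not

`phfa.simulate` generates labelled multichannel recordings so every stage is
testable without patient data. Background is 1/f (α = 1) Gaussian noise
(σ = 50 µV) plus white noise (σ = 5 µV) — the simplest process with a
realistic spectral slope and controllable band power. Pathological (SOZ)
channels receive (i) band-limited 80–500 Hz noise raising their high-band
power by `band_power_gain` (default 4), and (ii) Laplace-amplitude
band-limited bursts at Poisson times (default 10/min) that create the heavy
tails targeted by the skewness/kurtosis features without mimicking HFOs.
HFO-like transients (Hann-windowed 80–250 Hz sinusoids, 20–100 ms, 10–40 µV)
are injected at 3/min on SOZ channels vs 0.3/min elsewhere, and broadband
sharp artifacts at 1/min everywhere; all injected events are annotated, so
redaction can be exercised against ground truth. Per-patient seeds are
`master_seed + patient_index`, making generation reproducible and
order-independent.

Default cohort geometry: 24 patients × 16 channels (2 SOZ, 4 RV) × twelve
5-min epochs at 4096 Hz. The generator does **not** model seizure dynamics,
sleep staging, spatial correlation across the electrode array, non-stationary
artifact regimes, or realistic HFO morphology variability. Passing tests on
these cohorts therefore demonstrate that the pipeline detects the planted
statistical contrast (elevated high-band power, burstiness, event-rate
asymmetry) under controlled conditions — not clinical performance on real
iEEG.

## Calibration and validation studies

`phfa.calibration` packages the simulation studies used by the test suite and
the reproducibility script:

- **Type-I error**: 2000 null cohorts (10 patients × 20 channels, label
  independent of the feature); the weighted association test's rejection rate
  at α = 0.05 is checked against [0.03, 0.07].
- **Odds-ratio recovery**: cohorts simulated from a logistic model with slope
  log(1.5) per sMAD (40 patients × 50 channels); the mean recovered OR is
  checked against [1.40, 1.61].
- **End-to-end discrimination**: a scaled-down cohort of 20 patients ×
  8 channels (2 SOZ, 3 RV) × six 5-min epochs at 2048 Hz — sizes chosen so
  the full signal-level pipeline (≈ 0.5 GB of samples per cohort) runs on a
  single CPU in a few minutes while keeping 5-min epochs and a
  >1 kHz sampling rate. With the planted gain of 4 the hold-out-one-patient
  pHFA score is required to reach AUC > 0.9 and median SOZ asymmetry > 0.3;
  the matching null cohort must give median SOZ asymmetry within ±0.1 of 0.
- **Leakage/determinism**: corrupting a held-out patient's features must
  leave that fold's model bit-identical, and fixed-seed regeneration must be
  bit-identical.

## Known limitations

- The EDF writer is minimal (16-bit, 1-s records, per-channel symmetric
  physical scaling); it serves the package's own interchange needs, not
  arbitrary EDF+ features (no annotations channel, no discontinuous records).
- HFO rates are computed from annotation counts over analysed interictal
  minutes; no detector is included — annotations are an input.
- Channels with poor signal quality are expected to be excluded upstream;
  there is no automatic bad-channel detection.
- Asymmetries are undefined for patients whose label covers all or none of
  the analysed channels; such patients are skipped for that label.
- With strongly separable cohorts the pHFA scores saturate near 0/1 (the
  ridge-fallback fit has a very large margin); the score's ranking remains
  informative, but absolute magnitudes should not be over-interpreted.
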