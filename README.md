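# phfa — interictal high-frequency background activity biomarkers for iEEG

`phfa` quantifies the interictal high-frequency *background* of intracranial
EEG — the long-duration activity that remains after every detected
high-frequency oscillation (HFO) and artifact has been redacted — and turns it
into per-channel biomarkers of the seizure-onset zone (SOZ). It is aimed at
epilepsy researchers working with presurgical iEEG who want to go beyond
event counting: the background itself carries localising information.

## What it computes

From common-average-referenced, interictal, event-redacted iEEG filtered into
two bands (30–80 Hz and 80–500 Hz, 10th-order zero-phase elliptic filters),
the package computes **19 morphology features per band** per channel and
5-minute epoch. Each feature is a transform → statistic → scaling chain:

- transforms: identity, rectification R(y)ⱼ = |yⱼ|, line length
  L(y)ⱼ = |yⱼ₊₁ − yⱼ|·f_S, curvature C(y)ⱼ = |yⱼ₊₂ + yⱼ − 2yⱼ₊₁|·f_S²,
  Teager–Kaiser energy T(y)ⱼ = (yⱼ² − yⱼ₊₁yⱼ₋₁)·f_S², with f_S the sampling
  rate in kHz and y the normalised signal (x − μ)/σ;
- statistics: mean, SD, skewness, kurtosis of the transformed samples;
- scaling: 10·log₁₀ for nonnegative statistics, arctan for skewness.

Per-epoch features are reduced to one value per channel by subtracting the
across-channel median within each epoch and taking the 75th percentile over
epochs (*time-integrated features*). Downstream:

- **Association**: per-feature logistic regression of channel labels
  (SOZ / resected volume / temporal lobe) on sMAD-scaled features, with
  patient-equal weights; odds ratios per sMAD, Wald 95% CIs,
  Bonferroni-corrected significance tiers.
- **pHFA score**: hold-out-one-patient cross-validation of
  whitening → PCA (≥95% variance) → logistic regression, giving each channel
  a score in [0, 1]; the product pHFA × HFO-rate is a stricter hybrid
  biomarker (high only where both agree).
- **Asymmetry**: per patient and biomarker,
  A = (x̄_in − x̄_out)/(x̄_in + x̄_out) over channels inside/outside a labelled
  region — a scale-invariant effect size in [−1, 1] — with cohort medians and
  bootstrap 95% CIs.

A synthetic-cohort generator (1/f background, planted high-band power gain
and bursts on SOZ channels, injectable annotated HFOs/artifacts) makes the
whole pipeline testable without patient data. See `docs/methods.md` for
models, conventions and limitations.

## Worked example

Run the full pipeline on a small simulated cohort (6 patients, 8 channels of
which 2 SOZ, four 60-s epochs — a smoke-scale configuration):

```python
from phfa import PipelineConfig, run

cfg = PipelineConfig(
    seed=11,
    epoch_length_s=60.0,
    n_boot=1000,
    cohort=dict(
        n_patients=6, channels_per_patient=8, n_soz=2, n_rv=3,
        epoch_count=4, fs=1024.0,
    ),
)
outdir = run(cfg, "example_run")
```

`example_run/` then contains the per-epoch feature table, the 38-column
time-integrated channel features, association tables, LOPO pHFA scores and
asymmetry summaries, plus a `manifest.json` with the config hash. The
asymmetry summary (`asymmetry_summary.csv`) from this exact run:

```
biomarker label    median     ci_lo    ci_hi  n
 hfo_rate    rv  0.764124  0.570845 0.950014  6
 hfo_rate   soz  0.838084  0.716712 0.956073  6
 hfo_rate    tl -0.025641 -0.807780 0.351117  6
     phfa    rv  0.999998  0.999202 1.000000  6
     phfa   soz  0.999997  0.999551 1.000000  6
     phfa    tl -0.000558 -0.998669 0.930143  6
  product    rv  1.000000  1.000000 1.000000  6
  product   soz  1.000000  1.000000 1.000000  6
  product    tl  0.045765 -1.000000 0.915386  6
```

Reading: each row is the cohort median asymmetry of one biomarker with
respect to one label, with its bootstrap 95% CI over patients. Medians near
+1 for `soz` and `rv` mean the biomarker is concentrated almost entirely on
seizure-onset/resected channels (this toy cohort has a strong planted
effect, so the pHFA score saturates); the `tl` medians near 0 with wide CIs
show no temporal-lobe confound is planted.

The same stages are available individually from the shell:

```sh
phfa simulate  --config cohort.yaml --out-dir data/
phfa features  --edf data/sim00.edf --annotations data/sim00_annotations.json \
               --channels data/channels.csv --out epochs00.csv
phfa integrate --features epochs.csv --out channels_integrated.csv
phfa associate --features channels_integrated.csv --labels data/channels.csv \
               --label-col soz --out association.csv
phfa score     --features channels_integrated.csv --labels data/channels.csv \
               --hfo-rates rates.csv --out scores.csv
phfa asymmetry --scores scores.csv --labels data/channels.csv --out asym.csv
phfa run-all   --config pipeline.yaml --out-dir run/
```

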