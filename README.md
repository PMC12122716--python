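# relapsekit

Personalized, unsupervised detection of psychiatric relapse from long-term
smartwatch recordings.

Patients with psychotic disorders commonly relapse even under treatment, and
day-level clinical annotation is scarce and delayed. `relapsekit` implements
an anomaly-detection pipeline for the kind of data a research smartwatch
emits — triaxial linear and angular motion at 20 Hz, heart rate and RR
intervals at 5 Hz, and device-detected sleep windows — and turns it into a
daily relapse score per patient, trained **without any relapse labels**:

1. **Cleaning** — physiologic range filtering, linear interpolation of gaps
   up to 3 h (longer spans discarded), and ectopic-beat correction of the RR
   stream into NN intervals.
2. **Features** — 12 activity/HRV metrics per non-overlapping 5-min
   interval: mean linear/angular acceleration norm; mean/max/min heart rate;
   mean NN, SDNN, RMSSD; LF and HF band power; Poincaré SD1 and SD2.
3. **Profiles** — 48 × 12 matrices (4 h × 12 features), stratified by sleep
   status and z-scored per patient with statistics frozen on the training
   split.
4. **Autoencoder** — a per-patient 2D convolutional autoencoder (one
   convolution block, 64 filters, 11 × 12 kernel, 15 latent features,
   LeakyReLU, Adam at 1e-4, early stopping with patience 3) trained on
   non-relapse profiles only.
5. **Clustering** — k-means and a full-covariance Gaussian mixture with
   k = 2 over the latent vectors; cluster→relapse orientation and the final
   method are selected by the validation harmonic mean of PR-AUC and
   ROC-AUC.
6. **Evaluation** — the daily score is the unweighted mean of the day's
   4-h window predictions, Ŷ = Σₙ ŷₙ / N; PR-AUC, ROC-AUC and their
   harmonic mean 2ab/(a+b) are reported pooled across patients and per
   patient, next to the positive-rate baseline.

Because the motivating wearable dataset is access-restricted, the package
ships a first-class **synthetic cohort generator** (`relapsekit.synthio`)
whose state-dependent parameters (sleep/awake × relapse/non-relapse) are
calibrated so the *extracted* daily features reproduce configured group
statistics — e.g. a sleep-state mean NN of 759 ± 89 ms in non-relapse vs
683 ± 17 ms in relapse — together with contiguous multi-day relapse events,
nightly sleep windows, missing gaps, ectopic beats and out-of-range
outliers.

## Worked example

```python
from relapsekit import synthio
from relapsekit.cae import CAEConfig
from relapsekit.experiments import run_synthetic_study

table, results = run_synthetic_study(
    synthio.default_study_specs(),      # 10 patients x 21 days
    seed=11,
    experiment_ids=[7, 8],              # sleep-only vs awake-only pipelines
    cae_config=CAEConfig(max_epochs=50),
)
print(table.round(3).to_string(index=False))
```

```
 experiment  pr_auc  roc_auc  harmonic_mean  baseline_positive_rate
          7   0.665    0.614          0.639                   0.566
          8   0.596    0.536          0.564                   0.566
```

Experiment 7 trains the autoencoder and clusters on sleep windows only;
experiment 8 uses awake windows only. The generator concentrates relapse
effects in the sleep state, so the sleep pipeline beats both the
positive-rate baseline (the expected PR-AUC of an uninformative scorer,
0.566 here) and the awake pipeline — the qualitative ordering the method is
designed to expose. The full eight-configuration grid
(`experiment_ids=range(1, 9)`) crosses autoencoder training data
(all/sleep/awake) with clustering data (separate, all, sleep-only,
awake-only).

A command-line interface mirrors the library:

```bash
relapsekit simulate --config cohort.yaml --out raw/ --seed 1
relapsekit featurize --in raw/ --out features/
relapsekit run-grid --config cohort.yaml --out results/ --seed 1
relapsekit evaluate --pred pred.csv --labels labels.csv
```

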