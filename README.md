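# neuropipe

Digital-biomarker analysis for **chemotherapy-induced peripheral
neuropathy (CIPN)** from smartphone assessments. Up to 70% of patients on
neurotoxic chemotherapy develop CIPN — numbness, tingling and motor
symptoms in the feet and hands that impair gait and dexterity. This
package implements the analysis pipeline for a remote-assessment design:
a short in-pocket walking task (inertial accelerometer + pedometer), a
touchscreen nine-hole-peg dexterity task, and the EORTC QLQ-CIPN20 /
PRO-CTCAE patient-reported instruments, analysed case vs control with
PLS discriminant analysis.

It is aimed at mobile-health / biostatistics researchers who need the
full chain as tested, reusable pieces:

* **session_io** — versioned JSON session schema (acceleration +
  attitude quaternions + pedometer, touch traces, survey items) with
  strict validation; missing data are absent keys, never sentinels.
* **surveys** — CIPN20 scale scoring, `score = (mean − 1)/3 × 100` with
  the EORTC half-rule, subscales (CIPN8/CIPN4/CIPN2Feet/CIPN2Hands/CIPNM),
  and the case rule: any of items 1–4 ≥ 3 ("quite a bit"/"very much").
* **gait_features** — quaternion rotation to the world frame, heading/sway
  axis assignment by integrated-velocity SD, QC (duration < 3.50 s,
  in-hand, phone-moved), pedometer step length, and per-axis time- and
  frequency-domain features (spectral Shannon entropy, median and
  dominant frequency, spectral skewness/kurtosis from the normalised
  Welch spectrum).
* **hand_features** — peg-trace segmentation and the 60-feature set:
  2 hands × {place, remove} × {distance, duration, speed} ×
  {mean, median, min, max, SD} over 4 repetitions.
* **multivariate_stats** — ≥70% availability filter, autoscaling with
  logged mean imputation, PCA, orthogonal-scores NIPALS PLS1/PLS-DA,
  VIP scores (Σ VIP² = p; important if VIP ≥ 2 or |loading| ≥ 0.2),
  leave-one-out validation (RMSEP = √(PRESS/n), R² = 1 − PRESS/SS_tot),
  Welch t tests and Pearson chi-square.
* **synthetic_data** — a cohort generator (default n = 26: 17 cases /
  9 controls) in which one latent severity drives shorter step length
  (0.78 → 0.54 m anchors), a broader sway spectrum, shorter dominant-hand
  peg removals, and rule-consistent surveys, with configurable
  nonadherence; ground truth lands in the manifest.
* **pipeline / CLI** — `neuropipe simulate | run | report`.

See `docs/methods.md` for the model details and every declared choice.

## Worked example

```bash
neuropipe simulate --out cohort --seed 5
neuropipe run --cohort cohort --out results >/dev/null
neuropipe report --run-dir results
```

prints

```
26 participants (17 cases / 9 controls); 90 features after availability filter
PLS-DA: 11 features with VIP >= 2 (of 15 with VIP >= 1)
LOO (6 components): R2 = 0.917, RMSEP = 0.137
```

Reading `results/report.json` for this run: median step length is 0.60 m
in cases vs 0.77 m in controls (Welch t = −5.78, p = 3.6 × 10⁻⁵) — cases
take shorter steps; the first two principal components carry 29.5% of the
feature variance; and the VIP ≥ 2 features are exactly the channels the
generator ties to severity — dominant-hand peg-removal distance and speed
summaries plus sway-axis spectral features (higher Shannon entropy and
median frequency in cases, i.e. a less predictable, broader sway
spectrum). `results/` also holds the wide/long feature matrices, the QC
log with per-walk exclusion reasons, the VIP table with attached t tests,
the LOO curve, and the per-group survey score table.

Because the feature matrix is filtered at ≥70% availability, cohorts with
slightly more sensor nonadherence can drop the whole gait-feature block
(for example 18/26 = 69.2% available); the QC log and the report's
accounting section make that visible, and step length — analysed
separately on the pedometer-permitted subset — is unaffected.

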