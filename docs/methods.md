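# Methods

`neuropipe` analyses smartphone-based functional assessments for detecting
chemotherapy-induced peripheral neuropathy (CIPN): a short walking task
recorded by the phone's inertial sensors and pedometer, a touchscreen
nine-hole-peg dexterity task, and the EORTC QLQ-CIPN20 / PRO-CTCAE
patient-reported instruments. This note documents the models, the tunable
parameters, the synthetic-cohort generator, and the numerical and design
choices where the method left genuine freedom.

## Patient-reported scales and case definitions

CIPN20 items are ordinal 1–4 (1 = not at all … 4 = very much); items 1–9
are sensory, 10–17 motor, 18–20 autonomic. Scale scores use the EORTC
linear transform

    score = (mean(present items) − 1) / 3 × 100

on the fixed subsets CIPN20 (1–20), CIPN8 (1–8), CIPN4 (1–4), CIPN2Feet
(1–2), CIPN2Hands (3–4), CIPNM (10–17), with the EORTC half-rule: a scale
is missing unless at least half of its items were answered. Participants
are **cases** when any of the first four items (feet/hands numbness and
tingling) is ≥ 3; feet- and hands-cases restrict the rule to items 1–2 and
3–4, so `is_case = is_feet_case ∨ is_hands_case` on complete responses.
Participants without a completed survey can carry a label from the cohort
manifest (a screening-interview analogue); a completed survey always takes
precedence.

## Gait processing

Per-sample user (gravity-removed) acceleration is rotated into the world
frame by the device-attitude quaternion, stored (w, x, y, z), mapping
device → world with world z up. Vertical acceleration is the world z
component. Between the two horizontal axes, the **heading** axis is the
one whose velocity — the cumulative trapezoidal integral of acceleration,
no drift correction — has the larger SD; the other is the **sway** axis.
An exact SD tie breaks to the first axis with a logged warning.

Quality control excludes a walk when (checked in this order):

1. duration < 3.50 s (*early termination*; 3.50 s exactly is retained);
2. the phone was held in the hand (*in_hand*, from the placement label);
3. the device-frame gravity direction, averaged over the first and last
   0.5 s windows, rotates by more than `qc.gravity_rotation_deg`
   (default 30°) — the phone moved inside the pocket or bag. The study
   protocol gives no numeric criterion for this; 30° is a heuristic,
   config-exposed and logged.

Forward and back walks are two replications; per-axis features are the
arithmetic mean over non-excluded replications (averaging rather than
concatenation was an open choice). Step length is pedometer distance /
step count, computed only under pedometer permission, missing on a zero
step count.

Per axis we compute time-domain summaries (mean, sample SD, skewness,
Pearson kurtosis, mean energy) and frequency-domain summaries of the
Welch power spectral density: linear detrend, Hann window, 50% overlap,
segment length min(256, n), band (0, 25] Hz. The PSD is normalised to a
probability distribution p over frequency bins, giving

* Shannon entropy −Σ pᵢ ln pᵢ (natural log; bounded by ln(#bins)),
* median frequency: the smallest bin with cumulative p ≥ 0.5
  (no interpolation, for determinism),
* dominant frequency: the bin of maximal power. The field sometimes
  reports a "maximum frequency"; the literal maximum represented frequency
  is always Nyquist and carries no information, so this package uses the
  dominant frequency, with a 95% spectral-edge alternative via
  `psd.max_freq_mode = "edge95"`,
* spectral skewness and kurtosis: third and fourth standardised moments
  of frequency under p (defined as 0 when all mass is in one bin).

A Hann-windowed pure tone necessarily leaks over ~3 bins, giving a
single-tone entropy floor near 0.87 nats; with a rectangular window and a
period-synchronous segment length the tone collapses to one bin and the
entropy approaches 0. Both behaviours are tested.

## Hand (nine-hole-peg) features

Touch traces are segmented into drags (down → move\* → up); in task order
drag 2k is the *place* and drag 2k+1 the *remove* of repetition k+1, up to
4 repetitions per hand. Per movement: distance = polyline path length in
screen points (no physical calibration — features are device-relative),
duration = t_last − t_first, speed = distance / duration. Per
(hand × phase) cell the five summaries (mean, median, min, max, sample SD)
of each quantity over available repetitions give the canonical 60-feature
set: 2 hands × 2 phases × 3 quantities × 5 summaries. The published
description lists means/medians/minimums/maximums and reports SD features
in its results; this 5-summary factorisation is the unique natural one
reaching exactly 60 and is declared, not inferred. Cells with one
repetition have missing SD; empty cells are all-missing.

## Multivariate statistics

Features available in ≥ 70% of participants are retained (the filter
boundary is inclusive); zero-variance columns are dropped with a log
entry (discretised frequency summaries can land in one bin for every
participant). Remaining missing cells are mean-imputed — 0 after
autoscaling (column mean 0, sample SD 1) — with per-cell imputation flags
kept; a complete-case alternative is configurable. PCA is the SVD of the
autoscaled matrix.

PLS-DA is orthogonal-scores NIPALS PLS1 on the centered 0/1 case
indicator: per component, w ∝ X'y (unit norm), t = Xw, p = X't/(t't),
q = y't/(t't), then X ← X − t p'. Scores are mutually orthogonal;
explained X-variance and explained Y-variance (the "between-group"
variance of a class indicator) are both reported because the phrase is
ambiguous. Variable importance in projection over A components is

    VIP_j = sqrt( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ),  SS_a = q_a² t_a't_a

and satisfies Σ VIP² = p. Features with VIP ≥ 2 or any |loading| ≥ 0.2 in
the first components (defaults: 2 components for importance) are flagged
important and annotated with Welch two-sample t tests (uncorrected
α = .05; pooled-variance optional). Predictive performance is
leave-one-out cross-validation at up to 6 components, re-centering and
re-scaling inside every fold (imputation is done once, before the loop):
RMSEP_k = √(PRESS_k/n), R²_k = 1 − PRESS_k/SS_tot, which can be negative
for models worse than the mean predictor. Everything here is
deterministic given its input.

The importance default of 2 components against 6 for validation reflects
the two roles the model plays: the first two components carry the group
separation that the importance thresholds interrogate, while the
validation curve is reported deeper to show where prediction saturates.

## Synthetic cohorts

The study cohort (n = 26; 17 cases, 9 controls) is not deposited, so the
generator emulates its statistical structure. One latent severity scalar
per participant — controls ~ U(0, 0.15), cases ~ U(0.85, 1) — drives every
channel, inducing the cross-channel correlation a PLS-DA exploits:

* **step length**: linear in severity between the group anchors 0.78 m
  (control) and 0.54 m (case) — the two magnitudes the study prints —
  plus N(0, 0.08 m) between-subject noise; pedometer distance is
  step_length × 7 steps per walk, so the extraction pathway returns the
  planted value exactly;
* **sway spectrum**: the sway-axis series is a mixture of a 0.9 Hz tone
  and ≤10 Hz band-limited noise with broadband weight 0.15 → 0.85 as
  severity goes 0 → 1, RMS-normalised to 0.4 m/s² so *only* spectral sway
  features carry signal and sway time-domain features are negative
  controls; heading/vertical axes are severity-independent step-frequency
  (1.8 Hz) harmonics;
* **peg task**: dominant-hand removal distances scale by
  1 − (1 − 0.70)·severity (ratio 0.70 at full severity, a free parameter
  chosen to give case-control separation of the order the study's
  P ≈ .001–.01 results imply at n = 26); placement and subordinate-hand
  cells differ only by noise;
* **surveys**: items noisy-monotone in severity with the classification
  rule guaranteed by construction (cases have a first-four item ≥ 3,
  controls are capped at 2).

Nonadherence defaults mirror the study's accounting: half the cohort
declines pedometer permission (12/26 granted in the study), 8% each of
in-hand, phone-moved and early-termination walks (the study excluded 7/26
accelerometer records), 8% missing surveys (2/26 in the study). The
manifest records all ground truth. Effects not printed in the study
(broadband weights, peg ratio, noise SDs) are free parameters with these
documented defaults; they were chosen once as field-realistic magnitudes,
and noise levels place default-cohort LOO R² in a broad 0.3–0.9 band
rather than at any particular published value, which is data-dependent
and not a valid calibration target.

What the generator does **not** emulate: biomechanically realistic gait
(harmonics, not body dynamics), device-specific sensor noise, turn
segments between the two walks, screen-geometry constraints on peg paths,
or item-level CIPN20 response styles. Passing tests therefore demonstrate
that the pipeline recovers planted structure of realistic magnitude under
realistic missingness — not clinical validity on real patients.

## Problem sizes and determinism

Analyses run at the study scale (n = 26, ~90 features); stochastic
recovery properties are assessed over 20 generator seeds, and one latent
draw per participant makes cohort generation byte-reproducible from the
config seed. `scripts/acceptance.py` seeds every random source from its
`--seed` argument.

## Known limitations

* The phone-moved criterion (gravity rotation between end windows) misses
  movement that returns the phone to its initial orientation.
* Mean imputation before (not inside) the LOO loop leaks a small amount
  of information through imputed cells; re-centering/re-scaling is
  fold-internal.
* The 60-feature factorisation and several spectral conventions (entropy
  log base, median-frequency convention, dominant-frequency reading of
  "maximum frequency") are declared choices where the method description
  is silent; all are config-exposed or documented above.
* Screen-point peg features are not comparable across device models.
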