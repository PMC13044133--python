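# Methods

`swayrisk` implements a subject-level fall-risk classification pipeline for
quiet-standing posturography: center-of-pressure (COP) signals are
decomposed by empirical mode decomposition (EMD), a 130-dimensional feature
vector is computed per trial, and five fixed-configuration classifiers are
validated with leave-one-subject-out cross-validation (LOSO-CV), trial-to-
subject probability aggregation, and bootstrap inference.  This note records
the model assumptions, the defaults and why they were chosen, and what the
synthetic cohorts do and do not establish.

## Study structure and labels

The reference design is 32 subjects with Parkinson's disease — 8 labelled
*fall risk* (Mini-BESTest balance score ≤ 21) and 24 *no fall risk*
(score > 21) — measured in four standing conditions (rigid/unstable surface
× eyes open/closed, coded `rs_eo`, `rs_ec`, `us_eo`, `us_ec`), three 30 s
trials per condition at 100 Hz, with anterior–posterior (AP) and
medio-lateral (ML) COP channels.  That yields 32 × 4 × 3 = 384 trial-level
samples.  The binary label is derived from the score; the score itself is
never used downstream.

## Synthetic cohort generator

Real COP recordings are replaced by a three-band filtered-noise model per
axis:

| band  | frequency (Hz) | role                              |
|-------|----------------|-----------------------------------|
| drift | ~0.01–0.3      | slow postural wander              |
| mid   | ~0.3–1.5       | primary sway oscillation          |
| high  | ~1.5–8         | fine-scale corrective activity    |

Each component is second-order-Butterworth band-passed Gaussian noise,
normalized to unit SD and scaled by a per-subject amplitude (lognormal
between-subject spread, σ = 0.25), a per-condition gain (`rs_eo` 1.0,
`rs_ec` 1.3, `us_eo` 1.8, `us_ec` 2.2 — sway grows when vision is removed
or the surface is compliant) and a per-trial lognormal jitter (σ = 0.15).
Baseline band SDs put AP sway at roughly three times ML sway, as in quiet
standing.  All energy sits below 10 Hz so the low-pass preprocessing is
near-transparent, and the three distinct spectral scales guarantee that EMD
finds five stable modes on essentially every 30 s record.

Group differences are injected only in the high band, with the signs the
subject-level comparison is expected to recover:

* **Amplitude**: at-risk subjects' high-band SD is multiplied by
  `hf_amp_ratio = 0.45` — more constrained fine-scale sway, hence lower
  IMF1 dispersion (STD/RMS/IQR/TotalPower) in the at-risk group.
* **Heavy tails**: the at-risk high band is modulated by a blockwise
  Gaussian scale mixture (0.25 s blocks, 10% of blocks amplified 3×,
  envelope normalized to unit mean square), producing positive excess
  kurtosis without changing the band variance.

Magnitudes are deliberately uncalibrated — no public per-condition COP
descriptives exist to calibrate against — so only effect *directions* are
contractual.  In practice the injected effect separates the groups more
cleanly than a real cohort would (held-out AUC near 1.0 at the defaults);
passing recovery tests therefore demonstrates that the pipeline detects a
present effect and stays at chance when none is injected, not that it
would attain any particular AUC on clinical data.  Mini-BESTest scores are
uniform draws within each group's range (10–21 / 22–28); only the label
matters.

Cohorts round-trip through two CSVs (long-format samples; subjects with
scores and labels), UTF-8, `.` decimal, COP in cm, time in s.  Reading
revalidates the score⇔label rule and per-cell trial counts.

## Preprocessing

COP from force-plate channels: `AP = 100·Mx/Fz`, `ML = −100·My/Fz` (cm),
with any non-positive vertical force rejected as degenerate loading.  The
plate-to-body axis mapping and sign convention are loader concerns; every
extracted feature except skewness is invariant to a global sign flip.
Smoothing uses a fourth-order Butterworth low-pass at 10 Hz applied
forward and backward (zero phase, magnitude response |H|²), with scipy's
odd-symmetric edge padding.  "Fourth-order, zero-phase" is read as *design
order 4, applied twice*; the alternative reading (order 2 per pass) is a
one-argument change.  No mean-centering is applied before decomposition:
the EMD residual absorbs the offset, and centering would double-handle the
drift.

## Empirical mode decomposition

Classic sifting EMD, implemented from scratch:

* **Extrema**: strict neighbor comparison; interior plateaus count once at
  their midpoint.  Fewer than two maxima or minima signals a monotone
  residual (a stop condition, not an error).
* **Envelopes**: cubic splines through the extrema with two extrema
  mirrored across each record end, the standard defense against end-swing
  contamination.
* **Sift stop**: Huang's Cauchy criterion SD = Σ(h_prev−h)²/Σh_prev² < 0.2
  *and* the mode condition (extrema and zero-crossing counts differing by
  at most one), capped at 100 iterations.  The Cauchy rule alone left
  visibly malformed first modes on broadband signals (dozens of riding
  waves); adding the count condition restored well-formed IMFs and, as a
  side effect, made five-mode extraction succeed on >99.5% of synthetic
  trials.
* **Depth**: five IMFs are extracted and required (the feature stage is
  defined on IMF1–IMF5); anything deeper stays in the residual.  Records
  that do not support five modes raise an explicit insufficient-modes
  error; the cohort-level feature table drops such trials (well under 1%
  at 30 s) with a logged warning, or propagates the error on request.

Reconstruction Σimfs + residual = input is exact by construction (float
error only) and asserted in tests; approximate orthogonality is reported
as a diagnostic index, not enforced.

## Features

Thirteen metrics × five IMFs × two axes = 130 named features,
`COP{ap|ml}_IMF{1..5}_{Metric}`.  Conventions that matter:

* STD uses N−1; RMS = √mean(x²); IQR uses linear-interpolation (type-7)
  quantiles — convention differences exceed float noise.
* TotalPower is the mean squared amplitude, Parseval-equivalent to the
  periodogram integral.
* CV = 100·STD/|mean| with a guard for the near-zero-mean IMFs: when
  |mean| ≤ 1e−12·RMS the denominator is floored and a degeneracy counter
  incremented.
* ApEn (self-matches included) and SampEn (excluded) use m = 2,
  r = 0.2·SD, Chebyshev distance — the field-standard defaults, exposed in
  `EntropyParams`.  SampEn with zero template matches returns the cap
  ln(B) + ln 10 instead of infinity.  Both share one numba pair-counting
  kernel; tests compare against a naive double-loop oracle.
* Skewness is the Fisher moment coefficient; kurtosis is *excess*
  (normal → 0).
* Bin-Entropy is −Σ p_i ln p_i over a 10-bin equal-width histogram spanning
  the series' own [min, max]; a constant series returns 0 with a flag.

Features are computed on raw (unstandardized) IMFs; z-scoring happens only
inside model training.

## Group statistics

Trial features are averaged per subject within a condition (the subject is
the observational unit), then each feature is compared between groups:
Shapiro–Wilk per group at α = 0.05 gates Welch's t-test (both groups
normal) versus a two-sided Mann–Whitney U (exact when sizes permit and no
ties, else tie-corrected normal approximation).  Per-group normality
testing is the defensible reading for a two-sample design.  No multiplicity
correction is applied, and the report says so.  At the study's 8/24 sizes
the screen's null flag rate is compatible with the nominal 5% (tested with
a t-interval over independent seeded cohorts, which stays valid despite the
strong correlation among the 13 metrics sharing an IMF series).

## Validation engine

* **LOSO-CV**: one fold per subject; all of a subject's trials are held
  out together, eliminating within-subject pseudo-replication.
  Standardization parameters (per-feature train mean/SD) come from the
  training fold only, and every fold records provenance that tests audit.
* **Models** (fixed, never tuned here): DT (depth 3), RF (100 trees,
  depth 3), XGB (50 trees, depth 2, η = 0.1, positive-class weight 3),
  LR (C = 5), linear SVM (C = 1.5, probability outputs); all class-weighted
  for the 1:3 imbalance and seeded (42).
* **Aggregation**: a subject's probability is the arithmetic mean of their
  trial probabilities.
* **AUC**: Mann–Whitney pair formulation, ties ½.
* **Operating point**: Youden's J maximized over midpoints of consecutive
  sorted unique probabilities; ties take the lowest threshold (favors
  sensitivity); p ≥ threshold ⇒ fall risk.
* **Bootstrap**: 1000 subject resamples; single-class replicates are
  redrawn (≤100 attempts) rather than scored; mean/SD and 95% percentile
  CI; sensitivity/specificity averaged at each replicate's own Youden
  threshold (a fixed-threshold variant would be a small change, but the
  per-replicate rule reflects that the threshold is itself estimated).
* **Model comparison**: paired subject resampling of the AUC difference
  against the RF baseline; two-sided sign-fraction p = 2·min(P(Δ≤0),
  P(Δ≥0)) clipped to [1/B, 1].  A model against itself gives p = 1.
* **Calibration**: subjects sorted by predicted probability and split into
  three near-equal rank bins (11/11/10 at n = 32) — equal-count binning
  keeps every bin populated at this sample size — plus the Brier score.
* **Condition screen**: full-feature LOSO with the baseline RF per
  condition and for all conditions pooled (pooling adds trials per subject
  before aggregation), each summarized by bootstrap AUC, sorted best
  first.

### SFFS

Sequential forward floating selection maximizes the subject-level AUC of a
base model under an inner LOSO over the available (training) subjects:
forward steps add the best-gaining feature, floating steps drop any earlier
pick whose removal strictly improves on the best objective seen at the
smaller size, stopping at gain < 1e−4 or 10 features, with deterministic
name-order tie-breaks.  Two usage modes reconcile leakage safety with
single-subset reporting:

* `nested` — SFFS re-run inside every outer fold on training subjects
  only; the reported subset is the modal subset across folds (ties to the
  lexicographically smallest).  This is the leakage-guarded mode the
  validation claims rest on.
* `descriptive` — one SFFS pass over all subjects, mirroring the style of
  a single reported feature triple; labelled descriptive because it sees
  every subject.

Nested SFFS over all 130 features is combinatorially expensive (outer
folds × steps × candidates × inner folds model fits ≈ 10⁶ RF fits at
n = 32), so the end-to-end acceptance run selects features with the
descriptive mode over a candidate pool pre-screened to the 20 smallest
univariate p-values; the nested mode is exercised on smaller candidate
pools in the test suite.

## Problem sizes used by the test suite and acceptance run

The acceptance script runs the full default cohort (384 trials, 130
features, ≈4 minutes end to end).  Seeded test banks use: 20 default-effect
`rs_ec` cohorts (cheap non-entropy metrics) for effect-direction and
classifier-recovery checks; 20 null-effect cohorts at the study's 8/24
sizes (all 130 features) for screen calibration; 20 null cohorts with cheap
metrics for the chance-level check; 50 seeded probability-level instances
for bootstrap coverage and power.  SFFS recovery uses an 18-subject toy
(3 informative + 7 noise features, 1.5 SD subject-level effect) with the LR
model spec as the wrapper objective — chosen for runtime, with a
single-seed RF-objective check retained — and the exhaustive two-subset
oracle uses a 6-feature toy.

## Known limitations

* The generator reproduces structure and effect directions, not COP
  physiology: no postural feedback dynamics, no medication state, age, or
  disease-stage covariates, and no per-condition spectral reshaping beyond
  a gain.  Absolute AUC/Brier values on synthetic cohorts say nothing
  about clinical performance.
* LOSO with an 8/24 imbalance is pessimistically biased under the null
  (training prevalence anti-correlates with the held-out label), so
  null-cohort AUCs center near 0.42 rather than 0.50; tests account for
  this.
* EMD has no uniqueness guarantee; different sift/boundary policies give
  numerically different IMFs, so feature values are comparable only within
  one implementation.
* Exact reproduction of any published cohort's numbers requires that
  cohort's force-plate recordings; a loader for such data only needs to
  emit the cohort CSV contract (`cop_from_forces` plus the documented axis
  conventions cover the kinetics-to-COP step).
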