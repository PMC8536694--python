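# Methods

This note documents the models, conventions and design choices behind
`enosedx`: what the simulator emulates, how each pipeline stage is defined,
which parameters matter, and what the tests do and do not demonstrate.

## 1. Signal model

A recording is the resistance of `n_sensors` (default 6) hot MOS gas
sensors sampled at 1 Hz over three contiguous phases: baseline reference
air (default 300 s), exposure to the urine headspace (3000 s), and recovery
under odourless air (1800 s). Phase windows are half-open, 0-based index
intervals; the time column is authoritative and the nominal rate is
validated against it (relative tolerance 1e-6).

The simulator generates

    R_s(t) = R0_s * d * (1 - a_s * g(t)) * (1 + eps_s(t))

- `g(t)` is a first-order exponential on/off response: 0 on the baseline,
  `1 - exp(-(t - t_on)/tau_on)` during exposure, and exponential recovery
  with `tau_off` afterwards, continuous at the phase boundary. The time
  constants default to `tau_on = tau_off = 120 s`: the response reaches
  steady state within a few minutes, and no published functional form
  constrains the shape further, so the simplest adsorption kinetics is
  used.
- `d` is a per-day log-normal baseline multiplier (`day_scale_sd`, default
  0.2). A multiplicative whole-curve distortion is exactly the family of
  artefacts SNV removes, which is why between-day shift is modelled this
  way.
- `eps` is iid Gaussian relative measurement noise (`noise_sd`, default
  0.01): MOS resistance noise scales with the signal.

The fractional response amplitude of sensor `s` factorises as

    a_s = amplitude_control[s]
          * class_effect[s]              (PCa samples only)
          * temperature_factor[T]
          * portion_factor[portion]
          * subject_multiplier           (log-normal, shared by all sensors)
          + jitter_s                     (additive N(0, amplitude_jitter_sd))

and must stay in (0, 1); a deterministic amplitude at or above 1 is an
error (the resistance would cross zero), while the random jitter is clipped
into (0, 1) with a warning.

### Why the additive jitter term exists

All the multiplicative ingredients cancel out of scale-free statistics:
if every source of within-class variation scaled with the enrichment
factors, classification performance would be mathematically independent of
conditioning temperature and urination portion, which contradicts the
protocol effects the pipeline is supposed to exhibit. The additive jitter
models background volatiles and chamber variability whose contribution does
*not* grow with headspace enrichment. It is the noise floor that makes
weakly enriched headspaces (low temperature, final portion) genuinely
harder to classify, and its default (0.04 amplitude units) was calibrated
once so that the default cohort lands in the reported diagnostic
performance band (see §6).

### Default study conditions

- Cohort: 110 PCa / 54 control subjects (the modelling dataset size), one
  recording per subject, analysis days drawn from a pool of 20 with
  per-day multipliers shared across subjects measured on the same day.
- Sensitivities `amplitude_control = (0.30, 0.22, 0.26, 0.20, 0.24, 0.18)`
  at the reference condition (60 °C, first portion).
- `class_effect = (1.40, 1, 1, 1.20, 1, 1)`: the disease raises the
  response on two sensors, with sensor 1 dominant — mirroring an array in
  which one zinc-oxide element carries most of the discriminative signal.
- `temperature_factor = {23: 0.12, 37: 0.30, 50: 0.60, 60: 1.00}`
  (strictly increasing): headspace enrichment grows with conditioning
  temperature.
- `portion_factor = {first: 1.00, midstream: 0.85, final: 0.25,
  catheter: 0.95}`: prostatic metabolites are most concentrated in the
  first portion of urination and largely washed out by the final portion;
  a catheter sample mixes portions and sits near the first.
- `subject_sd = 0.05`, `repeats_per_subject = 1`, seed-driven throughout:
  every random draw is a deterministic function of `(seed, sample_id)`, so
  recordings are reproducible individually and cohorts bit-identical under
  a fixed seed.

### What the simulator does not model

No gas-diffusion or surface-chemistry physics, no humidity or temperature
cross-sensitivity, no long-term sensor drift, no instrument-to-instrument
transfer. Passing tests therefore demonstrate that the *analysis pipeline*
behaves correctly under the assumed statistical structure — not that the
assumed structure captures everything in real clinical recordings.

## 2. SNV preprocessing

SNV standardizes each sensor curve independently over the whole recording
(baseline + exposure + recovery): subtract the curve mean, divide by its
standard deviation. Conventions fixed for reproducibility:

- sample standard deviation (n−1 denominator);
- whole-curve normalization, not per phase (the curve is the unit the
  correction applies to);
- constant curves (sd = 0) are rejected as dead sensors.

SNV output is invariant to positive affine maps of the raw curve, hence
removes the simulator's day multiplier exactly; it is idempotent up to
floating tolerance; and the stored per-sensor (mean, sd) reconstruct the
raw curve exactly.

The baseline reference `R_0` is the median of the baseline window (robust
to noise), and the response intensity of a sensor is `R_0 / R_min` with
`R_min` the exposure-window minimum — ≥ 1 for a responding MOS sensor.

## 3. Feature extraction

Eight descriptor families per sensor (A–H, see `features.py`); under the
default grids each sensor yields 5+5+3+1+4+4+2+1 = 25 descriptors, i.e.
150 per recording. Conventions that were genuinely open and are now fixed:

- **Timepoints.** Offsets in seconds into the owning phase window; the
  value at a timepoint is the median over ±15 s (configurable), for noise
  robustness. An offset equal to the phase duration refers to the last
  sample. Default grids: A/B at 600…3000 s of exposure, C at 600/1200/1800 s
  of recovery, four derivative-ratio triples, four local-difference pairs,
  α ∈ {0.1, 0.5} for the smoothed-difference filter. The grids were chosen
  to total exactly 25 descriptors per sensor; all are configurable.
- **Raw vs SNV curve.** With `use_snv=True` (default) families A–G are
  computed on the SNV curve; H is always the raw-curve ratio `R_0/R_min`.
  As a ratio H is invariant to the multiplicative baseline scale anyway,
  while carrying the absolute response amplitude that SNV deliberately
  discards. Computing D (`R_min`) on the SNV curve keeps the entire default
  feature vector invariant to the day multiplier; users who want the
  absolute resistance minimum set `use_snv=False`.
- **Family G.** `y[k] = (1−α)y[k−1] + α(x[k]−x[k−1])`, `y[0] = 0`, over
  baseline + exposure; the scalar reported is `min_k y[k]` (the steepest
  smoothed descent; resistance falls on exposure).
- **Degenerate denominators.** |R(t2)−R(t1)| < 1e-12 in family E yields
  0.0 with a logged warning rather than NaN, keeping the matrix finite for
  the selector.

Every family is verified against an independent brute-force evaluation on
hand-written ≤10-point series (1e-10), and G against its unrolled
closed-form sum.

## 4. Shadow-feature selection

A from-scratch all-relevant selector in the Boruta family. Per iteration:
one freshly permuted shadow copy of every surviving feature is appended,
a random forest is fitted, and a feature scores a hit when its importance
exceeds the maximum shadow importance. One-sided binomial tests of the hit
count against Binomial(n, 1/2), Bonferroni-corrected across currently
undecided features, confirm (upper tail) or reject (lower tail) at
`p_threshold = 0.01`; rejected features and their shadows are dropped;
iteration stops when nothing is tentative or after `max_iter = 100`.
Features still tentative at termination are excluded from the final model
(conservative). Shadow permutations are seeded per feature name, so
decisions are invariant to column order up to the forest's own
tie-breaking.

Two numerical choices matter and were made deliberately:

- **Importance = Z-score of per-tree impurity importance** (mean over
  trees divided by its tree-to-tree sd; default, with raw MDI and
  permutation importance as options). Raw mean-decrease-in-impurity is
  nearly deterministic across iterations, so a feature whose *chance*
  correlation with the labels happens to sit at the top of the null
  distribution of the fixed finite sample beats the fresh shadow maximum
  persistently and ends up confirmed. Standardizing by the per-tree spread
  penalizes such sporadically useful features: under permuted labels their
  hit rates drop below 0.4 while genuinely informative features stay at
  1.0.
- **Constant shadow-pool size.** The shadow pool is padded back to its
  initial size with extra fresh permutations of surviving features. If the
  pool shrank with the rejections, the max-shadow bar would weaken over
  iterations (a maximum over a handful of shadows instead of 150) and
  borderline features would be confirmed by attrition rather than merit.

The forest inside the selector uses 100 trees and `sqrt(p)` candidate
features per split.

## 5. Classification and evaluation

- Random forest, 500 trees, `sqrt(p)` features per split, no class
  weighting; stratified 10-fold cross-validation with a fixed seed; the
  out-of-fold predictions are pooled into a single confusion matrix whose
  cells sum to the cohort size. Feature selection runs once on the full
  matrix before cross-validation (the standard design for this analysis
  type; the selection optimism this can introduce is a known caveat).
- Metrics: accuracy (tp+tn)/total, sensitivity tp/(tp+fn), specificity
  tn/(tn+fp), each with an exact Clopper–Pearson 95% CI (beta-quantile
  form). A metric with a zero denominator is reported as undefined, never
  as 0. CI coverage is verified by simulation at the study's denominators
  (n = 54 and 110). Note the reference 2×2 matrix (S-row 47, 20; PCa-row
  7, 90) gives accuracy exactly 137/164 = 83.5% (rounds to 84%); the
  sometimes-quoted 83% is a rounding/reporting inconsistency, so the
  package reports exact values and flags the discrepancy here instead of
  matching 83% by construction.
- PCA scores: columns centred and standardized (descriptor families live
  on heterogeneous scales), full-SVD solver, component signs fixed by
  making the largest-magnitude loading positive.
- Repeatability index: mean within-subject pairwise Euclidean distance
  divided by mean between-subject distance in the leading-2-PC space;
  values well below 1 indicate subject-level clustering of repeats,
  ~1 indicates none.

### Protocol comparisons

- **Conditioning temperature.** One cohort per temperature is simulated
  and pushed through the full pipeline independently
  (`compare_conditions`); with the default monotone temperature factors,
  60 °C cohorts outperform 50 °C cohorts in sensitivity.
- **Urination portion.** `portion_sensitivity` mirrors the
  protocol-investigation design: the diagnosis model is trained on a
  standard first-portion cohort, and PCa samples collected at each portion
  (from a held-out set of subjects) are classified against it; sensitivity
  per portion is the fraction classified PCa. This design is what produces
  the characteristic collapse for the final portion — a within-portion
  re-trained model would largely re-normalize the amplitude scale away.

## 6. Calibration and problem sizes

Effect sizes are not published as numbers anywhere; they are free
parameters of the simulator. They were calibrated once, during
development, so that the default 110/54 cohort at 60 °C lands in the
reported diagnostic performance band (sensitivity/specificity in the
high-70s to mid-90s), and were not revisited afterwards. The test suite
runs the full pipeline at the study's actual size (164 samples, 150
features, 10 folds, 5 seeds); the selector's ground-truth checks use
n = 200 with a 10 informative / 140 noise split; repeatability checks use
20 subjects × 3 repeats.

## 7. Known limitations

- The number of confirmed features on real data is data-dependent; the
  selector's output size on synthetic cohorts (typically 5–12) is not a
  reproduction target.
- Default-cohort performance sits at the upper end of the reported band:
  with only published summary statistics to constrain an entire covariance
  structure, the simulator is necessarily a simplification, and its class
  signal is somewhat cleaner than clinical reality.
- Single-pass 10-fold CV (no repetition/averaging), majority-vote RF
  classification only (no ROC thresholding), no drift correction, no
  cross-instrument model transfer.
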