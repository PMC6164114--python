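# Methods

`breathdx` implements the analysis chain of an electronic-nose (e-nose)
breath test for case/control discrimination: a 32-channel conducting-polymer
chemiresistive array sniffs a bagged alveolar-air sample, each channel's
fractional resistance change is the feature, and linear/kernel classifiers
are evaluated under a nested validation design. Because raw instrument data
of this kind are rarely public, the package pairs the analysis chain with a
generative simulator so every stage is testable against known ground truth.

## Sensor sweep model

One measurement ("sweep") has three phases: a baseline purge (default 10 s)
of clean air, a sample purge (40 s) during which the polymers swell in the
analyte and resistance rises, and a washout (10 s). The simulator uses
first-order kinetics — the simplest dynamics consistent with sensors that
visibly reach steady state within the purge:

    R_k(t) = B_k d(t)                                    baseline purge
    R_k(t) = B_k d(t) [1 + a_k (1 - e^{-(t-t0)/tau})]    sample purge
    R_k(t) = B_k d(t) [1 + a_k* e^{-(t-t1)/tau}]         washout

with `B_k` the per-channel baseline resistance, `a_k` the programmed
fractional response, `tau` = `tau_rise` (default 4 s; the washout reuses the
same constant, leaving a residual of `a e^{-2.5} ≈ 0.08 a` at sweep end —
about 0.4% of baseline at default response levels, safely inside the 1%
drift tolerance), and `d(t) = 1 + drift_magnitude * t` a linear
multiplicative baseline ramp applied to replicates that drift (probability
`drift_prob` each), `d ≡ 1` otherwise. Replicate 1 of every subject carries
an additive response bias (`first_replicate_bias`, default +0.01),
emulating residual air in the connecting tubing.

The response hierarchy is Gaussian: subject truth
`a_jk = mu_k + delta_k·1[case] + u_jk`, `u ~ N(0, sigma_subject²)`
(optionally a full covariance matrix for harder recovery tests), and
replicate realization `a_jkr = a_jk + e_jkr`, `e ~ N(0, sigma_replicate²)`.
Noise enters through the response amplitude, not per time point; the trace
itself is smooth.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| `mu_control` | 0.05 | a ~5% ΔR/R0 is a typical conducting-polymer response to breath VOCs |
| `delta_mu` | ±0.004 alternating across channels | a disease signature is a *pattern* change across polymers; a uniform scale shift would lie exactly in the null space of sample-vector normalization and be unlearnable by construction |
| `sigma_subject` | 0.01 | biological between-subject spread, ~20% of the mean response |
| `sigma_replicate` | 1e-4 | puts the within-subject CV near 0.2%, the middle of the 0.08–0.32% band reported for well-maintained instruments of this class |
| `drift_prob`, `drift_magnitude` | 0.05, 0.002/s | occasional drifting replicates whose terminal baseline misses by ~10%, clearly detectable at the 1% tolerance |
| `tau_rise` | 4 s | 40 s purge = 10 time constants: saturation to 1 − e⁻¹⁰ |
| `sample_rate` | 5 Hz | ≥ 50 points per phase with small files; heavy simulations in tests/scripts use 0.5 Hz (still ≥ 5 points per phase), which changes nothing downstream because features depend on phase means/maxima |

The simulator emulates cohort structure, replicate protocol, contamination,
and drift. It does **not** emulate polymer-swelling physics,
humidity–resistance coupling, sensor cross-correlation (unless a covariance
is supplied), instrument export formats, or spectrum-bias effects of control
selection — so green tests certify the arithmetic and the validation
machinery, not field performance of any instrument.

## Feature extraction and replicate QC

Per channel, `ΔR/R0 = (Rmax − R0)/R0`. `R0` is the mean over the final 50%
of the baseline purge (avoids purge-onset transients; the window is a
constant, not a knob), `Rmax` the maximum within the sample purge. The
feature is scale-invariant: multiplying a whole trace by c > 0 changes
nothing.

Quality control operationalizes visual screening: replicate 1 is always
deleted; a replicate is deleted as *drifted* when any channel's terminal
washout baseline (mean of the washout's last 10%) misses the initial
baseline by more than 1% relative (`drift_tolerance`, configurable).
Retained replicates are averaged channel-wise; a subject with fewer than 2
retained replicates is rejected with the causes listed. Averaging is done
on raw ΔR/R0 before any normalization; normalizing each replicate before
averaging is the other defensible order and can be emulated by normalizing
replicate features manually before aggregation.

## Scaling

Preprocessing order is fixed: per-sample vector normalization (each row
scaled to sum of squares c = 1 — any constant is equivalent after the next
step), then per-sensor autoscaling `x' = (x − x̄_k)/s_k` with
(n−1)-denominator SDs. The autoscaler is a fitted state (means, SDs, n_fit)
serializable to JSON; by default it is fitted on the calibration training
subjects only and applied unchanged to internal and external sets. The
`paper_faithful_scaling` switch instead fits on all subjects jointly —
whole-database scaling as sometimes described in applied reports — and
exists only to quantify that leakage; it is never the default.

## Repeatability

Per sensor, repeatability across the 10 bag measurements is summarized two
ways:

- **ICC(3,k)** — two-way fixed (consistency) average-measures intraclass
  correlation, `(MS_subjects − MS_error)/MS_subjects` from the two-way ANOVA
  decomposition. Each measurement j ∈ {3..10} is compared pairwise against
  measurement 2 (the reference, measurement 1 being deleted), and the
  per-sensor summary is the *minimum* over pairs — the conservative reading
  of "each measurement vs the 2nd". A joint mode (one ICC over all retained
  columns) is available but not default. For a k = 2 pair the population
  value is the Spearman–Brown step-up 2ρ/(1+ρ) of the single-measure
  reliability ρ = σ²_subj/(σ²_subj + σ²_rep). Zero between-subject variance
  makes the coefficient undefined; it is reported as NaN, never clamped.
- **CV%** — within-subject sample SD across retained replicates divided by
  the within-subject mean, ×100, averaged over subjects (the standard
  repeatability CV). Sensors with a zero mean for any subject are reported
  NaN.

## Validation design

Nested ("repeated double") cross-validation: the calibration cohort is
split by seeded permutation into 80% training / 20% internal validation
(unstratified by default, mirroring study practice where internal-set
compositions differ between runs; a stratified mode preserves class ratios
within one subject). The external cohort is disjoint by hard contract —
overlapping IDs raise — and is scored exactly once per repeat with the
calibration-fitted scaler and model. A split that leaves a class out of
training is rejected and deterministically reseeded with seed+1, with the
event logged and the effective seed recorded in the plan.

Learners: LDA (scikit-learn; Ledoit–Wolf shrinkage of the pooled covariance
whenever n_train < 2·p, keeping 32-feature fits well-posed at study-scale
n), and an RBF SVM whose cost ∈ {0.1, 1, 10, 100} and kernel width
(median-heuristic γ scaled by {0.5, 1, 2}) are chosen by inner stratified
CV maximizing accuracy. Classification thresholds are fixed a priori:
signed decision score 0, i.e. the equal-prior boundary for LDA. Default
`n_repeats` = 1 (one seeded split, the shape of a published table);
repeated mode averages per-metric over seeds.

Diagnostic reports carry the seven table metrics (FP rate ≡ 1 −
specificity, FN rate ≡ 1 − sensitivity, all as percentages, displayed
half-up to one decimal, stored unrounded), plus the Mann–Whitney AUC with
ties half-counted and a DeLong 95% CI (normal approximation on DeLong's
structural-components variance, truncated to [0, 1]); the DeLong code is
validated against R's pROC on frozen fixtures.

A PCA projection (column-centered SVD, component signs fixed by the
largest-loading-positive convention) is provided for the customary
two-component discrimination plot.

## Confusion-matrix reconstruction

Published tables print rounded percentages; `reconstruct_confusion` inverts
them: an exhaustive search over non-negative integer (tp, fn, fp, tn)
consistent with the supplied cohort sizes keeps every matrix whose metrics
round (half-up, one decimal — the convention that reproduces all
reproducible entries of the motivating table) to every supplied value. With
no size constraint the search is unbounded and refused. An empty solution
set is a *proof* of inconsistency among the printed values; the result then
reports every maximal consistent subset of the metrics and the matrices it
admits, so the erratum can be localized (e.g. a printed false-positive rate
of 12.4% where every candidate matrix gives 11.4%).

## Sample size

For a test expected to classify C% of subjects correctly, the binomial
standard error of the observed accuracy is SE = √(C(100 − C)/n); the
required n for a target SE is the ceiling of C(100 − C)/SE². At C = 80 and
SE = 3 this gives n = 178.

## Numerical and testing choices

- All randomness flows through `numpy.random.default_rng` seeds carried in
  configs; the demo pipeline is byte-deterministic (validation.json hashes
  equal across reruns) and stamps every artifact with the seed and a config
  hash.
- The synthetic recovery checks run at 400 calibration + 100 external
  subjects, 0.5 Hz sweeps: the programmed Mahalanobis separation Δ = 2
  (accounting for the σ²_rep/9 averaging term) predicts an optimal-score
  external AUC of Φ(Δ/√2) ≈ 0.921, and the measured LDA external AUC is
  required to fall within 3 Hanley–McNeil SEs of it. These checks bypass
  row normalization (the closed form is for raw equal-covariance Gaussian
  features).
- The chance-level guard re-permutes all labels per repeat and averages
  external accuracy over 20 LDA repeats; a single 100-subject permutation
  has a ~5-point SD, so averaging is what makes the [45%, 55%] window a
  meaningful leakage alarm rather than a coin flip.
- Known limitations: no detrending or drift *correction* (drifted data are
  deleted, not repaired); no absolute-agreement ICC(2,k); no alternative
  scalings (range/Pareto); no feature selection or calibration curves; CV
  and ICC assume a rectangular replicate table, so subjects missing a
  requested replicate (e.g. flagged drift) are dropped from the
  repeatability summary rather than imputed.
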