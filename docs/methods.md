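# Methods

This note records the models, parameter choices and numerical conventions
behind `vitalrisk`, and what the synthetic data does and does not establish.

## Problem setting

The unit of inference is a transport episode: one critically ill child moved
between hospitals by a specialist retrieval team, continuously monitored on
seven channels (HR, SBP, DBP, MBP, RR, SpO₂, core temperature), with a
static EHR record (demographics, diagnosis group, interventions, a PIM3
mortality risk scored at first team contact, critical-incident label,
transport time) and a binary 30-day mortality outcome. The pipeline
estimates, every 10 minutes, the probability that the child dies within 30
days of PICU admission, and attributes each estimate to its input features.

## Preprocessing

**Cleaning.** Closed plausibility intervals per channel (HR [0, 300] bpm,
SBP [0, 270], DBP [0, 250], MBP [0, 250] mmHg, RR [0, 180] /min,
SpO₂ [0, 100] %, temperature [20, 45] °C). Out-of-range values become
missing rather than being clipped: clipping would fabricate physiology at
exactly the extremes that carry risk signal. Cleaning is idempotent.

**Imputation.** Per channel and episode: linear interpolation in time at
interior gaps, nearest-value fill at the leading/trailing edges. This is
order-preserving, deterministic, and uses no information from other
channels or patients, so it cannot leak outcome information. A channel with
zero observed values in an episode is excluded (logged); a patient with no
usable channel contributes no samples. The pipeline order is fixed
clean → impute → standardise; because standardisation is affine, imputing
before or after standardising yields identical Z-streams, so the ordering
choice is inconsequential and we fix the simpler one.

**Standardisation.** z = (x − μ)/σ with (μ, σ) looked up per
(age band, channel). Age bands: newborn ≤ 1 m, infant ≤ 12 m, pre-school
≤ 4 y, school ≤ 11 y, adolescent ≤ 18 y. The reference table shipped in
`config.DEFAULT_REFERENCE_RANGES` contains plausible paediatric norms and
is deliberately an editable config input (YAML round-trip provided): sites
should substitute their own normative values. The transform is exactly
invertible, which the tests exercise to 1e-9.

## Featurisation

Windows are half-open `[start, start + w)` on the resampled grid, 10 minutes
long by default. Deceased-patient streams are windowed with an overlapping
stride of 50 grid points; survivor streams with consecutive disjoint
windows. Window counts are therefore `floor((L − w)/s) + 1` and
`floor(L/w)` for grid length L. The stride is counted in grid points, so
its wall-clock meaning scales with the sampling interval (a config field;
default 1 s, at which the two classes contribute comparable sample counts
at 6% mortality — see the generator section).

The 13 per-channel statistics: mean, median, SD (population), min, max,
range, IQR, skewness, excess kurtosis, Shannon entropy (nats) of Z-values
binned into 16 equal-width bins over [−5, 5], sample entropy
SampEn(m = 2, r = 0.2·SD), total periodogram power, and the least-squares
slope per second. Conventions for degenerate windows: on an exactly
constant window (detected as min == max, immune to floating-point
round-off in the variance) SD, range, IQR, entropy terms, power, slope,
skewness and kurtosis are all 0. Total periodogram power is computed from
the DFT of the mean-removed window as Σ|X_f|²/n², which equals the
population variance by Parseval's identity — the tests assert agreement to
1e-9. Sample entropy uses a compiled O(n²) template-count kernel; the test
oracle is an independent brute-force pair enumeration.

Static block (21 features, fixed codebook): age in months, age-band
ordinal, weight, male indicator, 7 diagnosis-group one-hots, invasive
ventilation, single/multiple vasoactive-infusion indicators, inhaled NO,
ECMO, PIM3 risk, 3 critical-incident one-hots (none/patient/equipment),
transport minutes. With 7 × 13 derived statistics the feature vector has
112 entries in a fixed, documented order that doubles as the model's
feature contract.

## Modelling

Patients are split 90/10 into train/holdout, stratified by outcome
(each class contributes `round(class · 0.1)`, at least 1, to the holdout),
so the ~6% death rate is preserved on both sides. Hyperparameters are
chosen by seeded random search over documented per-backend spaces, scored
by mean fold AUROC over 5 cross-validation folds that are **grouped by
patient** (stratified at the sample level): no patient's windows ever span
a fold boundary, the conservative extension of train/test patient
disjointness. A single-candidate search (`n_search=1`) skips fold scoring
and fits directly, which is equivalent by construction. The winning
configuration is refit on all training samples.

Patient-level risk is the arithmetic mean of the patient's window-sample
probabilities, so it always lies within the min/max of those
probabilities. Stacking (random forest + gradient-boosted + logistic bases
with a logistic meta-model) fits the combiner on out-of-fold base
predictions from patient-grouped folds, never on in-sample fits.

A convolutional or recurrent sequence model is not included: the backend
interface (`predict_proba` over the feature contract) admits one without
touching the pipeline, but the tabular backends are the deliberate scope.

## Evaluation

AUROC is the Mann–Whitney rank statistic with ties counted half; average
precision is the step-wise area under the precision–recall curve; MCC,
PPV, NPV, recall and F1 come from the thresholded confusion matrix, with
any degenerate denominator reported as 0 and flagged rather than raised.
The decision threshold defaults to the Youden's J maximiser computed on
**out-of-fold** training-patient fused risks (patient-grouped folds, the
backend refit per fold with its chosen hyperparameters). In-sample risks of
a flexible model are nearly separated and would place the threshold far
above anything a held-out patient reaches; out-of-fold risks estimate the
scale the holdout actually sees, and the holdout never chooses its own
threshold. The report records the threshold used. Confidence intervals
are 95% percentile bootstrap over patient-level resamples — the patient,
not the window, is the unit of inference — with single-class resamples
redrawn (logged). The PIM3 comparison evaluates both score vectors on the
identical patient set and exports a per-patient scatter table.

## Explanation

Shapley values are computed in probability space (the dashboard contract
plots risk-scale contributions) against a background of 100 seeded training
samples. Exact mode enumerates all 2^d coalitions, valuing a coalition S as
the mean prediction with features in S from the instance and the rest from
each background row; it is capped at d = 12 features and satisfies local
accuracy (base + Σφ = prediction) to 1e-9. Sampled mode walks seeded
random permutations (one background row per permutation) and batches the
d + 1 predictions of each walk; its telescoping construction satisfies
local accuracy exactly with respect to the sampled background rows, and
per-feature Monte-Carlo standard errors are reported. Risk traces use
**common random numbers** across windows — the same permutations and
background draws for every window — so identical windows receive identical
attributions and window-to-window contribution changes are purely
data-driven, not estimator noise.

A transition event is a window at which a feature's contribution moves from
≤ 0 to > 0 — the strict sign flip from favouring survival to favouring
death. The default has no hysteresis; a configurable dead-zone suppresses
chatter around zero when wanted.

## Synthetic cohort generator

The generator is first-class, tested code that emulates the statistical
structure of a regional paediatric transport population:

- 30-day mortality: exactly `round(n · rate)` deceased (default rate 0.06);
  deterministic rather than binomial so small-cohort tests are exact.
  P(death within 48 h | death within 30 d) = 0.27.
- Demographics: age-band frequencies 37.9 / 20.5 / 17.6 / 14.5 / 9.5 %
  (newborn→adolescent), uniform age within band, weight from a
  piecewise-linear weight-for-age curve with 15% log-normal spread;
  diagnosis-group, ventilation (72.4%), vasoactive (31.4%), inhaled-NO
  (2.5%), ECMO (2%) and critical-incident (14.9%) frequencies as observed
  in such cohorts.
- Monitoring duration: log-normal, median 67 min, σ = 0.68
  (IQR ≈ 41–104 min, ≈ 1.1 median monitored hours); transport time
  log-normal with median 206 min.
- Trajectories: per channel, an Ornstein–Uhlenbeck (AR(1)) process in
  Z-space, relaxation time τ = 300 s, stationary SD 0.6, plus a
  patient-level offset (SD 0.5). Non-survivors additionally drift linearly
  from 0 to the configured deterioration effect over the episode (defaults
  SpO₂ −1.5 Z, SBP −1.0 Z). Raw values are mapped through the age-band
  reference and clipped into the plausibility bounds, so all pre-artifact
  values are physically plausible; survivor streams are stationary,
  non-survivor streams deteriorate progressively.
- Artifacts: per-point independent missingness with channel-specific rates
  (HR 2.85%, SBP 9.25%, DBP 9.30%, MBP 8.76%, RR 3.11%, SpO₂ 2.87%,
  TEMP 12.5%) and out-of-range spikes with probability 0.005.
- PIM3: outcome-conditioned Beta draws — survivors Beta(2.2, 62) (median
  3.0%, IQR 1.8–4.6%), non-survivors Beta(1.1, 11) — calibrated once, by
  Monte-Carlo before any model was trained, so that PIM3 alone
  discriminates moderately (asymptotic patient-level AUROC ≈ 0.74).
- Sampling interval: 1 s by default. The raw monitor frequency is a genuine
  unknown in transport practice, so it is a config field; 1 s is the value
  at which a 50-point minority stride yields deceased/survivor sample
  counts within a factor of two of each other at 6% mortality, which is the
  balance the windowing scheme is designed to produce.
- Reproducibility: the entire cohort is a pure function of the config and
  seed, byte-identical across runs; artifact noise is seeded per
  (seed, patient, channel) so `inject_artifacts` is order-independent.

**What the generator does not emulate:** referral-hospital stabilisation
phases, bursty telemetry dropouts (missingness is i.i.d. per point),
cross-channel physiological coupling (channels are conditionally
independent given outcome and age), intervention effects on trajectories,
repeat transports, or any real normative reference table. Consequently, a
passing signal-recovery experiment shows that the pipeline recovers a
planted deterioration signal under realistic noise, imbalance and
missingness — not that the model reaches any particular performance on
real transport data.

## Experiment sizes and numerical choices

The signal-recovery experiment uses 5 independent replicates, each a fresh
600-patient cohort with a fresh 90/10 split and random-forest fit (300
trees, min leaf 2, √p features), reporting medians across replicates.
Replicating the whole experiment — rather than refitting one cohort —
matters because a 60-patient holdout contains only ~4 deaths, so
single-cohort PIM3 AUROCs are dominated by the luck of 36 Beta draws;
medians over independent replicates estimate the design's behaviour, not
one cohort's. Bootstrap calibration uses a binormal score generator with
known true AUROC Φ(μ/√2), 200 trials at n = 300 with 60 events. Exact
Shapley tests use ≤ 8 features and small backgrounds; sampled-estimator
convergence is checked by quadrupling the permutation count twice and
comparing median maximum errors. Oracle agreement tolerances: 1e-12 for
rank-vs-pairwise AUROC and MCC-vs-Pearson, 1e-9 for Parseval and Shapley
local accuracy.

## Known limitations

- The 13-statistic set and 21-variable codebook are fixed, documented
  choices; other reasonable encodings exist and would change feature
  indices (the contract is versioned through the model bundle).
- No probability calibration (Platt/isotonic) is applied; fused risks are
  discrimination-oriented.
- The threshold-dependent metrics inherit the instability of small
  holdouts (~4 events); the bootstrap intervals make that visible rather
  than hiding it.
- Attributions explain the model, not physiology: a feature driving
  predicted risk is a correlate, not a cause.
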