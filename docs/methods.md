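# Methods

## The instability index

Post-intubation hemodynamic instability (PIHI) is quantified per patient
from three peri-intubation vital-sign sequences — systolic pressure (SP,
mmHg), diastolic pressure (DP, mmHg) and heart rate (HR, BPM) — sampled
nominally every 10 s over a window of 5 minutes before and 5 minutes after
intubation (60 points when complete; the intubation instant t = 0 itself is
not sampled, so the window is t ∈ {−300, …, −10, +10, …, +300} s).

For patient *i* and channel *s* the per-sequence coefficient of variation is

    y_is = σ_pop(x_i^s) / mean(x_i^s),

with the **population** standard deviation (divisor K, the sequence
length), taken verbatim from the index definition rather than the K−1
sample form. Being a ratio, y_is is invariant to the scale of the channel,
which is what makes mmHg and BPM channels commensurable.

Channel weights use the entropy-weight method. Each channel's CVs are
normalised into a share distribution p_is = y_is / Σ_i y_is across the N
patients and

    w_s = 1 + (1/ln N) Σ_i p_is ln p_is,      0·ln 0 := 0.

w_s is one minus the normalised Shannon entropy of the share distribution:
a channel whose instability is identical in every patient carries no
discriminating information and receives weight exactly 0; a channel whose
instability varies across patients receives more weight. Natural logarithms
are used throughout; the 1/ln N prefactor makes the weight base-invariant.
An all-zero channel also gets weight 0 (with a warning); the index is
undefined only if every channel is all-zero. Weights are computed once per
analysis cohort, not per subset.

The raw index is the weighted average z_i = Σ_s w_s y_is / Σ_s w_s — a
convex combination, so min_s y_is ≤ z_i ≤ max_s y_is exactly. Raw values
are min–max normalised to [0, 1] with bounds fit on the analysis cohort and
persisted (`NormalizationBounds`), so held-out patients are scored on the
training scale; out-of-bounds values are clipped with a logged warning.
The normalised index is discretised into five classes at edges 0.2 / 0.4 /
0.6 / 0.8 (right-open bins, the last bin closed so 1.0 is class 5) and
dichotomised at 0.3 into stable (< 0.3) / instable (≥ 0.3).

Completeness policy: a patient enters the CV matrix only if all three
channels have at least `min_points = 54` in-window measurements (90% of the
nominal 60). Incomplete sequences are excluded, never interpolated,
mirroring an exclusion-based (rather than imputation-based) data policy.
Both the window and the threshold are configuration parameters.

## The synthetic cohort generator

The hospital dataset behind the original analysis is not deposited, so the
generator produces cohorts with the statistical shape that the analysis
assumes; every downstream stage is validated by recovering a known ground
truth. What it emulates, and what it does not:

**Covariates.** Age, height, weight and the preoperative vitals are
truncated normals at published adult-cohort training moments (age
49.98 ± 13.88 y on [18, 91]; height 164.20 ± 6.72 cm; weight
64.51 ± 11.32 kg; SP 133.55 ± 20.41 / DP 78.42 ± 12.12 mmHg;
HR 79.06 ± 13.08 BPM); sex and hypertension are Bernoulli (female 69.8%,
hypertension 17.0%). The truncated-normal location is solved numerically so
the *truncated* mean equals the target (asymmetric bounds otherwise bias
the mean by up to a few tenths of a unit). Two joint dependencies are
modelled deliberately: height–weight correlation ρ = 0.6, which makes the
derived BMI = weight/(height/100)² reproduce the published BMI moments
(≈ 23.84 ± 3.38 — with independent height and weight the BMI mean would be
biased to ≈ 24.05); and SP–DP correlation ρ = 0.6, which makes the
constraint SP > DP + 5 mmHg violable by only ~0.3% of draws so that joint
redraws leave the marginal means unbiased. Hypertensive patients get a
+12 mmHg systolic offset, with the base mean and component SD deflated so
the mixture reproduces the overall target moments. The full empirical
correlation structure of a real cohort is *not* reproduced.

**Doses.** Per-kg doses are truncated normals centred at the published
per-kg medians (fentanyl 1.667 µg/kg, lidocaine 0.606, propofol 2.174,
rocuronium 0.714 mg/kg) with the published dispersions, truncated to the
published converted ranges intersected with the absolute dose range divided
by the patient's weight — generated cohorts therefore always pass default
dose validation. Absolute dose = per-kg × weight. No
pharmacokinetic/pharmacodynamic structure is modelled.

**Ground-truth instability.** Each patient carries a latent λ ∈ [0, 1],

    λ = logistic(η),
    η = β₀ + Σ_j β_j z_j + γ·z_age·z_SP + Σ_j δ_j (z_j² − 1)/√2 + ε,

with features standardised against the generator's own population targets
(so the truth function is deterministic in the configuration, not in the
sample) and ε ~ N(0, 0.20²). Default linear weight is concentrated on age
(0.28) and preoperative SP/DP/HR (0.22/0.16/0.16), with smaller terms for
doses and anthropometrics; the interaction (γ = 0.60) and curvature terms
(δ = 0.35 on HR, 0.25 on age) are zero-mean and uncorrelated with the
linear terms, so a substantial share of the signal is invisible to a linear
model — this is what lets the benchmark reproduce the qualitative ordering
in which tree ensembles clearly beat the linear baseline. The defaults were
fixed once by variance budgeting against three contracts: the class
distribution of the normalised index has class 2 modal and class 5 rare;
the index recovers λ with Spearman ρ ≥ 0.9 at n = 500; and a nonlinear
learner out-predicts the linear baseline by a wide margin. λ is written to
`truth.csv`, separate from the model inputs, so leakage into training is
structurally impossible.

**Sequences.** Pre-intubation values fluctuate around the patient's
preoperative baseline as a stationary AR(1) in relative units (φ = 0.7,
stationary SD 1.2%). At intubation an excursion rises instantaneously and
decays exponentially (τ = 90 s) with relative amplitude A_s·λ
(A_SP = A_DP = 0.60, A_HR = 0.50), giving raw CVs up to ≈ 0.15 at λ = 1.
Values are floored at 30 (mmHg or BPM). The kinetics are stipulated, not
fitted to any dataset: no measurement artifacts, cuff errors, missingness
or circadian structure are simulated. Consequently, passing tests show the
*pipeline* recovers a known generating process — they say nothing about how
well the index captures instability in real monitoring data.

## Balancing and splitting

The continuous index target is imbalanced after discretisation. SMOTE
oversampling brings every class to the majority count by default: each
synthetic row is a + u(b − a), u ~ U[0, 1], with a a uniformly drawn class
member and b one of its k = 5 nearest same-class neighbours — Euclidean
distance on z-scored features, because raw units (years, mmHg, mg/kg) are
not commensurable. The continuous target is interpolated with the same u;
since the class bins are intervals and both endpoints lie in the bin, the
synthetic label is automatically consistent. Binary features (sex,
hypertension) are rounded back to {0, 1}. Classes with a single member are
skipped (nothing to interpolate).

Tomek links — pairs of mutual nearest neighbours with different labels —
are then removed (both members by default; majority-member-only is
configurable). Removal is iterated to a fixed point because deleting points
can expose new mutual-nearest-neighbour pairs; the cleaned set always
passes a final link scan. A `ResampleReport` reconciles all counts exactly
(after = before + created − removed, per class).

Protocols: the default (`paper`) order resamples the **full** dataset and
then splits 9:1, reproducing the original workflow; synthetic neighbours of
training points can then appear in the test set, which flatters test
metrics. The `clean` protocol splits first and resamples the training set
only. Both are first-class options; reported benchmark numbers state the
protocol used.

## The model benchmark

Five regressors predict the normalised index from the 13 features (sex,
age, height, weight, BMI, hypertension, preoperative SP/DP/HR, four per-kg
doses), in that fixed column order (enforced at predict time):

| family | published settings | settings chosen here (unstated in the source) |
|---|---|---|
| MLR | — | — |
| SVR | RBF, gamma = 100, C = 1.5 | epsilon = 0.1 |
| ETR | 890 trees, unlimited depth | — |
| MLP | layers (66, 65), ReLU, lr 0.001, momentum 0.7 | SGD, batch 256, ≤ 200 epochs, early stopping on 10% validation |
| XGB | 648 trees, depth 16, min child weight 9 | eta = 0.1, hist tree method |

"RBF kernel coefficient of 100" is read as gamma = 100 and "penalty
parameter of 1.5" as C = 1.5; both are overridable since the phrasing is
ambiguous. SVR and MLP receive z-scored features (scaler fit on training
data only); trees and MLR take raw features. Predictions are clipped to
[0, 1] for reporting but not inside metric computations unless asked.
Ten-fold cross-validation and exhaustive grid search (scored by mean CV
RMSE; ties broken toward smaller settings) are provided. Tree-ensemble
feature importance is impurity-based, renormalised to sum to 1 per fold and
averaged over 10 folds, with the fold SD reported (error bars are
conventionally twice the SD); XGBoost uses total gain as its impurity
analogue.

## Evaluation

MAE, RMSE, MAPE and R² are direct transcriptions of their definitions.
MAPE is kept as a fraction internally (percent is presentation); pairs with
y = 0 — possible since the normalised index can be exactly 0 — are excluded
and counted, with an epsilon-floor variant deliberately not the default.
95% CIs are percentile bootstrap (1000 resamples by default) over
prediction pairs; the interval is widened to include the point estimate in
the rare finite-sample case where the percentile interval misses it. For
the stable/instable dichotomy, 'instable' is the positive class, true
labels come from the observed index, the predicted index is the score, and
AUC is trapezoidal (equal to the Mann–Whitney pair-ordering probability
with half credit for ties) with a bootstrap CI.

The feature-difference analysis screens variance homogeneity with Levene's
test (mean-centred) and compares means across the five classes with the
Welch ANOVA and the Brown–Forsythe robust ANOVA for means (F* with
Satterthwaite-type denominator degrees of freedom) — the appropriate pair
when variances differ across severity strata. Note the naming collision:
"Brown–Forsythe" also names a median-centred variance test; here it is the
means ANOVA, which is what makes its statistics comparable to Welch's.
Classes with fewer than 3 members are dropped with a notice. All p-values
are two-sided and unadjusted.

## Numerical and design notes

- All randomness flows through `numpy.random.Generator` seeded from
  explicit config/argument seeds; generator sub-streams are derived with
  `SeedSequence` spawn keys so stages are independently reproducible.
  Identical configuration gives byte-identical output files.
- Nearest-neighbour queries for SMOTE use scikit-learn; the Tomek scan uses
  an exact chunked distance computation with lowest-index tie-breaking so
  it matches a brute-force oracle exactly.
- `fit_bounds` requires at least two distinct values; a constant index
  cohort is a hard error rather than a silent degenerate normalisation.
- Problem sizes in the test suite: the full benchmark runs at n = 5000
  patients (≈ 11,700 rows after balancing) and the cross-validated
  importance analysis at n = 1500, sizes at which every reported contrast
  (tree vs linear R², AUC, importance ranking) is stable across seeds.
- Known limitations: the generator's marginals are faithful but its joint
  structure is minimal (three dependencies); sequence kinetics are
  stipulated; the paper-order protocol leaks synthetic neighbours across
  the split by design (use `clean` to avoid it); no probability
  calibration, no multiplicity correction, no ASA 3–4 comorbidity burden.
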