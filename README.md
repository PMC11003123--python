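# pihi — post-intubation hemodynamic instability index and prediction benchmark

After induction of general anesthesia, endotracheal intubation can trigger
abrupt excursions of blood pressure and heart rate. Anticipating this
*post-intubation hemodynamic instability* (PIHI) before the first drug is
given — from preoperative patient information and the planned induction
doses — is a practical problem in perioperative risk assessment. This
package implements, end to end and with a fully tested synthetic stand-in
for hospital data, a pipeline that:

1. **quantifies** instability per patient as the *integrated coefficient of
   variation* (ICV): for patient *i* and channel *s* ∈ {SP, DP, HR} over a
   ±5-min window around intubation,

       y_is = σ_pop(x_i^s) / x̄_i^s                      (per-sequence CV)
       w_s  = 1 + (1/ln N) Σ_i p_is ln p_is,  p_is = y_is / Σ_i y_is
       z_i  = Σ_s w_s y_is / Σ_s w_s                     (entropy-weighted index)

   normalised min–max to [0, 1], binned into 5 classes
   ([0, 0.2), …, [0.8, 1.0]) and dichotomised at 0.3 into stable/instable;
2. **simulates** cohorts (demographics, induction doses, vital-sign
   sequences) whose instability is driven by a known latent λ, so index
   recovery and prediction can be validated;
3. **balances** the discretised target with SMOTE oversampling plus
   Tomek-link cleaning and splits 9:1;
4. **benchmarks** five regressors (multiple linear regression, RBF support
   vector regression, extra-trees, a two-layer perceptron, XGBoost) on the
   13 input features, with 10-fold CV, grid search and Gini feature
   importance;
5. **evaluates** with MAE / RMSE / MAPE / R² (bootstrap 95% CIs), ROC/AUC
   at the 0.3 threshold, correlation matrices, and a Levene / Welch /
   Brown–Forsythe feature-difference table across instability classes.

Intended users: biostatisticians and anesthesia-informatics researchers who
want a reproducible reference implementation of the index and its
validation machinery, or a harness to plug their own cohort tables into
(`cohort.csv` / `sequences.csv` schemas, see `pihi.cohort_io`).

## Worked example

```python
from pihi.pipeline import run_pipeline

result = run_pipeline(n_patients=5000, seed=0, protocol="paper", n_boot=0)

print("channel weights:", dict(zip(result.weights.channels,
                                   result.weights.normalized.round(3))))
print("class shares:", {k: round(v, 3) for k, v in result.class_shares().items()})
print("lambda recovery (Spearman):", round(result.lambda_spearman, 3))
for fam, m in result.metrics.items():
    print(f"{fam}: R2={m.r2:.3f} MAE={m.mae:.4f} RMSE={m.rmse:.4f}")
print("ETR AUC at 0.3:", round(result.roc["ETR"].auc, 3))
```

Output (≈ 75 s on one CPU):

```
channel weights: {'SP': 0.335, 'DP': 0.335, 'HR': 0.33}
class shares: {1: 0.213, 2: 0.472, 3: 0.195, 4: 0.087, 5: 0.034}
lambda recovery (Spearman): 0.995
MLR: R2=0.507 MAE=0.1500 RMSE=0.1893
SVR: R2=0.197 MAE=0.2076 RMSE=0.2417
ETR: R2=0.974 MAE=0.0250 RMSE=0.0431
MLP: R2=0.789 MAE=0.0940 RMSE=0.1239
XGB: R2=0.969 MAE=0.0279 RMSE=0.0476
ETR AUC at 0.3: 0.993
```

Reading this: the three channels carry nearly equal entropy weights on this
cohort (their instability is comparably heterogeneous across patients); the
normalised index is imbalanced with class 2 modal and class 5 rare; the
index recovers the generator's latent instability almost perfectly in rank;
and the tree ensembles predict the index far better than the linear
baseline — the expected signature of a target built from interactions and
threshold effects. The `protocol="paper"` order resamples before splitting
(synthetic neighbours can leak into the test set, flattering all models);
pass `protocol="clean"` to split first and resample the training set only.

The same stages are available as a CLI:

```bash
pihi simulate --n 5000 --seed 7 --outdir data/
pihi icv --sequences data/sequences.csv --out icv.csv --weights weights.json
pihi balance --in features.csv --k 5 --seed 7 --protocol paper \
             --out train.csv --test-out test.csv --report report.json
pihi train --family etr --data train.csv --seed 7 --model-out model.bin
pihi evaluate --model model.bin --test test.csv --out metrics.json --roc roc.csv
pihi stats --data features.csv --out difference_table.csv
```

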