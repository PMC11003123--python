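"""Prediction metrics, ROC analysis, correlations and the per-class
feature-difference table.

Regression metrics are the direct definitions: MAE = mean |yhat - y|,
RMSE = sqrt(mean (yhat - y)^2), MAPE = mean |(yhat - y)/y| (a fraction
internally; percent is a presentation choice), R^2 = 1 - SSE/SST. Pairs
with y = 0 are excluded from MAPE (the normalised index can be exactly 0)
and counted. Confidence intervals are percentile bootstrap over prediction
pairs.

For the stable/instable dichotomy at 0.3 the true labels come from the
observed index and the predicted index serves as the score; the AUC is the
Mann-Whitney pair-ordering probability (ties get half credit), with a
bootstrap CI.

The feature-difference analysis compares each feature across the five
instability classes with Levene's test (mean-centred) for variance
homogeneity and, since physiological features are typically
heteroscedastic across severity strata, the Welch and Brown-Forsythe
ANOVAs for mean differences (Satterthwaite-type degrees of freedom,
two-sided p-values, no multiplicity correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .icv import STABLE_THRESHOLD, assign_binary

__all__ = [
    "MetricsReport",
    "ROCReport",
    "regression_metrics",
    "metric_cis",
    "roc_auc",
    "correlation_matrix",
    "feature_difference_table",
]


@dataclass
class MetricsReport:
    mae: float
    rmse: float
    mape: float     # fraction, not percent
    r2: float
    n: int
    mape_excluded: int = 0          # pairs dropped from MAPE for y_true = 0
    ci: dict[str, tuple[float, float]] | None = None
    ci_method: str | None = None

    def __post_init__(self):
        if self.ci is not None:
            for name, (lo, hi) in self.ci.items():
                point = getattr(self, name)
                if not (lo <= point <= hi):
                    raise ValueError(f"{name} CI ({lo}, {hi}) does not bracket {point}")

    def as_dict(self) -> dict:
        out = {"mae": self.mae, "rmse": self.rmse, "mape": self.mape,
               "r2": self.r2, "n": self.n, "mape_excluded": self.mape_excluded}
        if self.ci is not None:
            out["ci"] = {k: list(v) for k, v in self.ci.items()}
            out["ci_method"] = self.ci_method
        return out


@dataclass
class ROCReport:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_ci: tuple[float, float] | None = None
    n_positive: int = 0
    n_negative: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})


def _point_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float, float, int]:
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    nz = y_true != 0
    mape = float(np.mean(np.abs(err[nz] / y_true[nz]))) if nz.any() else float("nan")
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err ** 2)) / sst if sst > 0 else float("nan")
    return mae, rmse, mape, r2, int((~nz).sum())


def regression_metrics(y_true, y_pred) -> MetricsReport:
    """Point MAE/RMSE/MAPE/R^2 for a prediction vector."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    if y_true.size < 2:
        raise ValueError("need at least 2 pairs")
    mae, rmse, mape, r2, n_zero = _point_metrics(y_true, y_pred)
    if n_zero:
        warnings.warn(f"{n_zero} pair(s) with y_true = 0 excluded from MAPE")
    return MetricsReport(mae=mae, rmse=rmse, mape=mape, r2=r2,
                         n=y_true.size, mape_excluded=n_zero)


def metric_cis(y_true, y_pred, n_boot: int = 1000,
               seed: int | None = 0) -> MetricsReport:
    """Metrics with 95% percentile-bootstrap CIs over prediction pairs."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 10:
        raise ValueError("bootstrap CIs need at least 10 pairs")
    report = regression_metrics(y_true, y_pred)
    rng = np.random.default_rng(seed)
    samples = {"mae": [], "rmse": [], "mape": [], "r2": []}
    n = y_true.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        mae, rmse, mape, r2, _ = _point_metrics(y_true[idx], y_pred[idx])
        for key, value in zip(samples, (mae, rmse, mape, r2)):
            samples[key].append(value)
    ci = {}
    for key, vals in samples.items():
        lo, hi = np.nanpercentile(vals, [2.5, 97.5])
        point = getattr(report, key)
        # the percentile interval is widened to the point estimate if a
        # finite-sample bootstrap lands entirely on one side of it
        ci[key] = (min(float(lo), point), max(float(hi), point))
    report.ci = ci
    report.ci_method = f"percentile bootstrap, {n_boot} resamples"
    return report


def roc_auc(y_true_icv, y_score, threshold: float = STABLE_THRESHOLD,
            n_boot: int = 1000, seed: int | None = 0) -> ROCReport:
    """ROC/AUC for the stable/instable dichotomy of the true index.

    'instable' (index >= threshold) is the positive class; the predicted
    index is the ranking score. AUC is computed by trapezoidal integration
    of the ROC curve, which equals the Mann-Whitney pair-ordering
    probability with half credit for ties.
    """
    y_true_icv = np.asarray(y_true_icv, dtype=float)
    y_score = np.asarray(y_score, dtype=float)
    labels = (assign_binary(y_true_icv, threshold) == "instable").astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present after thresholding")
    fpr, tpr, thresholds = roc_curve(labels, y_score)
    auc = float(roc_auc_score(labels, y_score))
    auc_ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        boots = []
        n = labels.size
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if labels[idx].min() == labels[idx].max():
                continue
            boots.append(roc_auc_score(labels[idx], y_score[idx]))
        lo, hi = np.percentile(boots, [2.5, 97.5])
        auc_ci = (min(float(lo), auc), max(float(hi), auc))
    return ROCReport(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc,
                     auc_ci=auc_ci, n_positive=int(labels.sum()),
                     n_negative=int((1 - labels).sum()))


def correlation_matrix(table: pd.DataFrame, method: str = "pearson",
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlation coefficients and two-sided p-values.

    Zero-variance columns yield undefined coefficients, reported as NaN.
    Returns (coefficients, p_values), both symmetric with unit diagonal.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    cols = list(table.columns)
    k = len(cols)
    corr = np.eye(k)
    pvals = np.zeros((k, k))
    func = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i in range(k):
        xi = table[cols[i]].to_numpy(dtype=float)
        for j in range(i + 1, k):
            xj = table[cols[j]].to_numpy(dtype=float)
            if xi.std() == 0 or xj.std() == 0:
                r, p = np.nan, np.nan
            else:
                res = func(xi, xj)
                r, p = float(res.statistic), float(res.pvalue)
            corr[i, j] = corr[j, i] = r
            pvals[i, j] = pvals[j, i] = p
    return (pd.DataFrame(corr, index=cols, columns=cols),
            pd.DataFrame(pvals, index=cols, columns=cols))


def _welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA (F and two-sided p)."""
    g = len(groups)
    n = np.array([len(x) for x in groups], dtype=float)
    m = np.array([x.mean() for x in groups])
    v = np.array([x.var(ddof=1) for x in groups])
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    a = np.sum(w * (m - mw) ** 2) / (g - 1)
    r = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    b = 1 + 2 * (g - 2) / (g ** 2 - 1) * r
    f = a / b
    df2 = (g ** 2 - 1) / (3 * r)
    return float(f), float(stats.f.sf(f, g - 1, df2))


def _brown_forsythe_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Brown-Forsythe robust ANOVA for means (F* with Satterthwaite df)."""
    g = len(groups)
    n = np.array([len(x) for x in groups], dtype=float)
    m = np.array([x.mean() for x in groups])
    v = np.array([x.var(ddof=1) for x in groups])
    total = n.sum()
    grand = np.sum(n * m) / total
    denom_terms = (1 - n / total) * v
    f = np.sum(n * (m - grand) ** 2) / np.sum(denom_terms)
    c = denom_terms / np.sum(denom_terms)
    df2 = 1.0 / np.sum(c ** 2 / (n - 1))
    return float(f), float(stats.f.sf(f, g - 1, df2))


def feature_difference_table(features: pd.DataFrame, class_labels,
                             min_class_size: int = 3) -> pd.DataFrame:
    """Per-feature Levene / Welch / Brown-Forsythe statistics across the
    instability classes.

    Classes with fewer than ``min_class_size`` members are dropped with a
    notice; at least two usable classes are required.
    """
    class_labels = np.asarray(class_labels)
    usable = []
    for cls in np.unique(class_labels):
        size = int((class_labels == cls).sum())
        if size >= min_class_size:
            usable.append(cls)
        else:
            warnings.warn(f"class {cls} has {size} member(s) (< {min_class_size}); dropped")
    if len(usable) < 2:
        raise ValueError("need at least 2 classes with enough members")
    rows = []
    for col in features.columns:
        groups = [features.loc[class_labels == cls, col].to_numpy(dtype=float)
                  for cls in usable]
        if any(np.var(x, ddof=1) == 0 for x in groups):
            rows.append({"feature": col, "levene_stat": np.nan, "levene_p": np.nan,
                         "welch_stat": np.nan, "welch_p": np.nan,
                         "brown_forsythe_stat": np.nan, "brown_forsythe_p": np.nan})
            continue
        lev_stat, lev_p = stats.levene(*groups, center="mean")
        w_stat, w_p = _welch_anova(groups)
        bf_stat, bf_p = _brown_forsythe_anova(groups)
        rows.append({"feature": col,
                     "levene_stat": float(lev_stat), "levene_p": float(lev_p),
                     "welch_stat": w_stat, "welch_p": w_p,
                     "brown_forsythe_stat": bf_stat, "brown_forsythe_p": bf_p})
    return pd.DataFrame(rows).set_index("feature")
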