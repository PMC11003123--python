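"""The five-regressor benchmark for predicting the instability index.

Families: multiple linear regression (MLR, the baseline), RBF-kernel
support vector regression (SVR), extremely randomised trees (ETR),
a two-hidden-layer perceptron (MLP) and gradient-boosted trees (XGBoost).
Default hyperparameters are the published settings: SVR gamma = 100,
C = 1.5; ETR 890 estimators, unlimited depth; MLP hidden layers (66, 65),
ReLU, SGD with learning rate 0.001 and momentum 0.7; XGBoost 648
estimators, max depth 16, min child weight 9. Settings the publication
leaves open (SVR epsilon, MLP batch size/epochs, XGBoost learning rate) use
documented conventional defaults and are overridable per spec.

SVR and MLP see z-scored features (scaler fit on the training data only);
tree ensembles and MLR consume raw features. Feature importance for the
tree families is impurity-based (Gini), renormalised to sum to one and
averaged over cross-validation folds; XGBoost uses total gain as its
impurity analogue.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .balance import LabeledDataset
from .evaluate import MetricsReport, regression_metrics

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "TrainedModel",
    "ImportanceVector",
    "default_spec",
    "train",
    "predict",
    "kfold_cv",
    "grid_search",
    "gini_importance",
]

FAMILIES = ("MLR", "SVR", "ETR", "MLP", "XGB")

TREE_FAMILIES = ("ETR", "XGB")

SCALED_FAMILIES = ("SVR", "MLP")

_PAPER_DEFAULTS: dict[str, dict] = {
    "MLR": {},
    "SVR": {"gamma": 100.0, "C": 1.5, "epsilon": 0.1},
    "ETR": {"n_estimators": 890, "max_depth": None},
    "MLP": {"hidden_layer_sizes": (66, 65), "activation": "relu",
            "learning_rate_init": 0.001, "momentum": 0.7, "batch_size": 256,
            "max_iter": 200, "early_stopping": True, "validation_fraction": 0.1},
    "XGB": {"n_estimators": 648, "max_depth": 16, "min_child_weight": 9,
            "learning_rate": 0.1},
}


@dataclass
class ModelSpec:
    """A model family plus hyperparameters; unspecified ones resolve to the
    documented defaults for that family."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        self.hyperparameters = {**_PAPER_DEFAULTS[self.family], **self.hyperparameters}


def default_spec(family: str, seed: int = 0) -> ModelSpec:
    """The published configuration for a family (MLR has no hyperparameters)."""
    return ModelSpec(family=family, seed=seed)


def _build_estimator(spec: ModelSpec):
    hp = spec.hyperparameters
    if spec.family == "MLR":
        est = LinearRegression()
    elif spec.family == "SVR":
        est = SVR(kernel="rbf", **hp)
    elif spec.family == "ETR":
        est = ExtraTreesRegressor(random_state=spec.seed, n_jobs=1, **hp)
    elif spec.family == "MLP":
        est = MLPRegressor(solver="sgd", random_state=spec.seed, **hp)
    else:  # XGB
        est = XGBRegressor(random_state=spec.seed, n_jobs=1, tree_method="hist",
                           importance_type="total_gain", **hp)
    if spec.family in SCALED_FAMILIES:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    feature_order: list[str]
    n_train: int
    clip_predictions: bool = True

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return predict(self, features)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path, feature_order: list[str] | None = None) -> "TrainedModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if feature_order is not None and list(model.feature_order) != list(feature_order):
            raise ValueError("stored model was trained with a different feature order")
        return model


@dataclass
class ImportanceVector:
    """Per-feature normalised importance (sums to 1) with fold-to-fold SD."""

    features: list[str]
    importance: np.ndarray
    fold_sd: np.ndarray

    def top(self, n: int) -> list[str]:
        order = np.argsort(self.importance)[::-1]
        return [self.features[i] for i in order[:n]]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"importance": self.importance, "fold_sd": self.fold_sd},
                            index=pd.Index(self.features, name="feature"))


def train(spec: ModelSpec, data: LabeledDataset,
          clip_predictions: bool = True) -> TrainedModel:
    """Fit one family on a labelled dataset.

    Deterministic given the spec seed. A constant target triggers a warning
    but still fits.
    """
    import warnings
    y = data.target
    if np.all(y == y[0]):
        warnings.warn("training target is constant; the fitted model is degenerate")
    est = _build_estimator(spec)
    X = data.features.to_numpy(dtype=float)
    est.fit(X, y)
    return TrainedModel(spec=spec, estimator=est,
                        feature_order=list(data.features.columns),
                        n_train=len(data), clip_predictions=clip_predictions)


def predict(model: TrainedModel, features: pd.DataFrame,
            clip: bool | None = None) -> np.ndarray:
    """Predict the normalised index; refuses mismatched feature order."""
    if list(features.columns) != list(model.feature_order):
        raise ValueError(
            f"feature columns {list(features.columns)} do not match the "
            f"training order {model.feature_order}")
    pred = np.asarray(model.estimator.predict(features.to_numpy(dtype=float)),
                      dtype=float)
    clip = model.clip_predictions if clip is None else clip
    return np.clip(pred, 0.0, 1.0) if clip else pred


def kfold_cv(spec: ModelSpec, data: LabeledDataset, k: int = 10,
             seed: int | None = 0) -> list[MetricsReport]:
    """k-fold cross-validation (default 10): per-fold point metrics on the
    held-out fold. Fold assignment is deterministic given the seed."""
    if k > len(data):
        raise ValueError(f"k={k} exceeds the number of rows {len(data)}")
    reports = []
    for train_idx, val_idx in KFold(n_splits=k, shuffle=True, random_state=seed)\
            .split(np.arange(len(data))):
        model = train(spec, data.take(train_idx))
        pred = predict(model, data.take(val_idx).features, clip=False)
        reports.append(regression_metrics(data.target[val_idx], pred))
    return reports


def grid_search(family: str, grid: dict[str, list], data: LabeledDataset,
                k: int = 10, seed: int | None = 0,
                ) -> tuple[ModelSpec, pd.DataFrame]:
    """Exhaustive grid search scored by mean cross-validated RMSE.

    Ties are broken toward smaller hyperparameter values (fewer estimators,
    shallower trees) in the order the grid lists its keys. Returns the best
    spec and the full results table (one row per grid point).
    """
    from itertools import product
    keys = list(grid)
    if not keys or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    rows = []
    for combo in product(*(grid[k_] for k_ in keys)):
        hp = dict(zip(keys, combo))
        reports = kfold_cv(ModelSpec(family, hp, seed=seed or 0), data, k=k, seed=seed)
        rows.append({**hp, "mean_rmse": float(np.mean([r.rmse for r in reports]))})
    results = pd.DataFrame(rows)
    order = results.sort_values(
        ["mean_rmse"] + keys,
        key=lambda col: col.map(lambda v: (v is None, v)) if col.name in keys else col)
    best = order.iloc[0]
    best_hp = {k_: best[k_] for k_ in keys}
    best_hp = {k_: (None if pd.isna(v) else v) for k_, v in best_hp.items()}
    return ModelSpec(family, best_hp, seed=seed or 0), results


def gini_importance(spec: ModelSpec, data: LabeledDataset, k: int = 10,
                    seed: int | None = 0) -> ImportanceVector:
    """Impurity-based feature importance of a tree ensemble, per
    cross-validation fold, renormalised and averaged; the fold SD feeds the
    presentation layer (error bars are conventionally twice the SD)."""
    if spec.family not in TREE_FAMILIES:
        raise ValueError(f"Gini importance requires a tree family {TREE_FAMILIES}, "
                         f"got {spec.family}")
    per_fold = []
    for train_idx, _ in KFold(n_splits=k, shuffle=True, random_state=seed)\
            .split(np.arange(len(data))):
        model = train(spec, data.take(train_idx))
        imp = np.asarray(model.estimator.feature_importances_, dtype=float)
        per_fold.append(imp / imp.sum())
    per_fold = np.array(per_fold)
    mean = per_fold.mean(axis=0)
    return ImportanceVector(features=list(data.features.columns),
                            importance=mean / mean.sum(),
                            fold_sd=per_fold.std(axis=0, ddof=1))
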