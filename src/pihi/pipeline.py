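"""End-to-end orchestration: simulate (or load) a cohort, compute the
instability index, balance, split, train the model benchmark and evaluate.

This is the programmatic equivalent of running the CLI stages in sequence
and is what the reproduction script drives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as models_mod
from .balance import LabeledDataset, ResampleReport, smote_tomek, split_train_test
from .cohort_io import build_feature_table
from .evaluate import MetricsReport, ROCReport, metric_cis, regression_metrics, roc_auc
from .icv import NormalizationBounds, WeightVector, icv_table
from .synthetic import SimCohort, SimConfig, generate_cohort

__all__ = ["PipelineResult", "prepare_dataset", "run_benchmark", "run_pipeline"]


@dataclass
class PipelineResult:
    sim: SimCohort
    icv: pd.DataFrame                 # per-patient index table
    weights: WeightVector
    bounds: NormalizationBounds
    dataset: LabeledDataset           # before resampling
    resample_report: ResampleReport
    train_set: LabeledDataset
    test_set: LabeledDataset
    metrics: dict[str, MetricsReport] = field(default_factory=dict)
    roc: dict[str, ROCReport] = field(default_factory=dict)

    @property
    def lambda_spearman(self) -> float:
        """Rank agreement between the generator's latent instability and the
        computed index (recoverability check)."""
        from scipy.stats import spearmanr
        ids = self.icv.index
        lam = pd.Series(self.sim.true_lambda,
                        index=[r.patient_id for r in self.sim.records])
        return float(spearmanr(lam.loc[ids], self.icv["norm_icv"]).statistic)

    def class_shares(self) -> dict[int, float]:
        counts = self.icv["icv_class"].value_counts()
        return {int(c): float(counts.get(c, 0)) / len(self.icv) for c in range(1, 6)}


def prepare_dataset(sim: SimCohort, *, min_points: int = 54):
    """Index computation + feature assembly for a simulated cohort."""
    table, weights, bounds = icv_table(sim.sequences, window_s=sim.config.window_s,
                                       min_points=min_points)
    targets = table["norm_icv"].to_dict()
    features, _ = build_feature_table(sim.records, sim.doses, targets=targets)
    dataset = LabeledDataset.from_feature_table(features)
    return table, weights, bounds, dataset


def run_benchmark(train_set: LabeledDataset, test_set: LabeledDataset,
                  families=models_mod.FAMILIES, seed: int = 0,
                  n_boot: int = 200):
    """Fit each family on the training set and evaluate on the test set.

    Returns (metrics, roc) keyed by family; predictions are clipped to
    [0, 1] for reporting.
    """
    metrics: dict[str, MetricsReport] = {}
    roc: dict[str, ROCReport] = {}
    for family in families:
        model = models_mod.train(models_mod.default_spec(family, seed=seed), train_set)
        pred = models_mod.predict(model, test_set.features)
        if n_boot > 0:
            metrics[family] = metric_cis(test_set.target, pred, n_boot=n_boot, seed=seed)
        else:
            metrics[family] = regression_metrics(test_set.target, pred)
        try:
            roc[family] = roc_auc(test_set.target, pred, n_boot=n_boot, seed=seed)
        except ValueError:
            pass  # degenerate test split: only one binary class present
    return metrics, roc


def run_pipeline(n_patients: int = 5000, seed: int = 0, *,
                 protocol: str = "paper", families=models_mod.FAMILIES,
                 split_ratio: float = 0.9, smote_k: int = 5,
                 n_boot: int = 200, config: SimConfig | None = None,
                 ) -> PipelineResult:
    """Full run on a synthetic cohort.

    ``protocol="paper"`` resamples the whole dataset and then splits 9:1;
    ``protocol="clean"`` splits first and resamples only the training set,
    avoiding synthetic-neighbour leakage into the test set.
    """
    if protocol not in ("paper", "clean"):
        raise ValueError(f"protocol must be 'paper' or 'clean', got {protocol!r}")
    if config is None:
        config = SimConfig(n_patients=n_patients, seed=seed)
    sim = generate_cohort(config)
    table, weights, bounds, dataset = prepare_dataset(sim)

    if protocol == "paper":
        balanced, report = smote_tomek(dataset, k=smote_k, seed=seed)
        train_set, test_set = split_train_test(balanced, ratio=split_ratio, seed=seed)
    else:
        train_raw, test_set = split_train_test(dataset, ratio=split_ratio, seed=seed)
        train_set, report = smote_tomek(train_raw, k=smote_k, seed=seed)

    result = PipelineResult(sim=sim, icv=table, weights=weights, bounds=bounds,
                            dataset=dataset, resample_report=report,
                            train_set=train_set, test_set=test_set)
    if families:
        result.metrics, result.roc = run_benchmark(
            train_set, test_set, families=families, seed=seed, n_boot=n_boot)
    return result
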