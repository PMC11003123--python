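import numpy as np
import pandas as pd
import pytest

from pihi.balance import LabeledDataset
from pihi.cohort_io import FEATURE_ORDER
from pihi.icv import assign_class
from pihi.synthetic import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A 150-patient default cohort shared across tests."""
    return generate_cohort(SimConfig(n_patients=150, seed=11))


def random_labeled_dataset(rng, n, n_features=4, n_classes=3, feature_names=None):
    """A random dataset with targets placed inside the requested class bins."""
    classes = rng.integers(1, n_classes + 1, size=n)
    target = (classes - 1) * 0.2 + 0.2 * rng.random(n) * 0.999
    names = feature_names or [f"f{j}" for j in range(n_features)]
    features = pd.DataFrame(rng.normal(size=(n, n_features)), columns=names)
    return LabeledDataset(features=features, target=target,
                          class_labels=assign_class(target))


def cohort_csv(path, rows):
    """Write a cohort.csv fixture from a list of row dicts (defaults filled)."""
    defaults = dict(age=45, sex=0, height_cm=165.0, weight_kg=64.0,
                    hypertension=0, pre_sp=130.0, pre_dp=78.0, pre_hr=78.0,
                    fentanyl_mg=0.1, lidocaine_mg=40.0, propofol_mg=130.0,
                    rocuronium_mg=45.0)
    out = []
    for i, row in enumerate(rows):
        full = {"patient_id": f"P{i}", **defaults, **row}
        full.setdefault("bmi", full["weight_kg"] / (full["height_cm"] / 100) ** 2)
        out.append(full)
    pd.DataFrame(out).to_csv(path, index=False)
    return path
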