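"""Class-imbalance handling for the continuous instability target.

The normalised index is first discretised into the five instability classes,
which leaves one dominant class; minority classes are then oversampled with
SMOTE (synthetic rows interpolated between same-class nearest neighbours)
and the augmented set is cleaned by removing Tomek links (mutually nearest
neighbours with different class labels). Distances are Euclidean on
z-scored features — the raw feature units (years, cm, mmHg, mg/kg) are not
commensurable. The continuous target is interpolated alongside the
features, which keeps every synthetic row's class label consistent with its
target (class bins are intervals, so a convex combination of two targets in
a bin stays in the bin).

Two protocols for combining resampling with the 9:1 train/test split are
supported at the pipeline level: ``paper`` resamples the full dataset and
then splits (synthetic neighbours can leak across the split), while
``clean`` splits first and resamples the training set only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .cohort_io import FEATURE_ORDER
from .icv import assign_class

__all__ = [
    "LabeledDataset",
    "ResampleReport",
    "smote_oversample",
    "find_tomek_links",
    "smote_tomek",
    "split_train_test",
]

BINARY_FEATURES = ("sex", "hypertension")


@dataclass
class LabeledDataset:
    """Feature matrix with continuous target, class labels and row origin."""

    features: pd.DataFrame            # N x 13, FEATURE_ORDER columns
    target: np.ndarray                # normalised ICV in [0, 1]
    class_labels: np.ndarray          # 1..5, consistent with the target
    origin: np.ndarray = None         # "original" / "synthetic" per row

    def __post_init__(self):
        self.target = np.asarray(self.target, dtype=float)
        self.class_labels = np.asarray(self.class_labels, dtype=int)
        if self.origin is None:
            self.origin = np.full(len(self.target), "original", dtype=object)
        self.origin = np.asarray(self.origin, dtype=object)
        n = len(self.features)
        if not (len(self.target) == len(self.class_labels) == len(self.origin) == n):
            raise ValueError("features, target, class_labels and origin lengths differ")
        if self.features.isna().any().any():
            raise ValueError("feature matrix contains missing entries")
        if not np.array_equal(self.class_labels, assign_class(self.target)):
            raise ValueError("class_labels inconsistent with target under the class bins")

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame, target_column: str = "icv"):
        """Build from a feature table carrying the normalised index."""
        target = table[target_column].to_numpy(dtype=float)
        features = table[FEATURE_ORDER].reset_index(drop=True)
        return cls(features=features, target=target, class_labels=assign_class(target))

    def __len__(self) -> int:
        return len(self.target)

    def take(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            features=self.features.iloc[idx].reset_index(drop=True),
            target=self.target[idx], class_labels=self.class_labels[idx],
            origin=self.origin[idx])

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.class_labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass
class ResampleReport:
    """Bookkeeping for one resampling run; counts reconcile per class."""

    counts_before: dict[int, int]
    counts_after: dict[int, int]
    created: dict[int, int]
    removed: dict[int, int]
    k_neighbors: int
    seed: int | None
    skipped_classes: list[int] = field(default_factory=list)

    def __post_init__(self):
        for cls in set(self.counts_before) | set(self.counts_after):
            before = self.counts_before.get(cls, 0)
            after = self.counts_after.get(cls, 0)
            if after != before + self.created.get(cls, 0) - self.removed.get(cls, 0):
                raise ValueError(f"class {cls}: counts do not reconcile")

    @property
    def n_created(self) -> int:
        return sum(self.created.values())

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def _standardize(X: np.ndarray) -> np.ndarray:
    """z-score columns; zero-variance columns are left centred only."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mean) / sd


def smote_oversample(data: LabeledDataset, k: int = 5,
                     targets: dict[int, int] | None = None,
                     seed: int | None = None) -> LabeledDataset:
    """SMOTE: grow each minority class to its target count by interpolation.

    Each synthetic row is ``a + u (b - a)`` with ``u ~ U[0, 1]``, ``a`` a
    uniformly chosen row of the class and ``b`` one of ``a``'s ``k`` nearest
    same-class neighbours (Euclidean on z-scored features, ``k`` capped at
    class size − 1). The continuous target is interpolated with the same
    ``u``; binary features are rounded back to {0, 1} on synthetic rows.
    Default targets bring every class up to the majority count. Classes
    with a single member cannot be interpolated and are skipped with a
    warning.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    counts = data.class_counts()
    if targets is None:
        majority = max(counts.values())
        targets = {cls: majority for cls in counts}
    rng = np.random.default_rng(seed)
    X = data.features.to_numpy(dtype=float)
    Z = _standardize(X)
    binary_idx = [data.features.columns.get_loc(c) for c in BINARY_FEATURES
                  if c in data.features.columns]

    new_rows, new_targets, new_labels = [], [], []
    for cls in sorted(counts):
        need = targets.get(cls, counts[cls]) - counts[cls]
        if need <= 0:
            continue
        members = np.where(data.class_labels == cls)[0]
        if members.size < 2:
            warnings.warn(f"class {cls} has a single member; cannot interpolate, skipped")
            continue
        k_eff = min(k, members.size - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Z[members])
        _, neigh = nn.kneighbors(Z[members])  # column 0 is the point itself
        seed_pos = rng.integers(0, members.size, size=need)
        neigh_pick = rng.integers(0, k_eff, size=need)
        u = rng.random(need)
        for s_pos, n_pick, u_i in zip(seed_pos, neigh_pick, u):
            a = members[s_pos]
            b = members[neigh[s_pos, n_pick + 1]]
            row = X[a] + u_i * (X[b] - X[a])
            for j in binary_idx:
                row[j] = round(row[j])
            new_rows.append(row)
            new_targets.append(data.target[a] + u_i * (data.target[b] - data.target[a]))
            new_labels.append(cls)

    if not new_rows:
        return data
    features = pd.concat(
        [data.features,
         pd.DataFrame(new_rows, columns=data.features.columns)],
        ignore_index=True)
    return LabeledDataset(
        features=features,
        target=np.concatenate([data.target, new_targets]),
        class_labels=np.concatenate([data.class_labels, new_labels]),
        origin=np.concatenate([data.origin, ["synthetic"] * len(new_rows)]))


def _nearest_neighbor_indices(Z: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Index of each row's nearest other row; ties go to the lowest index."""
    n = len(Z)
    sq = np.einsum("ij,ij->i", Z, Z)
    out = np.empty(n, dtype=int)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (Z[start:stop] @ Z.T)
        d2[np.arange(start, stop) - start, np.arange(start, stop)] = np.inf
        out[start:stop] = np.argmin(d2, axis=1)
    return out


def find_tomek_links(data: LabeledDataset) -> list[tuple[int, int]]:
    """All pairs of mutual nearest neighbours carrying different class labels.

    Distances are Euclidean on z-scored features; nearest-neighbour ties are
    broken toward the lowest row index. Returns sorted (i, j) pairs, i < j.
    """
    if len(data) < 2:
        return []
    Z = _standardize(data.features.to_numpy(dtype=float))
    nn = _nearest_neighbor_indices(Z)
    links = []
    for i in range(len(data)):
        j = nn[i]
        if j > i and nn[j] == i and data.class_labels[i] != data.class_labels[j]:
            links.append((i, int(j)))
    return links


def smote_tomek(data: LabeledDataset, k: int = 5,
                targets: dict[int, int] | None = None,
                seed: int | None = None,
                removal: str = "both") -> tuple[LabeledDataset, ResampleReport]:
    """SMOTE oversampling followed by Tomek-link cleaning.

    ``removal="both"`` (default) drops both members of every link found in
    the augmented set; ``"majority"`` drops only the link member from the
    more frequent class (post-SMOTE counts, ties to the lower label).
    Removing points can expose fresh mutual-nearest-neighbour pairs, so
    removal is repeated until the set is link-free — the cleaned output
    always passes a final link scan.
    """
    if removal not in ("both", "majority"):
        raise ValueError(f"removal must be 'both' or 'majority', got {removal!r}")
    counts_before = data.class_counts()
    augmented = smote_oversample(data, k=k, targets=targets, seed=seed)
    created = {cls: 0 for cls in counts_before}
    for cls, cnt in augmented.class_counts().items():
        created[cls] = cnt - counts_before.get(cls, 0)

    removed = {cls: 0 for cls in counts_before}
    cleaned = augmented
    while True:
        links = find_tomek_links(cleaned)
        if not links:
            break
        post_counts = cleaned.class_counts()
        drop = set()
        for i, j in links:
            if removal == "both":
                drop.update((i, j))
            else:
                ci, cj = cleaned.class_labels[i], cleaned.class_labels[j]
                drop.add(i if (post_counts[ci], -ci) >= (post_counts[cj], -cj) else j)
        for idx in drop:
            cls = int(cleaned.class_labels[idx])
            removed[cls] = removed.get(cls, 0) + 1
        keep = np.setdiff1d(np.arange(len(cleaned)), np.array(sorted(drop), dtype=int))
        cleaned = cleaned.take(keep)
    report = ResampleReport(
        counts_before=counts_before, counts_after=cleaned.class_counts(),
        created=created, removed=removed, k_neighbors=k, seed=seed,
        skipped_classes=[cls for cls, cnt in counts_before.items()
                         if cnt == 1 and targets is None])
    return cleaned, report


def split_train_test(data: LabeledDataset, ratio: float = 0.9,
                     seed: int | None = None,
                     stratify: bool = False) -> tuple[LabeledDataset, LabeledDataset]:
    """Shuffled, disjoint, exhaustive train/test split (default 9:1).

    Train size is floor(ratio * N); stratification by instability class is
    optional.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    if len(data) < 10:
        raise ValueError("need at least 10 rows to split")
    idx_train, idx_test = train_test_split(
        np.arange(len(data)), train_size=ratio, random_state=seed, shuffle=True,
        stratify=data.class_labels if stratify else None)
    return data.take(idx_train), data.take(idx_test)
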