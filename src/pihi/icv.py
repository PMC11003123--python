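"""The integrated coefficient of variation (ICV): a post-intubation
hemodynamic instability index.

For patient *i* and vital-sign channel *s* (systolic pressure, diastolic
pressure, heart rate), the per-sequence coefficient of variation over the
peri-intubation window is

    y_is = pop_std(x_i^s) / mean(x_i^s)

with the *population* standard deviation (divisor K, the sequence length).
Channel weights come from the information entropy of each channel's share
distribution across the cohort,

    w_s = 1 + (1/ln N) * sum_i p_is ln p_is,   p_is = y_is / sum_i y_is,

so that a channel whose CVs are homogeneous across patients (maximal
entropy) gets weight 0 and a more discriminating channel gets more weight.
The index is the weighted average z_i = sum_s w_s y_is / sum_s w_s, a convex
combination of the patient's channel CVs, then min-max normalised to [0, 1]
over the analysis cohort. The normalised index is binned into five classes
([0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1.0]) and dichotomised at
0.3 into stable / instable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cohort_io import CHANNELS, VitalSequence

__all__ = [
    "CVMatrix",
    "WeightVector",
    "NormalizationBounds",
    "ICVResult",
    "compute_cv",
    "compute_cv_matrix",
    "entropy_weights",
    "integrate_icv",
    "fit_bounds",
    "normalize_icv",
    "assign_class",
    "assign_binary",
    "icv_table",
    "CLASS_EDGES",
    "STABLE_THRESHOLD",
]

#: Normalised-index bin edges; bins are right-open except [0.8, 1.0].
CLASS_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

#: Binary stable/instable cut on the normalised index.
STABLE_THRESHOLD = 0.3


@dataclass
class CVMatrix:
    """N patients x S channels matrix of per-sequence CV values."""

    values: np.ndarray
    patient_ids: list[str]
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("CV matrix must be 2-D (patients x channels)")
        if self.values.shape != (len(self.patient_ids), len(self.channels)):
            raise ValueError("CV matrix shape does not match ids/channels")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("CV values must be finite and non-negative")


@dataclass
class WeightVector:
    """Raw entropy weights (each in [0, 1]) and their sum-1 normalisation."""

    raw: np.ndarray
    normalized: np.ndarray
    channels: tuple[str, ...] = CHANNELS


@dataclass(frozen=True)
class NormalizationBounds:
    """Min-max bounds of the raw index, fit on the analysis cohort and
    persisted so held-out patients are normalised on the training scale."""

    icv_min: float
    icv_max: float

    def __post_init__(self) -> None:
        if not self.icv_max > self.icv_min:
            raise ValueError(f"degenerate bounds ({self.icv_min}, {self.icv_max})")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh)

    @classmethod
    def from_json(cls, path) -> "NormalizationBounds":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class ICVResult:
    patient_id: str
    raw_icv: float
    norm_icv: float
    icv_class: int
    binary_label: str


def compute_cv(seq) -> float:
    """Coefficient of variation of one sequence: population std over mean.

    ``seq`` may be a :class:`~pihi.cohort_io.VitalSequence` or an array of
    values. Requires at least two points and a positive mean.
    """
    values = seq.values if isinstance(seq, VitalSequence) else np.asarray(seq, dtype=float)
    if values.size < 2:
        raise ValueError(f"need at least 2 points to compute a CV, got {values.size}")
    mean = values.mean()
    if mean <= 0:
        raise ValueError(f"sequence mean must be positive, got {mean}")
    return float(values.std(ddof=0) / mean)


def compute_cv_matrix(sequences: list[VitalSequence], *, window_s: float = 300.0,
                      min_points: int = 54, on_incomplete: str = "exclude",
                      channels: tuple[str, ...] = CHANNELS,
                      ) -> tuple[CVMatrix, list[tuple[str, str]]]:
    """Per-patient, per-channel CVs over the +/- ``window_s`` window.

    A patient enters the matrix only with all ``channels`` present and each
    channel contributing at least ``min_points`` in-window measurements
    (default 54 = 90% of the nominal 60); otherwise the patient is excluded
    and reported (``on_incomplete="exclude"``) or the run aborts
    (``"fatal"``). No interpolation is attempted. Returns the matrix and the
    ``(patient_id, reason)`` exclusion list.
    """
    if on_incomplete not in ("exclude", "fatal"):
        raise ValueError(f"on_incomplete must be 'exclude' or 'fatal', got {on_incomplete!r}")
    by_patient: dict[str, dict[str, VitalSequence]] = {}
    for seq in sequences:
        by_patient.setdefault(seq.patient_id, {})[seq.channel] = seq.restrict(window_s)

    rows, ids, excluded = [], [], []
    for pid, chans in by_patient.items():
        reason = None
        missing = [c for c in channels if c not in chans]
        if missing:
            reason = f"missing channel(s) {missing}"
        else:
            short = [c for c in channels if len(chans[c]) < min_points]
            if short:
                reason = (f"channel(s) {short} have fewer than {min_points} "
                          f"in-window points")
        if reason is not None:
            if on_incomplete == "fatal":
                raise ValueError(f"patient {pid}: {reason}")
            excluded.append((pid, reason))
            continue
        rows.append([compute_cv(chans[c]) for c in channels])
        ids.append(pid)
    if not rows:
        raise ValueError("no patient passed the completeness policy")
    return CVMatrix(np.array(rows), ids, tuple(channels)), excluded


def entropy_weights(cv: CVMatrix) -> WeightVector:
    """Entropy-based channel weights from the CV matrix.

    Each channel's CVs are turned into a share distribution across the N
    patients; its raw weight is one minus the normalised entropy of that
    distribution (0 ln 0 := 0), so identical shares give weight exactly 0.
    An all-zero channel carries no information and also gets raw weight 0
    (with a warning); if every channel is all-zero the index is undefined.
    """
    y = cv.values
    n = y.shape[0]
    if n < 2:
        raise ValueError("entropy weights need at least 2 patients")
    col_sums = y.sum(axis=0)
    if np.all(col_sums == 0):
        raise ValueError("all channels have zero CV everywhere; index undefined")
    raw = np.zeros(y.shape[1])
    for s, total in enumerate(col_sums):
        if total == 0:
            warnings.warn(f"channel {cv.channels[s]} has all-zero CVs; weight set to 0")
            continue
        p = y[:, s] / total
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        raw[s] = 1.0 + plogp.sum() / np.log(n)
    normalized = raw / raw.sum()
    return WeightVector(raw=raw, normalized=normalized, channels=cv.channels)


def integrate_icv(cv: CVMatrix, weights: WeightVector) -> np.ndarray:
    """Raw index per patient: weighted average of the channel CVs.

    With normalised weights this is a convex combination, so each z_i lies
    between that patient's smallest and largest channel CV.
    """
    w = np.asarray(weights.normalized, dtype=float)
    if w.shape != (cv.values.shape[1],):
        raise ValueError(f"weight length {w.shape} does not match {cv.values.shape[1]} channels")
    return cv.values @ w


def fit_bounds(raw_icvs) -> NormalizationBounds:
    """Min/max of the supplied raw index values (>= 2 distinct required)."""
    arr = np.asarray(raw_icvs, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if not hi > lo:
        raise ValueError("all raw ICV values identical; normalization degenerate")
    return NormalizationBounds(lo, hi)


def normalize_icv(raw, bounds: NormalizationBounds):
    """Min-max normalise; out-of-bounds inputs (new patients beyond the
    training range) are clipped into [0, 1] with a warning."""
    raw = np.asarray(raw, dtype=float)
    span = bounds.icv_max - bounds.icv_min
    norm = (raw - bounds.icv_min) / span
    n_clip = int(np.sum((norm < 0) | (norm > 1)))
    if n_clip:
        warnings.warn(f"{n_clip} value(s) outside the normalization bounds were clipped")
        norm = np.clip(norm, 0.0, 1.0)
    return float(norm) if norm.ndim == 0 else norm


def assign_class(norm_icv):
    """Five-level instability class of the normalised index.

    Bins are [0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8) and [0.8,1.0]; the
    last bin is closed so 1.0 is class 5. Inputs outside [0,1] are invalid.
    """
    norm = np.asarray(norm_icv, dtype=float)
    if np.any((norm < 0) | (norm > 1)):
        raise ValueError("normalized ICV must lie in [0, 1]")
    cls = np.digitize(norm, CLASS_EDGES[1:-1]) + 1  # right-open bins, [0.8, 1.0] closed
    return int(cls) if cls.ndim == 0 else cls


def assign_binary(norm_icv, threshold: float = STABLE_THRESHOLD):
    """Dichotomise: 'stable' below the threshold, 'instable' at or above."""
    norm = np.asarray(norm_icv, dtype=float)
    if np.any((norm < 0) | (norm > 1)):
        raise ValueError("normalized ICV must lie in [0, 1]")
    label = np.where(norm < threshold, "stable", "instable")
    return str(label) if label.ndim == 0 else label


def icv_table(sequences: list[VitalSequence], *, window_s: float = 300.0,
              min_points: int = 54, bounds: NormalizationBounds | None = None,
              ) -> tuple[pd.DataFrame, WeightVector, NormalizationBounds]:
    """Full index pipeline: sequences -> per-patient CVs, entropy weights,
    raw and normalised index, class and binary label.

    When ``bounds`` is None they are fit on this cohort; pass stored bounds
    to score held-out patients on the training scale. Returns the per-patient
    table (indexed by patient_id, columns cv_sp/cv_dp/cv_hr/raw_icv/
    norm_icv/icv_class/binary_label), the weights, and the bounds used.
    """
    cv, _ = compute_cv_matrix(sequences, window_s=window_s, min_points=min_points)
    weights = entropy_weights(cv)
    raw = integrate_icv(cv, weights)
    if bounds is None:
        bounds = fit_bounds(raw)
    norm = normalize_icv(raw, bounds)
    table = pd.DataFrame({
        **{f"cv_{c.lower()}": cv.values[:, s] for s, c in enumerate(cv.channels)},
        "raw_icv": raw,
        "norm_icv": norm,
        "icv_class": assign_class(norm),
        "binary_label": assign_binary(norm),
    }, index=pd.Index(cv.patient_ids, name="patient_id"))
    return table, weights, bounds
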