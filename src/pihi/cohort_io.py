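"""Cohort tables, vital-sign sequences and the model feature table.

The analysis consumes two plain-text inputs:

``cohort.csv``
    one row per patient: demographics (age, sex, height, weight, BMI,
    hypertension), preoperative systolic/diastolic pressure and heart rate,
    and the absolute induction doses (mg) of fentanyl, lidocaine, propofol
    and rocuronium.

``sequences.csv``
    long format, one row per measurement: patient_id, time_s (signed seconds
    relative to intubation, 0 = intubation), channel in {SP, DP, HR}, value.

Doses enter the models on the per-kilogram scale (mg/kg); fentanyl is
conventionally quoted in µg/kg at presentation but stored in mg here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_ORDER",
    "CHANNELS",
    "COHORT_COLUMNS",
    "DEFAULT_DOSE_BOUNDS",
    "PatientRecord",
    "DrugDoses",
    "VitalSequence",
    "Cohort",
    "convert_dose",
    "read_cohort",
    "write_cohort",
    "read_sequences",
    "write_sequences",
    "build_feature_table",
]

#: The 13 model input features, in the fixed column order used everywhere.
FEATURE_ORDER = [
    "sex",
    "age",
    "height",
    "weight",
    "bmi",
    "hypertension",
    "pre_sp",
    "pre_dp",
    "pre_hr",
    "fentanyl_per_kg",
    "lidocaine_per_kg",
    "propofol_per_kg",
    "rocuronium_per_kg",
]

CHANNELS = ("SP", "DP", "HR")

DRUGS = ("fentanyl", "lidocaine", "propofol", "rocuronium")

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "height_cm",
    "weight_kg",
    "bmi",
    "hypertension",
    "pre_sp",
    "pre_dp",
    "pre_hr",
    "fentanyl_mg",
    "lidocaine_mg",
    "propofol_mg",
    "rocuronium_mg",
]

#: Default validation bounds for absolute doses (mg); override per dataset.
DEFAULT_DOSE_BOUNDS = {
    "fentanyl": (0.050, 0.500),
    "lidocaine": (0.0, 100.0),
    "propofol": (50.0, 250.0),
    "rocuronium": (20.0, 100.0),
}


def convert_dose(dose_mg: float, weight_kg: float) -> float:
    """Weight-normalised dose: administered amount (mg) per kg body weight.

    Raises ``ValueError`` for non-positive weight or negative dose.
    """
    if weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    if dose_mg < 0:
        raise ValueError(f"dose must be non-negative, got {dose_mg}")
    return dose_mg / weight_kg


@dataclass(frozen=True)
class PatientRecord:
    """Preoperative patient information: the nine non-dose model features."""

    patient_id: str
    age: int          # years, >= 18 (adult cohort)
    sex: int          # 0 = female, 1 = male
    height: float     # cm
    weight: float     # kg
    bmi: float        # kg/m^2
    hypertension: int  # 0/1
    pre_sp: float     # mmHg, first stable preoperative systolic pressure
    pre_dp: float     # mmHg, diastolic
    pre_hr: float     # beats per minute

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems = []
        if self.age < 18:
            problems.append(f"age {self.age} < 18")
        if self.sex not in (0, 1):
            problems.append(f"sex {self.sex} not in {{0,1}}")
        if self.hypertension not in (0, 1):
            problems.append(f"hypertension {self.hypertension} not in {{0,1}}")
        if self.height <= 0 or self.weight <= 0:
            problems.append("non-positive height/weight")
        if self.pre_sp <= self.pre_dp:
            problems.append(f"pre_sp {self.pre_sp} <= pre_dp {self.pre_dp}")
        if self.pre_sp <= 0 or self.pre_dp <= 0 or self.pre_hr <= 0:
            problems.append("non-positive vital sign")
        if self.height > 0 and self.weight > 0 and self.bmi > 0:
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(self.bmi - implied) > 0.05 * implied:
                problems.append(
                    f"bmi {self.bmi:.2f} inconsistent with weight/height^2 {implied:.2f}"
                )
        elif self.bmi <= 0:
            problems.append("non-positive bmi")
        return problems


@dataclass(frozen=True)
class DrugDoses:
    """Induction doses of the four drugs, absolute (mg) and per-kg (mg/kg)."""

    patient_id: str
    fentanyl_mg: float
    lidocaine_mg: float
    propofol_mg: float
    rocuronium_mg: float
    fentanyl_per_kg: float
    lidocaine_per_kg: float
    propofol_per_kg: float
    rocuronium_per_kg: float

    @classmethod
    def from_absolute(cls, patient_id: str, weight_kg: float, **doses_mg: float) -> "DrugDoses":
        """Build from absolute doses, deriving per-kg via :func:`convert_dose`."""
        per_kg = {f"{d}_per_kg": convert_dose(doses_mg[f"{d}_mg"], weight_kg) for d in DRUGS}
        return cls(patient_id=patient_id, **doses_mg, **per_kg)

    def validate(self, weight_kg: float | None = None,
                 bounds: dict[str, tuple[float, float]] | None = None) -> list[str]:
        bounds = DEFAULT_DOSE_BOUNDS if bounds is None else bounds
        problems = []
        for drug in DRUGS:
            mg = getattr(self, f"{drug}_mg")
            per_kg = getattr(self, f"{drug}_per_kg")
            if mg < 0 or per_kg < 0:
                problems.append(f"negative {drug} dose")
            lo, hi = bounds.get(drug, (0.0, math.inf))
            if not lo <= mg <= hi:
                problems.append(f"{drug} {mg} mg outside [{lo}, {hi}]")
            if weight_kg is not None and weight_kg > 0:
                if abs(per_kg - mg / weight_kg) > 1e-9:
                    problems.append(f"{drug} per-kg inconsistent with mg/weight")
        return problems


@dataclass
class VitalSequence:
    """One channel's peri-intubation measurement series for one patient.

    Times are seconds relative to intubation and strictly increasing;
    nominal cadence is 10 s over a [-300 s, +300 s] window (60 points when
    complete). Values are mmHg for SP/DP and BPM for HR, all positive.
    """

    patient_id: str
    channel: str
    times: np.ndarray
    values: np.ndarray
    complete: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("physiological values must be positive")

    def __len__(self) -> int:
        return len(self.times)

    def restrict(self, window_s: float) -> "VitalSequence":
        """Sub-sequence with |t| <= window_s (completeness flag preserved)."""
        mask = np.abs(self.times) <= window_s
        return replace(self, times=self.times[mask], values=self.values[mask])


@dataclass
class Cohort:
    """Validated patient records and doses, plus the row-rejection log."""

    records: list[PatientRecord]
    doses: list[DrugDoses]
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (patient_id, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")


def read_cohort(path, *, on_invalid: str = "drop_row",
                dose_bounds: dict[str, tuple[float, float]] | None = None) -> Cohort:
    """Read and validate ``cohort.csv``.

    Parameters
    ----------
    path
        CSV with the :data:`COHORT_COLUMNS` header. The ``bmi`` column may be
        absent, in which case BMI is imputed as weight/(height/100)^2; a
        provided ``bmi`` is never overwritten.
    on_invalid
        ``"drop_row"`` (default) drops rows violating any invariant and logs
        them in ``Cohort.rejected``; ``"fatal"`` raises on the first bad row.
    dose_bounds
        Per-drug absolute-dose validation ranges (mg); defaults to
        :data:`DEFAULT_DOSE_BOUNDS`.
    """
    if on_invalid not in ("drop_row", "fatal"):
        raise ValueError(f"on_invalid must be 'drop_row' or 'fatal', got {on_invalid!r}")
    df = pd.read_csv(path)
    mandatory = [c for c in COHORT_COLUMNS if c != "bmi"]
    _require_columns(df, mandatory, path)
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"{path}: duplicate patient_id(s) {dupes}")

    cohort = Cohort(records=[], doses=[])
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        reason = None
        if row[mandatory].isna().any():
            reason = "missing value in mandatory column"
        else:
            try:
                if "bmi" in df.columns and not pd.isna(row["bmi"]):
                    bmi = float(row["bmi"])
                else:
                    bmi = float(row["weight_kg"]) / (float(row["height_cm"]) / 100.0) ** 2
                record = PatientRecord(
                    patient_id=pid, age=int(row["age"]), sex=int(row["sex"]),
                    height=float(row["height_cm"]), weight=float(row["weight_kg"]),
                    bmi=bmi, hypertension=int(row["hypertension"]),
                    pre_sp=float(row["pre_sp"]), pre_dp=float(row["pre_dp"]),
                    pre_hr=float(row["pre_hr"]),
                )
                doses = DrugDoses.from_absolute(
                    pid, record.weight,
                    **{f"{d}_mg": float(row[f"{d}_mg"]) for d in DRUGS},
                )
                problems = record.validate() + doses.validate(record.weight, dose_bounds)
                reason = "; ".join(problems) if problems else None
            except (ValueError, TypeError) as exc:
                reason = str(exc)
        if reason is None:
            cohort.records.append(record)
            cohort.doses.append(doses)
        elif on_invalid == "fatal":
            raise ValueError(f"{path}: patient {pid}: {reason}")
        else:
            cohort.rejected.append((pid, reason))
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to the ``cohort.csv`` schema (full precision)."""
    rows = []
    for rec, dose in zip(cohort.records, cohort.doses):
        rows.append({
            "patient_id": rec.patient_id, "age": rec.age, "sex": rec.sex,
            "height_cm": rec.height, "weight_kg": rec.weight, "bmi": rec.bmi,
            "hypertension": rec.hypertension, "pre_sp": rec.pre_sp,
            "pre_dp": rec.pre_dp, "pre_hr": rec.pre_hr,
            **{f"{d}_mg": getattr(dose, f"{d}_mg") for d in DRUGS},
        })
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_sequences(path, *, expected_points: int = 60) -> list[VitalSequence]:
    """Read ``sequences.csv`` into one :class:`VitalSequence` per (patient, channel).

    Times are sorted ascending; sequences with fewer than ``expected_points``
    measurements are flagged ``complete=False`` (policy for incomplete
    sequences lives in the index computation, not here). Unknown channel
    labels and duplicate (patient, channel, time) triples are fatal.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["patient_id", "time_s", "channel", "value"], path)
    unknown = set(df["channel"].unique()) - set(CHANNELS)
    if unknown:
        raise ValueError(f"{path}: unknown channel label(s) {sorted(unknown)}")
    if df.duplicated(subset=["patient_id", "channel", "time_s"]).any():
        raise ValueError(f"{path}: duplicate (patient_id, channel, time_s) rows")
    sequences = []
    for (pid, channel), group in df.groupby(["patient_id", "channel"], sort=True):
        group = group.sort_values("time_s")
        sequences.append(VitalSequence(
            patient_id=str(pid), channel=str(channel),
            times=group["time_s"].to_numpy(dtype=float),
            values=group["value"].to_numpy(dtype=float),
            complete=len(group) >= expected_points,
        ))
    return sequences


def write_sequences(sequences: list[VitalSequence], path) -> None:
    frames = [
        pd.DataFrame({"patient_id": s.patient_id, "time_s": s.times,
                      "channel": s.channel, "value": s.values})
        for s in sequences
    ]
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format="%.17g")


def build_feature_table(records: list[PatientRecord], doses: list[DrugDoses],
                        targets: dict[str, float] | None = None) -> tuple[pd.DataFrame, int]:
    """Assemble the N x 13 model feature table.

    Returns ``(table, n_excluded)`` where the table is indexed by patient_id
    with columns in :data:`FEATURE_ORDER` (plus ``icv`` when ``targets`` is
    given) and ``n_excluded`` counts rows dropped for missing features or a
    missing target. Duplicate patient ids and records without matching doses
    are fatal.
    """
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient_id in records")
    dose_map = {d.patient_id: d for d in doses}
    missing_doses = [pid for pid in ids if pid not in dose_map]
    if missing_doses:
        raise ValueError(f"records without matching doses: {missing_doses}")

    rows, n_excluded = [], 0
    for rec in records:
        dose = dose_map[rec.patient_id]
        row = {
            "patient_id": rec.patient_id,
            "sex": rec.sex, "age": rec.age, "height": rec.height,
            "weight": rec.weight, "bmi": rec.bmi, "hypertension": rec.hypertension,
            "pre_sp": rec.pre_sp, "pre_dp": rec.pre_dp, "pre_hr": rec.pre_hr,
            **{f"{d}_per_kg": getattr(dose, f"{d}_per_kg") for d in DRUGS},
        }
        if targets is not None:
            if rec.patient_id not in targets or pd.isna(targets[rec.patient_id]):
                n_excluded += 1
                continue
            row["icv"] = float(targets[rec.patient_id])
        if any(pd.isna(v) for v in row.values()):
            n_excluded += 1
            continue
        rows.append(row)
    columns = FEATURE_ORDER + (["icv"] if targets is not None else [])
    table = pd.DataFrame(rows).set_index("patient_id")[columns] if rows else \
        pd.DataFrame(columns=columns)
    return table, n_excluded
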