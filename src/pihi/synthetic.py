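"""Synthetic peri-intubation cohorts with a known ground-truth instability.

The generator emulates the statistical shape of an adult (ASA 1-2) surgical
cohort: covariate marginals follow published training-set moments
(age 49.98 +/- 13.88 y, height 164.2 +/- 6.7 cm, weight 64.5 +/- 11.3 kg,
~70% female, ~17% hypertensive, preoperative SP/DP/HR around 133.6/78.4/79.1),
induction doses are truncated around the published per-kg medians within the
published converted ranges, and each patient gets three vital-sign sequences
(SP, DP, HR) at 10-s cadence over a +/- 5-min window around intubation.

A latent instability lambda in [0, 1] — a logistic squash of a linear
combination of standardized covariates and doses (weight concentrated on
age and the preoperative hemodynamics), an age x SP interaction, and
Gaussian noise — drives a post-intubation excursion: an instantaneous rise
at intubation with exponential decay whose relative amplitude scales with
lambda. lambda is ground truth for validating index recovery and the
prediction stages; it is stored separately and never enters model features.

Two joint dependencies beyond the marginals are deliberate: height-weight
correlation (rho = 0.6) so the derived BMI reproduces the published BMI
moments, and SP-DP correlation (rho = 0.6) so enforcing SP > DP requires
only rare redraws and leaves the marginal means unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import optimize, stats

from .cohort_io import (DRUGS, Cohort, DrugDoses, PatientRecord, VitalSequence,
                        write_cohort, write_sequences)

__all__ = [
    "CovariateParams",
    "DoseParams",
    "TruthParams",
    "SequenceParams",
    "SimConfig",
    "SimCohort",
    "sample_covariates",
    "sample_doses",
    "latent_instability",
    "simulate_sequences",
    "generate_cohort",
]


def _truncnorm_mean_matched(target_mean: float, sd: float, low: float, high: float):
    """Truncated normal whose *truncated* mean equals ``target_mean``.

    A plain ``truncnorm(loc=target)`` is biased when the bounds are
    asymmetric about the target; here the location is solved so the
    truncation-corrected mean hits the target exactly.
    """
    if sd == 0:
        loc = min(max(target_mean, low), high)
        return stats.truncnorm((low - loc), (high - loc), loc=loc, scale=1e-12)

    def truncated_mean(loc):
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    span = max(high - low, 10 * sd)
    loc = optimize.brentq(truncated_mean, low - span, high + span, xtol=1e-12)
    return stats.truncnorm((low - loc) / sd, (high - loc) / sd, loc=loc, scale=sd)


@dataclass
class CovariateParams:
    """Marginal targets for the preoperative covariates (training-set moments)."""

    age_mean: float = 49.98
    age_sd: float = 13.88
    age_range: tuple[float, float] = (18.0, 91.0)
    height_mean: float = 164.20          # cm
    height_sd: float = 6.72
    height_range: tuple[float, float] = (130.0, 200.0)
    weight_mean: float = 64.51           # kg
    weight_sd: float = 11.32
    weight_range: tuple[float, float] = (30.0, 140.0)
    height_weight_rho: float = 0.6       # makes derived BMI ~ 23.84 (3.38)
    female_prop: float = 0.6983
    hypertension_prop: float = 0.1701
    pre_sp_mean: float = 133.55          # mmHg, mixture mean over hypertension
    pre_sp_sd: float = 20.41             # mixture SD
    pre_sp_range: tuple[float, float] = (75.0, 230.0)
    hypertension_sp_shift: float = 12.0  # mmHg added to the hypertensive mean
    pre_dp_mean: float = 78.42
    pre_dp_sd: float = 12.12
    pre_dp_range: tuple[float, float] = (40.0, 135.0)
    sp_dp_rho: float = 0.6
    sp_dp_min_gap: float = 5.0           # redraw pairs with SP - DP below this
    pre_hr_mean: float = 79.06
    pre_hr_sd: float = 13.08
    pre_hr_range: tuple[float, float] = (35.0, 160.0)


@dataclass
class DoseParams:
    """Per-kg dose centers (published medians), dispersions and ranges."""

    center: dict = field(default_factory=lambda: {
        "fentanyl": 1.667e-3, "lidocaine": 0.606, "propofol": 2.174, "rocuronium": 0.714})
    sd: dict = field(default_factory=lambda: {
        "fentanyl": 0.53e-3, "lidocaine": 0.248, "propofol": 0.45, "rocuronium": 0.113})
    per_kg_range: dict = field(default_factory=lambda: {
        "fentanyl": (0.455e-3, 5.882e-3), "lidocaine": (0.0, 2.222),
        "propofol": (0.521, 4.902), "rocuronium": (0.190, 2.174)})
    # absolute (mg) ranges; sampling respects them jointly with the per-kg
    # range so generated cohorts pass default dose validation
    absolute_range: dict = field(default_factory=lambda: {
        "fentanyl": (0.050, 0.500), "lidocaine": (0.0, 100.0),
        "propofol": (50.0, 250.0), "rocuronium": (20.0, 100.0)})


@dataclass
class TruthParams:
    """Latent-instability function: lambda = logistic(eta), eta linear in
    standardized features + interaction + noise."""

    coefficients: dict = field(default_factory=lambda: {
        "age": 0.28, "pre_sp": 0.22, "pre_dp": 0.16, "pre_hr": 0.16,
        "propofol_per_kg": 0.08, "fentanyl_per_kg": 0.06,
        "rocuronium_per_kg": 0.05, "lidocaine_per_kg": 0.03,
        "bmi": 0.05, "hypertension": 0.06, "sex": -0.04,
        "height": 0.02, "weight": 0.02,
    })
    interaction: float = 0.60   # on z_age * z_pre_sp (zero-mean, purely nonlinear)
    # Hermite-type curvature (z^2 - 1)/sqrt(2) per feature: instability is
    # worst at the extremes of heart rate / age, not just at one end
    curvature: dict = field(default_factory=lambda: {"pre_hr": 0.35, "age": 0.25})
    intercept: float = -0.50
    noise: float = 0.20         # SD of Gaussian noise added to eta


@dataclass
class SequenceParams:
    """Vital-sign sequence kinetics (stipulated, not fitted to any dataset)."""

    ar_phi: float = 0.7         # AR(1) autocorrelation of baseline fluctuation
    ar_sigma: float = 0.012     # stationary relative SD of the fluctuation
    pulse_tau_s: float = 90.0   # decay time constant of the excursion
    pulse_amp: dict = field(default_factory=lambda: {"SP": 0.60, "DP": 0.60, "HR": 0.50})
    floor: float = 30.0         # physiological minimum for any measurement


@dataclass
class SimConfig:
    n_patients: int = 100
    seed: int = 0
    cadence_s: float = 10.0
    window_s: float = 300.0
    covariates: CovariateParams = field(default_factory=CovariateParams)
    doses: DoseParams = field(default_factory=DoseParams)
    truth: TruthParams = field(default_factory=TruthParams)
    sequences: SequenceParams = field(default_factory=SequenceParams)

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.cadence_s <= 0 or self.window_s <= 0:
            raise ValueError("cadence and window must be positive")
        if self.truth.noise < 0:
            raise ValueError("noise scale must be non-negative")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sections = {"covariates": CovariateParams, "doses": DoseParams,
                    "truth": TruthParams, "sequences": SequenceParams}

        def untuple(key, value):
            # YAML has no tuples; restore them for range-like fields
            if key.endswith("range"):
                if isinstance(value, list):
                    return tuple(value)
                if isinstance(value, dict):
                    return {k: tuple(v) for k, v in value.items()}
            return value

        kwargs = {}
        for key, value in raw.items():
            if key in sections:
                kwargs[key] = sections[key](
                    **{k: untuple(k, v) for k, v in value.items()})
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class SimCohort:
    """Generated cohort plus the ground truth used only for validation."""

    records: list[PatientRecord]
    doses: list[DrugDoses]
    sequences: list[VitalSequence]
    true_lambda: np.ndarray
    config: SimConfig

    def cohort(self) -> Cohort:
        return Cohort(records=self.records, doses=self.doses)


def _bivariate_truncated(rng, n, mean1, sd1, range1, mean2, sd2, range2, rho,
                         extra_ok=None):
    """Correlated normal pair with per-coordinate range truncation by redraw.

    ``extra_ok(x1, x2)`` can impose a joint constraint (also by redraw);
    all constraints are chosen rare enough that redraws leave the means
    essentially unbiased.
    """
    x1 = np.empty(n)
    x2 = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        z1 = rng.standard_normal(todo.size)
        z2 = rho * z1 + np.sqrt(1 - rho ** 2) * rng.standard_normal(todo.size)
        c1 = mean1 + sd1 * z1
        c2 = mean2 + sd2 * z2
        ok = ((c1 >= range1[0]) & (c1 <= range1[1]) &
              (c2 >= range2[0]) & (c2 <= range2[1]))
        if extra_ok is not None:
            ok &= extra_ok(c1, c2)
        x1[todo[ok]] = c1[ok]
        x2[todo[ok]] = c2[ok]
        todo = todo[~ok]
    return x1, x2


def sample_covariates(config: SimConfig) -> list[PatientRecord]:
    """Draw patient records matching the configured covariate marginals."""
    p = config.covariates
    n = config.n_patients
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    age = _truncnorm_mean_matched(p.age_mean, p.age_sd, *p.age_range)\
        .rvs(n, random_state=rng)
    age = np.clip(np.rint(age), np.ceil(p.age_range[0]), np.floor(p.age_range[1]))
    sex = (rng.random(n) >= p.female_prop).astype(int)  # 1 = male
    hypertension = (rng.random(n) < p.hypertension_prop).astype(int)

    height, weight = _bivariate_truncated(
        rng, n, p.height_mean, p.height_sd, p.height_range,
        p.weight_mean, p.weight_sd, p.weight_range, p.height_weight_rho)
    bmi = weight / (height / 100.0) ** 2

    # hypertensive patients run higher systolic; base mean set so the
    # mixture mean equals the configured target, component SD deflated so
    # the mixture SD matches too
    p_ht = p.hypertension_prop
    sp_base = p.pre_sp_mean - p_ht * p.hypertension_sp_shift
    sp_var = p.pre_sp_sd ** 2 - p_ht * (1 - p_ht) * p.hypertension_sp_shift ** 2
    sp_sd = np.sqrt(max(sp_var, 1e-12))
    sp_means = sp_base + p.hypertension_sp_shift * hypertension
    pre_sp = np.empty(n)
    pre_dp = np.empty(n)
    for group in (0, 1):
        idx = np.where(hypertension == group)[0]
        if idx.size == 0:
            continue
        sp, dp = _bivariate_truncated(
            rng, idx.size,
            sp_means[idx[0]], sp_sd, p.pre_sp_range,
            p.pre_dp_mean, p.pre_dp_sd, p.pre_dp_range, p.sp_dp_rho,
            extra_ok=lambda s, d: s - d >= p.sp_dp_min_gap)
        pre_sp[idx] = sp
        pre_dp[idx] = dp
    pre_hr = _truncnorm_mean_matched(p.pre_hr_mean, p.pre_hr_sd, *p.pre_hr_range)\
        .rvs(n, random_state=rng)

    width = len(str(n))
    return [
        PatientRecord(
            patient_id=f"P{i:0{width}d}", age=int(age[i]), sex=int(sex[i]),
            height=float(height[i]), weight=float(weight[i]), bmi=float(bmi[i]),
            hypertension=int(hypertension[i]), pre_sp=float(pre_sp[i]),
            pre_dp=float(pre_dp[i]), pre_hr=float(pre_hr[i]))
        for i in range(n)
    ]


def sample_doses(records: list[PatientRecord], config: SimConfig) -> list[DrugDoses]:
    """Draw per-kg doses (truncated around the configured centers) and derive
    absolute doses from each patient's weight.

    The effective per-kg bounds for a patient combine the converted range
    with the absolute range divided by that patient's weight, so generated
    doses always pass default dose validation.
    """
    d = config.doses
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    weights = np.array([rec.weight for rec in records])
    per_kg = {}
    for drug in DRUGS:
        # location solved once against the global per-kg range; the
        # weight-dependent bound tightens it only for extreme weights
        base = _truncnorm_mean_matched(d.center[drug], d.sd[drug],
                                       *d.per_kg_range[drug])
        loc, sd = base.kwds["loc"], base.kwds["scale"]
        lo = np.maximum(d.per_kg_range[drug][0], d.absolute_range[drug][0] / weights)
        hi = np.minimum(d.per_kg_range[drug][1], d.absolute_range[drug][1] / weights)
        if np.any(hi <= lo):
            bad = weights[hi <= lo]
            raise ValueError(f"empty dose range for {drug} at weight(s) {bad}")
        per_kg[drug] = stats.truncnorm.rvs((lo - loc) / sd, (hi - loc) / sd,
                                           loc=loc, scale=sd, size=len(records),
                                           random_state=rng)
    return [
        DrugDoses.from_absolute(
            rec.patient_id, rec.weight,
            **{f"{drug}_mg": float(per_kg[drug][i] * rec.weight) for drug in DRUGS})
        for i, rec in enumerate(records)
    ]


def _standardized_features(records, doses, config) -> dict[str, np.ndarray]:
    """Features standardized against the generator's own population targets
    (not the sample), so the truth function is deterministic in the config."""
    p = config.covariates
    d = config.doses
    out = {}
    cont = {
        "age": (p.age_mean, p.age_sd), "height": (p.height_mean, p.height_sd),
        "weight": (p.weight_mean, p.weight_sd),
        "pre_sp": (p.pre_sp_mean, p.pre_sp_sd), "pre_dp": (p.pre_dp_mean, p.pre_dp_sd),
        "pre_hr": (p.pre_hr_mean, p.pre_hr_sd),
    }
    for name, (mu, sd) in cont.items():
        x = np.array([getattr(r, name) for r in records], dtype=float)
        out[name] = (x - mu) / sd
    bmi_mu = p.weight_mean / (p.height_mean / 100.0) ** 2
    out["bmi"] = (np.array([r.bmi for r in records]) - bmi_mu) / 3.38
    for name, prop in (("sex", 1 - p.female_prop), ("hypertension", p.hypertension_prop)):
        x = np.array([getattr(r, name) for r in records], dtype=float)
        out[name] = (x - prop) / np.sqrt(prop * (1 - prop))
    for drug in DRUGS:
        x = np.array([getattr(ds, f"{drug}_per_kg") for ds in doses])
        out[f"{drug}_per_kg"] = (x - d.center[drug]) / d.sd[drug]
    return out


def latent_instability(records: list[PatientRecord], doses: list[DrugDoses],
                       config: SimConfig) -> np.ndarray:
    """Ground-truth instability lambda in [0, 1] for each patient."""
    t = config.truth
    z = _standardized_features(records, doses, config)
    eta = np.full(len(records), t.intercept, dtype=float)
    for name, coef in t.coefficients.items():
        eta += coef * z[name]
    eta += t.interaction * z["age"] * z["pre_sp"]
    for name, coef in t.curvature.items():
        eta += coef * (z[name] ** 2 - 1.0) / np.sqrt(2.0)
    if t.noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
        eta += t.noise * rng.standard_normal(len(records))
    return 1.0 / (1.0 + np.exp(-eta))


def simulate_sequences(record: PatientRecord, lam: float, config: SimConfig,
                       rng: np.random.Generator) -> list[VitalSequence]:
    """Three peri-intubation sequences for one patient.

    Pre-intubation: AR(1) relative fluctuation around the preoperative
    baseline. Post-intubation: the same fluctuation plus an excursion that
    rises instantaneously at intubation and decays exponentially, with
    relative amplitude ``pulse_amp[channel] * lam``. With zero AR noise and
    lam = 0 the sequences are exactly constant at baseline.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    sp = config.sequences
    n_side = int(round(config.window_s / config.cadence_s))
    times = np.concatenate([
        -config.cadence_s * np.arange(n_side, 0, -1),   # -window .. -cadence
        config.cadence_s * np.arange(1, n_side + 1),    # +cadence .. +window
    ])
    k = times.size
    baselines = {"SP": record.pre_sp, "DP": record.pre_dp, "HR": record.pre_hr}
    post = times > 0
    decay = np.zeros(k)
    decay[post] = np.exp(-(times[post] - times[post][0]) / sp.pulse_tau_s)

    out = []
    for channel in ("SP", "DP", "HR"):
        if sp.ar_sigma > 0:
            eps = rng.standard_normal(k)
            fluct = np.empty(k)
            fluct[0] = sp.ar_sigma * eps[0]
            innov_sd = sp.ar_sigma * np.sqrt(1 - sp.ar_phi ** 2)
            for t in range(1, k):
                fluct[t] = sp.ar_phi * fluct[t - 1] + innov_sd * eps[t]
        else:
            fluct = np.zeros(k)
        rel = 1.0 + fluct + sp.pulse_amp[channel] * lam * decay
        values = np.maximum(baselines[channel] * rel, sp.floor)
        out.append(VitalSequence(record.patient_id, channel, times.copy(), values))
    return out


def generate_cohort(config: SimConfig, outdir=None) -> SimCohort:
    """Compose covariates, doses, latent instability and sequences.

    With ``outdir`` set, writes ``cohort.csv`` and ``sequences.csv`` in the
    interchange schemas plus ``truth.csv`` (patient_id, lambda) — the truth
    file is separate from the model inputs by design. Identical configs
    (including seed) produce byte-identical files.
    """
    records = sample_covariates(config)
    doses = sample_doses(records, config)
    lam = latent_instability(records, doses, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    sequences = []
    for rec, lam_i in zip(records, lam):
        sequences.extend(simulate_sequences(rec, float(lam_i), config, rng))
    sim = SimCohort(records=records, doses=doses, sequences=sequences,
                    true_lambda=lam, config=config)
    if outdir is not None:
        import pathlib
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(sim.cohort(), outdir / "cohort.csv")
        write_sequences(sequences, outdir / "sequences.csv")
        import pandas as pd
        pd.DataFrame({"patient_id": [r.patient_id for r in records],
                      "lambda": lam}).to_csv(outdir / "truth.csv", index=False,
                                             float_format="%.17g")
    return sim
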