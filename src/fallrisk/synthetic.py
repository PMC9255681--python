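"""Synthetic primary-care EHR cohort generator.

Produces linked patient / medication / diagnosis / free-text-note tables with
the statistical structure the downstream analysis assumes, plus gold-standard
ground truth for every derived quantity (true fall dates, true predictor
vectors, per-note labels), so the whole pipeline is testable without access to
any real registry.

The generative model is the inverse of the final prediction model: a patient's
one-year fall probability is ``sigmoid(intercept + sum(coef * predictor))``
over 79 candidate predictors (age, sex, history of falls, 33 fall-risk-
increasing-drug groups, 43 chronic-condition groups), of which ten carry the
published non-zero coefficients and the rest are null. Marginal predictor
prevalences default to the published cohort rates where available. Age is
drawn as ``age_min + Gamma(shape, scale)`` tuned so the cohort median age is
about 72 years. Deaths, consultation gaps and look-back-only condition
histories are simulated at their published cohort fractions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

_DATA_DIR = Path(__file__).parent / "data"

# Cohort denominators and counts behind the default rates (published cohort).
_N_COHORT = 36_470
_N_DEATHS = 771
_N_LOOKBACK = 886
_N_NO_CONSULT = 1_389


class CohortConfigError(ValueError):
    """Raised when a cohort configuration field is invalid."""


@dataclass(frozen=True)
class PredictorSpec:
    """One candidate predictor: marginal prevalence and true log-odds coefficient."""

    name: str
    group: str  # "demographic" | "frid" | "condition"
    prevalence: float | None  # None for the continuous age column
    coefficient: float = 0.0


def _frid_specs() -> list[PredictorSpec]:
    prev = {
        # Table-1 cohort marginal rates (count / 36,470)
        "proton_pump_inhibitors": 14_578 / _N_COHORT,
        "opioids": 4_918 / _N_COHORT,
        "antihyperglycemic_drugs": 6_449 / _N_COHORT,
        "antidepressant_drugs": 2_778 / _N_COHORT,
        "antiepileptic_drugs": 1_397 / _N_COHORT,
        "antiparkinson_drugs": 515 / _N_COHORT,
        "urinary_incontinence_drugs": 1_021 / _N_COHORT,
        "nsaids": 5_068 / _N_COHORT,
        # remaining example groups: plausible primary-care dispensing rates
        "antipsychotics": 0.030,
        "anxiolytics": 0.045,
        "hypnotics_sedatives": 0.065,
        "thiazide_diuretics": 0.12,
        "loop_diuretics": 0.07,
        "potassium_sparing_diuretics": 0.02,
        "beta_blockers": 0.28,
        "calcium_channel_blockers": 0.16,
        "ace_inhibitors": 0.20,
        "angiotensin_ii_antagonists": 0.14,
        "nitrates": 0.04,
        "cardiac_glycosides": 0.02,
        "antiarrhythmics": 0.02,
        "alpha_blockers": 0.025,
        "statins": 0.35,
        "antithrombotics": 0.30,
        "antihistamines": 0.05,
        "antivertigo_drugs": 0.02,
        "muscle_relaxants": 0.02,
        "antimigraine_drugs": 0.02,
        "systemic_corticosteroids": 0.06,
        "bisphosphonates": 0.04,
        "glaucoma_eye_drops": 0.05,
        "laxatives": 0.09,
        "anticholinergic_inhalants": 0.05,
    }
    coef = {"proton_pump_inhibitors": 0.29, "opioids": 0.24}
    return [PredictorSpec(n, "frid", p, coef.get(n, 0.0)) for n, p in prev.items()]


def _condition_specs() -> list[PredictorSpec]:
    prev = {
        "anxiety_disorder": 1_104 / _N_COHORT,
        "dementia": 1_067 / _N_COHORT,
        "depression": 1_144 / _N_COHORT,
        "epilepsy": 366 / _N_COHORT,
        "parkinson_disease": 401 / _N_COHORT,
        "memory_concentration_problems": 2_626 / _N_COHORT,
        "vertigo_dizziness": 1_446 / _N_COHORT,
        "hypertension": 18_774 / _N_COHORT,
        "cardiac_arrhythmia": 6_750 / _N_COHORT,
        "coronary_heart_disease": 5_472 / _N_COHORT,
        "heart_failure": 1_862 / _N_COHORT,
        "orthostatic_hypotension": 226 / _N_COHORT,
        "stroke_tia": 2_287 / _N_COHORT,
        "diabetes": 8_183 / _N_COHORT,
        "kidney_disease": 1_270 / _N_COHORT,
        "hearing_disorder": 5_057 / _N_COHORT,
        "visual_disorder": 10_814 / _N_COHORT,
        "previous_injury": 3_269 / _N_COHORT,
        "back_neck_disorder": 3_510 / _N_COHORT,
        "osteoarthritis": 12_123 / _N_COHORT,
        "osteoporosis": 1_776 / _N_COHORT,
        "rheumatoid_arthritis": 821 / _N_COHORT,
        "vitamin_deficiency": 1_179 / _N_COHORT,
        "fatigue_weakness": 1_983 / _N_COHORT,
        "urinary_incontinence": 2_090 / _N_COHORT,
        "copd": 0.10,
        "asthma": 0.06,
        "pneumonia": 0.03,
        "malignancy": 0.08,
        "thyroid_disorder": 0.07,
        "obesity": 0.12,
        "anemia": 0.05,
        "sleep_disorder": 0.08,
        "substance_use_disorder": 0.02,
        "peripheral_neuropathy": 0.03,
        "migraine": 0.04,
        "peripheral_vascular_disease": 0.05,
        "venous_disease": 0.07,
        "gastrointestinal_disorder": 0.09,
        "liver_disorder": 0.02,
        "prostate_disorder": 0.10,
        "chronic_skin_ulcer": 0.02,
        "foot_problems": 0.05,
    }
    coef = {
        "previous_injury": 0.35,
        "depression": 0.54,
        "osteoarthritis": 0.20,
        "urinary_incontinence": 0.36,
        "memory_concentration_problems": 0.41,
    }
    return [PredictorSpec(n, "condition", p, coef.get(n, 0.0)) for n, p in prev.items()]


def default_predictor_spec() -> list[PredictorSpec]:
    """The 79 default candidate predictors.

    Ten carry the published non-zero coefficients (age 0.06/yr, female sex
    0.26, history of falls 0.72, proton pump inhibitors 0.29, opioids 0.24,
    previous injury 0.35, depression 0.54, osteoarthritis 0.20, urinary
    incontinence 0.36, memory/concentration problems 0.41); the other 69 are
    null. Order: age, female_sex, history_of_falls, FRID groups, condition
    groups.
    """
    demo = [
        PredictorSpec("age", "demographic", None, 0.06),
        PredictorSpec("female_sex", "demographic", 19_398 / _N_COHORT, 0.26),
        PredictorSpec("history_of_falls", "demographic", 4_751 / _N_COHORT, 0.72),
    ]
    return demo + _frid_specs() + _condition_specs()


TRUE_PREDICTORS = (
    "age",
    "female_sex",
    "history_of_falls",
    "proton_pump_inhibitors",
    "opioids",
    "previous_injury",
    "depression",
    "osteoarthritis",
    "urinary_incontinence",
    "memory_concentration_problems",
)


@dataclass(frozen=True)
class NoteNoise:
    """Per-patient probabilities of distractor notes, and mean unrelated notes."""

    negated: float = 0.05
    traffic: float = 0.02
    homonym: float = 0.02
    unrelated_mean: float = 1.0

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Windows are half-open ISO intervals adjacent at ``index_date``:
    observation ``[index - observation_days, index)`` for predictors,
    follow-up ``[index, index + followup_days)`` for the outcome.
    """

    n_patients: int
    index_date: date = date(2018, 12, 31)
    observation_days: int = 365
    followup_days: int = 365
    age_min: float = 65.0
    # (distribution name, *params); "gamma" draws age_min + Gamma(shape, scale),
    # tuned so the cohort median age is ~72; "constant" fixes age_min + offset.
    age_distribution: tuple = ("gamma", 2.0, 4.2)
    predictor_spec: list[PredictorSpec] = field(default_factory=default_predictor_spec)
    intercept: float = -6.92
    death_rate: float = _N_DEATHS / _N_COHORT
    no_consult_fraction: float = _N_NO_CONSULT / _N_COHORT
    lookback_fraction: float = _N_LOOKBACK / _N_COHORT
    lookback_years: int = 2
    note_noise: NoteNoise = field(default_factory=NoteNoise)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 0:
            raise CohortConfigError("n_patients: must be a non-negative integer")
        for fname in ("observation_days", "followup_days"):
            if getattr(self, fname) < 1:
                raise CohortConfigError(f"{fname}: must be >= 1 day")
        name = self.age_distribution[0]
        if name == "gamma":
            if len(self.age_distribution) != 3 or min(self.age_distribution[1:]) <= 0:
                raise CohortConfigError(
                    "age_distribution: gamma requires positive (shape, scale)"
                )
        elif name == "constant":
            if len(self.age_distribution) != 2 or self.age_distribution[1] < 0:
                raise CohortConfigError(
                    "age_distribution: constant requires a non-negative offset"
                )
        else:
            raise CohortConfigError(f"age_distribution: unknown distribution {name!r}")
        for fname in ("death_rate", "no_consult_fraction", "lookback_fraction"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise CohortConfigError(f"{fname}: must lie in [0, 1], got {v}")
        for spec in self.predictor_spec:
            if spec.prevalence is not None and not 0.0 <= spec.prevalence <= 1.0:
                raise CohortConfigError(
                    f"predictor_spec[{spec.name}]: prevalence must lie in [0, 1]"
                )
        for fname, v in self.note_noise.as_dict().items():
            if v < 0 or (fname != "unrelated_mean" and v > 1):
                raise CohortConfigError(f"note_noise.{fname}: invalid rate {v}")
        if self.lookback_years < 0:
            raise CohortConfigError("lookback_years: must be >= 0")

    @property
    def observation_window(self) -> tuple[date, date]:
        return (self.index_date - timedelta(days=self.observation_days), self.index_date)

    @property
    def followup_window(self) -> tuple[date, date]:
        return (self.index_date, self.index_date + timedelta(days=self.followup_days))

    @property
    def column_names(self) -> list[str]:
        return [s.name for s in self.predictor_spec]

    def rng(self, stage: int) -> np.random.Generator:
        # one documented fan-out rule: every stage draws from an independent
        # stream keyed by (seed, stage), so stages are individually reproducible
        return np.random.default_rng([int(self.seed), int(stage)])


@dataclass
class SyntheticCohort:
    """Linked synthetic tables plus hidden ground truth."""

    config: CohortConfig
    patients: pd.DataFrame  # patient_id, age_at_obs_start, sex, death_date
    medications: pd.DataFrame  # patient_id, atc, date
    diagnoses: pd.DataFrame  # patient_id, icpc, date
    notes: pd.DataFrame  # note_id, patient_id, date, text
    gold_notes: pd.DataFrame  # note_id, patient_id, gold_label
    truth: pd.DataFrame  # per patient: p_fall, fall, fall_date, ... + predictors


# ---------------------------------------------------------------------------
# covariates


def sample_covariates(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw patient demographics and the true 79-candidate predictor matrix.

    Binary predictors are independent Bernoulli draws at their configured
    marginal prevalences; age is continuous ``>= age_min``. Returns
    ``(patients, X)`` with ``X`` indexed by patient id in cohort order.
    """
    rng = config.rng(0)
    n = config.n_patients
    ids = [f"P{i:07d}" for i in range(n)]

    dist = config.age_distribution
    if dist[0] == "gamma":
        age = config.age_min + rng.gamma(dist[1], dist[2], size=n)
    else:  # constant
        age = np.full(n, config.age_min + dist[1])

    X = pd.DataFrame(index=pd.Index(ids, name="patient_id"))
    for spec in config.predictor_spec:
        if spec.prevalence is None:
            X[spec.name] = age
        else:
            X[spec.name] = (rng.random(n) < spec.prevalence).astype(np.int64)

    sex = np.where(X["female_sex"].to_numpy() == 1, "female", "male") \
        if "female_sex" in X else np.full(n, "female")
    patients = pd.DataFrame(
        {"patient_id": ids, "age_at_obs_start": age, "sex": sex}
    )
    return patients, X


def linear_predictor(X: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    """Intercept plus coefficient-weighted sum over the configured predictors."""
    lp = np.full(len(X), config.intercept, dtype=float)
    for spec in config.predictor_spec:
        if spec.coefficient != 0.0:
            lp += spec.coefficient * X[spec.name].to_numpy(dtype=float)
    return lp


def fall_probability(X: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    lp = linear_predictor(X, config)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-np.clip(lp, -700, 700)))


# ---------------------------------------------------------------------------
# outcomes


def simulate_outcomes(
    patients: pd.DataFrame, X: pd.DataFrame, config: CohortConfig
) -> pd.DataFrame:
    """Simulate falls, deaths and consultation gaps for the sampled cohort.

    The fall indicator is Bernoulli(sigmoid(LP)); fallers get a first-fall
    date uniform in the follow-up window. Deaths occur at ``death_rate`` with
    a uniform date strictly inside follow-up; a decedent who falls does so
    before death. ``no_consult`` patients generate no follow-up notes, so
    their falls cannot be ascertained from text.
    """
    rng = config.rng(1)
    n = len(X)
    fu_start, _ = config.followup_window
    p = fall_probability(X, config)
    fall = rng.random(n) < p

    died = rng.random(n) < config.death_rate
    # offsets in [1, followup_days - 1]: death strictly inside the half-open
    # follow-up window, with a positive observed fraction of the year
    death_off = rng.integers(1, max(config.followup_days - 1, 1) + 1, size=n)
    fall_off = rng.integers(0, config.followup_days, size=n)
    both = fall & died
    if both.any():
        # first fall uniform before death
        fall_off[both] = np.floor(
            rng.random(both.sum()) * death_off[both]
        ).astype(np.int64)

    no_consult = rng.random(n) < config.no_consult_fraction

    truth = pd.DataFrame(index=X.index)
    truth["p_fall"] = p
    truth["fall"] = fall.astype(np.int64)
    truth["fall_date"] = [
        (fu_start + timedelta(days=int(o))).isoformat() if f else ""
        for f, o in zip(fall, fall_off)
    ]
    truth["death_date"] = [
        (fu_start + timedelta(days=int(o))).isoformat() if d else ""
        for d, o in zip(died, death_off)
    ]
    truth["no_consult"] = no_consult.astype(np.int64)
    return truth


# ---------------------------------------------------------------------------
# coded event records


def load_templates(path: str | Path | None = None) -> dict[str, list[str]]:
    with open(path or _DATA_DIR / "note_templates.yml") as fh:
        templates = yaml.safe_load(fh)
    if not templates or not templates.get("fall"):
        raise CohortConfigError("note templates: 'fall' template list is empty")
    return templates


def _example_atc(prefix: str, rng: np.random.Generator) -> str:
    """Pad an ATC class prefix to a full 7-character code."""
    fill = "AB%02d" % rng.integers(1, 20)
    return (prefix + fill)[:7] if len(prefix) < 7 else prefix


def generate_records(
    X: pd.DataFrame,
    truth: pd.DataFrame,
    config: CohortConfig,
    frid_mapping: dict[str, list[str]] | None = None,
    condition_mapping: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Emit medication and diagnosis records realising the true indicators.

    Every active FRID indicator yields one dispense record with an ATC code
    from that group, dated in the observation window; every active condition
    yields one diagnosis record with an ICPC code from that group. Patients
    flagged for look-back have all their diagnosis records dated before the
    observation window instead (their conditions exist only in prior years).
    Returns (medications, diagnoses, lookback_flags).
    """
    from .features import default_frid_mapping, default_condition_mapping

    frid_mapping = frid_mapping or default_frid_mapping().groups
    condition_mapping = condition_mapping or default_condition_mapping().groups
    rng = config.rng(3)
    obs_start, obs_end = config.observation_window
    obs_days = config.observation_days
    lb_days = max(config.lookback_years * 365, 1)

    cond_cols = [s.name for s in config.predictor_spec if s.group == "condition"]
    has_condition = X[cond_cols].to_numpy().sum(axis=1) > 0 if cond_cols else np.zeros(len(X), bool)
    lookback = has_condition & (rng.random(len(X)) < config.lookback_fraction)

    meds, diags = [], []
    ids = X.index.to_numpy()
    for spec in config.predictor_spec:
        if spec.group == "frid":
            prefixes = frid_mapping[spec.name]
            for i in np.flatnonzero(X[spec.name].to_numpy() == 1):
                code = _example_atc(prefixes[rng.integers(len(prefixes))], rng)
                d = obs_start + timedelta(days=int(rng.integers(0, obs_days)))
                meds.append((ids[i], code, d.isoformat()))
        elif spec.group == "condition":
            codes = condition_mapping[spec.name]
            for i in np.flatnonzero(X[spec.name].to_numpy() == 1):
                code = codes[rng.integers(len(codes))]
                if lookback[i]:
                    d = obs_start - timedelta(days=int(rng.integers(1, lb_days + 1)))
                else:
                    d = obs_start + timedelta(days=int(rng.integers(0, obs_days)))
                diags.append((ids[i], code, d.isoformat()))

    medications = pd.DataFrame(meds, columns=["patient_id", "atc", "date"])
    diagnoses = pd.DataFrame(diags, columns=["patient_id", "icpc", "date"])
    return medications, diagnoses, lookback


# ---------------------------------------------------------------------------
# free-text notes


def render_notes(
    X: pd.DataFrame,
    truth: pd.DataFrame,
    config: CohortConfig,
    templates: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render free-text notes with gold labels.

    Every true fall of a consulting patient yields one trigger-bearing note at
    the fall date; a positive history-of-falls indicator yields one such note
    in the observation window. Distractor notes (negated / traffic-accident /
    homonym mentions) are added per patient at the configured ``note_noise``
    rates, plus Poisson-distributed unrelated notes. Gold labels partition all
    notes into {fall, negated, traffic, homonym, unrelated}.
    """
    templates = templates or load_templates()
    for key in ("fall", "negated", "traffic", "homonym", "unrelated"):
        if not templates.get(key):
            raise CohortConfigError(f"note templates: '{key}' template list is empty")
    rng = config.rng(2)
    obs_start, _ = config.observation_window
    fu_start, _ = config.followup_window
    noise = config.note_noise

    hist = X["history_of_falls"].to_numpy() if "history_of_falls" in X else np.zeros(len(X))
    rows: list[tuple[str, str, str]] = []  # patient_id, date, text
    gold: list[str] = []

    def pick(kind: str) -> str:
        pool = templates[kind]
        return pool[rng.integers(len(pool))]

    def random_date(i: int) -> str:
        # observation window always available; follow-up only for consulters
        if truth["no_consult"].iat[i] or rng.random() < 0.5:
            d = obs_start + timedelta(days=int(rng.integers(0, config.observation_days)))
        else:
            d = fu_start + timedelta(days=int(rng.integers(0, config.followup_days)))
        return d.isoformat()

    for i, pid in enumerate(X.index):
        if hist[i] == 1:
            d = obs_start + timedelta(days=int(rng.integers(0, config.observation_days)))
            rows.append((pid, d.isoformat(), pick("fall")))
            gold.append("fall")
        if truth["fall"].iat[i] == 1 and not truth["no_consult"].iat[i]:
            rows.append((pid, truth["fall_date"].iat[i], pick("fall")))
            gold.append("fall")
        for kind, rate in (
            ("negated", noise.negated),
            ("traffic", noise.traffic),
            ("homonym", noise.homonym),
        ):
            if rng.random() < rate:
                rows.append((pid, random_date(i), pick(kind)))
                gold.append(kind)
        for _ in range(rng.poisson(noise.unrelated_mean)):
            rows.append((pid, random_date(i), pick("unrelated")))
            gold.append("unrelated")

    note_ids = [f"N{i:08d}" for i in range(len(rows))]
    notes = pd.DataFrame(
        {
            "note_id": note_ids,
            "patient_id": [r[0] for r in rows],
            "date": [r[1] for r in rows],
            "text": [r[2] for r in rows],
        }
    )
    gold_notes = pd.DataFrame(
        {"note_id": note_ids, "patient_id": notes["patient_id"], "gold_label": gold}
    )
    return notes, gold_notes


# ---------------------------------------------------------------------------
# assembly and I/O


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Run every generation stage and return the linked cohort."""
    patients, X = sample_covariates(config)
    truth = simulate_outcomes(patients, X, config)
    medications, diagnoses, lookback = generate_records(X, truth, config)
    notes, gold_notes = render_notes(X, truth, config)

    patients = patients.copy()
    patients["death_date"] = truth["death_date"].to_numpy()
    full_truth = pd.concat([truth, X.drop(columns=["age"])], axis=1)
    full_truth.insert(0, "age", X["age"])
    full_truth["lookback"] = lookback.astype(np.int64)
    full_truth = full_truth.reset_index()
    return SyntheticCohort(
        config=config,
        patients=patients,
        medications=medications,
        diagnoses=diagnoses,
        notes=notes,
        gold_notes=gold_notes,
        truth=full_truth,
    )


_FILES = {
    "patients": "patients.csv",
    "medications": "medications.csv",
    "diagnoses": "diagnoses.csv",
    "notes": "notes.csv",
    "gold_notes": "gold_labels.csv",
    "truth": "ground_truth.csv",
}


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write the cohort as UTF-8 comma-delimited files plus a provenance sidecar.

    Reading the directory back with :func:`read_cohort` reproduces every table
    exactly, and a fixed seed fixes every output byte.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, fname in _FILES.items():
        getattr(cohort, attr).to_csv(directory / fname, index=False)
    cfg = dataclasses.asdict(cohort.config)
    cfg["index_date"] = cohort.config.index_date.isoformat()
    cfg["age_distribution"] = list(cohort.config.age_distribution)
    provenance = {"seed": cohort.config.seed, "config": cfg}
    with open(directory / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, default=str)


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Round-trip counterpart of :func:`write_cohort`."""
    directory = Path(directory)
    with open(directory / "provenance.json") as fh:
        prov = json.load(fh)
    cfg = prov["config"]
    cfg["index_date"] = date.fromisoformat(cfg["index_date"])
    cfg["age_distribution"] = tuple(cfg["age_distribution"])
    cfg["note_noise"] = NoteNoise(**cfg["note_noise"])
    cfg["predictor_spec"] = [PredictorSpec(**s) for s in cfg["predictor_spec"]]
    config = CohortConfig(**cfg)
    tables = {}
    for attr, fname in _FILES.items():
        tables[attr] = pd.read_csv(directory / fname, keep_default_na=False, dtype=None)
    # empty-string dates stay strings; numeric columns parsed by pandas
    return SyntheticCohort(config=config, **tables)
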