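"""Predictor engineering: from raw EHR tables to the candidate design matrix.

Builds the 79-column candidate matrix — age, sex, the text-derived history of
falls, 33 fall-risk-increasing-drug (FRID) groups mapped from ATC code
prefixes, and 43 chronic-condition groups mapped from ICPC codes — together
with the binary fall outcome and the death-censoring observation weights.

Condition indicators for patients with no diagnosis record in the observation
window are filled from prior years (look-back), mirroring routine-care
registration gaps. Patients who died during follow-up without an ascertained
fall receive a weight equal to the fraction of the follow-up year they were
observed; everyone else has weight 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .textmine import TriggerLexicon, ascertain_outcome, default_lexicon

_DATA_DIR = Path(__file__).parent / "data"


class MappingError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class CodeMapping:
    """Ordered group -> code-prefix lists for one coding system."""

    kind: str  # "atc_frid" | "icpc_condition"
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("atc_frid", "icpc_condition"):
            raise MappingError(f"unknown mapping kind {self.kind!r}")
        for name, prefixes in self.groups.items():
            if not prefixes or any(not p for p in prefixes):
                raise MappingError(f"group {name!r} has an empty prefix")

    @property
    def names(self) -> list[str]:
        return list(self.groups)


def load_mapping(path: str | Path, kind: str) -> CodeMapping:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return CodeMapping(kind=kind, groups={k: [str(p) for p in v] for k, v in raw.items()})


def default_frid_mapping() -> CodeMapping:
    return load_mapping(_DATA_DIR / "atc_frid.yml", "atc_frid")


def default_condition_mapping() -> CodeMapping:
    return load_mapping(_DATA_DIR / "icpc_conditions.yml", "icpc_condition")


def _in_window(dates: pd.Series, window: tuple[date, date]) -> pd.Series:
    d = pd.to_datetime(dates, format="%Y-%m-%d")
    return (d >= pd.Timestamp(window[0])) & (d < pd.Timestamp(window[1]))


def _prefix_indicators(
    records: pd.DataFrame,
    code_col: str,
    mapping: CodeMapping,
    patient_ids: pd.Index,
) -> pd.DataFrame:
    """Binary indicator per (patient, group): any record code starting with a
    group prefix. Set semantics: duplicate records and record order are
    irrelevant."""
    out = pd.DataFrame(0, index=patient_ids, columns=mapping.names, dtype=np.int64)
    if not len(records):
        return out
    codes = records[code_col].astype(str)
    for name, prefixes in mapping.groups.items():
        hit = codes.str.startswith(tuple(prefixes))
        if hit.any():
            pats = pd.Index(records.loc[hit, "patient_id"].unique())
            out.loc[pats.intersection(patient_ids), name] = 1
    return out


def map_medications(
    medications: pd.DataFrame,
    mapping: CodeMapping,
    window: tuple[date, date],
    patient_ids: pd.Index,
) -> pd.DataFrame:
    """FRID indicator columns: 1 iff any dispense in the half-open window whose
    ATC code starts with a group prefix."""
    if mapping.kind != "atc_frid":
        raise MappingError(f"expected atc_frid mapping, got {mapping.kind!r}")
    recs = medications.loc[_in_window(medications["date"], window)] if len(medications) else medications
    return _prefix_indicators(recs, "atc", mapping, patient_ids)


def map_conditions(
    diagnoses: pd.DataFrame,
    mapping: CodeMapping,
    window: tuple[date, date],
    patient_ids: pd.Index,
    lookback_days: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Chronic-condition indicators with look-back fill.

    Indicators come from diagnoses dated in the observation window. For
    patients with zero in-window diagnosis records, indicators are filled from
    records in the look-back span before the window (all prior records when
    ``lookback_days`` is None) and ``lookback_used`` is flagged for those who
    actually had prior records.
    """
    if mapping.kind != "icpc_condition":
        raise MappingError(f"expected icpc_condition mapping, got {mapping.kind!r}")
    if lookback_days is not None and lookback_days < 0:
        raise MappingError("lookback_days must be non-negative")
    lookback_used = pd.Series(False, index=patient_ids, name="lookback_used")
    if not len(diagnoses):
        cols = pd.DataFrame(0, index=patient_ids, columns=mapping.names, dtype=np.int64)
        return cols, lookback_used

    in_win = _in_window(diagnoses["date"], window)
    cols = _prefix_indicators(diagnoses.loc[in_win], "icpc", mapping, patient_ids)

    consulted = pd.Index(diagnoses.loc[in_win, "patient_id"].unique())
    absent = patient_ids.difference(consulted)
    if len(absent):
        d = pd.to_datetime(diagnoses["date"], format="%Y-%m-%d")
        lb_start = (
            pd.Timestamp(window[0]) - timedelta(days=lookback_days)
            if lookback_days is not None
            else pd.Timestamp.min
        )
        prior = diagnoses.loc[(d >= lb_start) & (d < pd.Timestamp(window[0]))]
        prior = prior[prior["patient_id"].isin(absent)]
        if len(prior):
            fill = _prefix_indicators(prior, "icpc", mapping, pd.Index(absent))
            cols.loc[absent] = fill.loc[absent].to_numpy()
            lookback_used.loc[pd.Index(prior["patient_id"].unique())] = True
    return cols, lookback_used


def compute_weights(
    patients: pd.DataFrame,
    outcome: pd.Series,
    followup_window: tuple[date, date],
    followup_days: int,
) -> pd.Series:
    """Observation weights for the weighted likelihood.

    Weight 1 for survivors and for decedents with an ascertained fall (they
    count as full observations of a faller); for decedents without a fall the
    weight is the observed fraction of the follow-up year,
    ``days(start -> death) / followup_days`` in (0, 1).
    """
    idx = pd.Index(patients["patient_id"], name="patient_id")
    w = pd.Series(1.0, index=idx, name="weight")
    start = pd.Timestamp(followup_window[0])
    dd = pd.to_datetime(patients["death_date"].replace("", pd.NA), errors="raise")
    died = dd.notna().to_numpy()
    if not died.any():
        return w
    days = (dd[died] - start).dt.days.to_numpy()
    if (days <= 0).any():
        bad = idx[died][days <= 0]
        raise DataError(f"death on/before follow-up start for patients: {list(bad[:5])}")
    frac = np.minimum(days / float(followup_days), 1.0)
    y_died = outcome.reindex(idx).to_numpy()[died]
    w.iloc[np.flatnonzero(died)] = np.where(y_died == 1, 1.0, frac)
    return w


CORE_COLUMNS = ("age", "female_sex", "history_of_falls")


@dataclass
class DesignMatrix:
    """Candidate design matrix with outcome, weights and provenance flags."""

    X: pd.DataFrame  # index patient_id; age real, all other columns binary
    y: pd.Series
    w: pd.Series
    flags: pd.DataFrame  # lookback_used, no_followup_consult

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    @property
    def patient_ids(self) -> pd.Index:
        return self.X.index

    def subset(self, mask: pd.Series) -> "DesignMatrix":
        keep = mask.reindex(self.X.index).fillna(False).astype(bool)
        return DesignMatrix(
            self.X.loc[keep], self.y.loc[keep], self.w.loc[keep], self.flags.loc[keep]
        )


def assemble_design_matrix(
    patients: pd.DataFrame,
    medications: pd.DataFrame,
    diagnoses: pd.DataFrame,
    notes: pd.DataFrame,
    observation_window: tuple[date, date],
    followup_window: tuple[date, date],
    frid_mapping: CodeMapping | None = None,
    condition_mapping: CodeMapping | None = None,
    lexicon: TriggerLexicon | None = None,
    age_min: float = 65.0,
    lookback_days: int | None = None,
) -> DesignMatrix:
    """Assemble the full candidate matrix from the raw tables.

    Column order: age, female_sex, history_of_falls, FRID groups, condition
    groups (79 columns under the default mappings). Eligibility: age at
    observation start >= ``age_min``. The outcome and the history-of-falls
    predictor are both ascertained from the notes by the rule-based detector.
    """
    frid_mapping = frid_mapping or default_frid_mapping()
    condition_mapping = condition_mapping or default_condition_mapping()
    lexicon = lexicon or default_lexicon()

    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"]
        raise DataError(f"duplicate patient ids: {list(dup[:5])}")

    eligible = patients.loc[patients["age_at_obs_start"] >= age_min]
    if not len(eligible):
        warnings.warn("no eligible patients (age >= %g); empty design matrix" % age_min)
    ids = pd.Index(eligible["patient_id"], name="patient_id")

    outcome = ascertain_outcome(notes, followup_window, lexicon, ids)
    history = ascertain_outcome(notes, observation_window, lexicon, ids)["fall"]
    frid = map_medications(medications, frid_mapping, observation_window, ids)
    cond, lookback_used = map_conditions(
        diagnoses, condition_mapping, observation_window, ids, lookback_days
    )

    X = pd.DataFrame(index=ids)
    X["age"] = eligible["age_at_obs_start"].to_numpy()
    X["female_sex"] = (eligible["sex"].to_numpy() == "female").astype(np.int64)
    X["history_of_falls"] = history.astype(np.int64)
    X = pd.concat([X, frid, cond], axis=1)

    y = outcome["fall"].rename("fall")
    w = compute_weights(eligible, y, followup_window, (followup_window[1] - followup_window[0]).days)

    if len(notes):
        fu_notes = notes.loc[_in_window(notes["date"], followup_window), "patient_id"]
        consulted = pd.Index(fu_notes.unique())
    else:
        consulted = pd.Index([])
    flags = pd.DataFrame(
        {
            "lookback_used": lookback_used.astype(bool),
            "no_followup_consult": ~ids.isin(consulted),
        },
        index=ids,
    )
    assert not X.isna().any().any(), "design matrix must have no missing cells"
    return DesignMatrix(X=X, y=y, w=w, flags=flags)
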