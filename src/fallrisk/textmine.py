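"""Rule-based ascertainment of falls from free-text clinical notes.

A note documents a fall when a trigger term (``fall``, ``fell``,
``stumbled``, ... with inflection variants) matches, no negation cue occurs
within the five tokens preceding the trigger in the same sentence, and no
traffic-accident or homonym term (``fall season`` and friends) co-occurs in
that sentence. Traffic accidents fall outside the clinical definition of a
fall; homonym contexts flag uses of a trigger word in a non-falling sense.
Applied over the follow-up window the classifier yields the binary outcome;
applied over the observation window it yields the history-of-falls predictor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

_DATA_DIR = Path(__file__).parent / "data"

NEGATION_WINDOW_TOKENS = 5  # clinical-NLP convention for pre-trigger negation scope


class LexiconError(ValueError):
    """Raised for empty or non-compiling lexica."""


@dataclass(frozen=True)
class TriggerLexicon:
    """Word lists driving the detector; matching is case-insensitive."""

    triggers: tuple[str, ...]
    negations: tuple[str, ...]
    traffic: tuple[str, ...]
    homonyms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.triggers:
            raise LexiconError("trigger list is empty")
        object.__setattr__(self, "_trigger_re", _compile_any(self.triggers))
        object.__setattr__(self, "_traffic_re", _compile_any(self.traffic))
        object.__setattr__(self, "_homonym_re", _compile_any(self.homonyms))
        object.__setattr__(
            self, "_negation_set", frozenset(t.lower() for t in self.negations)
        )


def _compile_any(terms: tuple[str, ...]) -> re.Pattern | None:
    if not terms:
        return None
    alternation = "|".join(re.escape(t) for t in sorted(terms, key=len, reverse=True))
    try:
        return re.compile(rf"\b(?:{alternation})\b", re.IGNORECASE)
    except re.error as exc:  # pragma: no cover - escape() should prevent this
        raise LexiconError(f"lexicon pattern failed to compile: {exc}") from exc


def load_lexicon(path: str | Path | None = None) -> TriggerLexicon:
    """Load a YAML lexicon (keys: triggers, negations, traffic, homonyms)."""
    with open(path or _DATA_DIR / "lexicon.yml") as fh:
        raw = yaml.safe_load(fh) or {}
    def _strs(key: str) -> tuple[str, ...]:
        return tuple(str(t) for t in (raw.get(key) or ()))

    return TriggerLexicon(
        triggers=_strs("triggers"),
        negations=_strs("negations"),
        traffic=_strs("traffic"),
        homonyms=_strs("homonyms"),
    )


def default_lexicon() -> TriggerLexicon:
    return load_lexicon(_DATA_DIR / "lexicon.yml")


@dataclass(frozen=True)
class NoteLabel:
    """Classification of one note with an auditable reason code."""

    note_id: str | None
    decision: str  # "fall" | "no_fall"
    reason: str  # trigger_hit | no_trigger | negated | traffic_context | homonym_context
    matched_span: tuple[int, int] | None = None


_SENTENCE_SPLIT = re.compile(r"[.!?\n]")
_TOKEN = re.compile(r"[\w']+")


def classify_note(
    text: str, lexicon: TriggerLexicon, note_id: str | None = None
) -> NoteLabel:
    """Deterministically classify one note as documenting a fall or not.

    The decision is ``fall`` iff some trigger occurrence survives all three
    filters (negation within the preceding five tokens of its sentence,
    traffic term in sentence, homonym term in sentence). When every trigger
    occurrence is filtered, the reason of the first occurrence is reported.
    """
    if not text:
        return NoteLabel(note_id, "no_fall", "no_trigger")
    trig_re = lexicon._trigger_re
    blocked_reason: str | None = None
    pos = 0
    for raw_sentence in _SENTENCE_SPLIT.split(text):
        start = pos
        pos += len(raw_sentence) + 1
        if not raw_sentence.strip():
            continue
        matches = list(trig_re.finditer(raw_sentence))
        if not matches:
            continue
        has_traffic = bool(lexicon._traffic_re and lexicon._traffic_re.search(raw_sentence))
        has_homonym = bool(lexicon._homonym_re and lexicon._homonym_re.search(raw_sentence))
        for m in matches:
            preceding = _TOKEN.findall(raw_sentence[: m.start()])
            negated = any(
                tok.lower() in lexicon._negation_set
                for tok in preceding[-NEGATION_WINDOW_TOKENS:]
            )
            if negated:
                blocked_reason = blocked_reason or "negated"
            elif has_traffic:
                blocked_reason = blocked_reason or "traffic_context"
            elif has_homonym:
                blocked_reason = blocked_reason or "homonym_context"
            else:
                span = (start + m.start(), start + m.end())
                return NoteLabel(note_id, "fall", "trigger_hit", span)
    if blocked_reason is None:
        return NoteLabel(note_id, "no_fall", "no_trigger")
    return NoteLabel(note_id, "no_fall", blocked_reason)


def classify_notes(notes: pd.DataFrame, lexicon: TriggerLexicon) -> pd.DataFrame:
    """Classify a notes table (note_id, patient_id, date, text) row-wise."""
    labels = [
        classify_note(t if isinstance(t, str) else "", lexicon, nid)
        for nid, t in zip(notes["note_id"], notes["text"])
    ]
    out = notes[["note_id", "patient_id", "date"]].copy()
    out["decision"] = [lab.decision for lab in labels]
    out["reason"] = [lab.reason for lab in labels]
    out["span_start"] = [lab.matched_span[0] if lab.matched_span else -1 for lab in labels]
    out["span_end"] = [lab.matched_span[1] if lab.matched_span else -1 for lab in labels]
    return out


def _parse_dates(series: pd.Series) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & series.astype(str).str.len().gt(0)
    if bad.any():
        raise ValueError(
            f"malformed note dates for records: {list(series[bad].index[:5])}"
        )
    return parsed


def ascertain_outcome(
    notes: pd.DataFrame,
    window: tuple[date, date],
    lexicon: TriggerLexicon,
    patient_ids: pd.Index | list[str] | None = None,
) -> pd.DataFrame:
    """Per-patient binary fall indicator over a half-open date window.

    A patient scores 1 iff at least one of their notes dated in
    ``[window[0], window[1])`` classifies as a fall; patients with no notes in
    the window (including patients absent from the notes table) score 0. The
    date of the earliest positive note is reported.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if patient_ids is None:
        patient_ids = pd.Index(notes["patient_id"].unique())
    result = pd.DataFrame(
        {"fall": 0, "first_fall_note_date": ""},
        index=pd.Index(patient_ids, name="patient_id"),
    )
    if len(notes):
        dates = _parse_dates(notes["date"])
        in_window = (dates >= start) & (dates < end)
        subset = notes.loc[in_window]
        if len(subset):
            labelled = classify_notes(subset, lexicon)
            pos = labelled[labelled["decision"] == "fall"]
            if len(pos):
                first = (
                    pos.assign(date=_parse_dates(pos["date"]))
                    .groupby("patient_id")["date"]
                    .min()
                )
                hit = first.index.intersection(result.index)
                result.loc[hit, "fall"] = 1
                result.loc[hit, "first_fall_note_date"] = (
                    first.loc[hit].dt.strftime("%Y-%m-%d").to_numpy()
                )
    return result


def derive_history_of_falls(
    notes: pd.DataFrame,
    observation_window: tuple[date, date],
    lexicon: TriggerLexicon,
    patient_ids: pd.Index | list[str] | None = None,
) -> pd.Series:
    """History-of-falls predictor: the outcome rule applied to the observation window."""
    out = ascertain_outcome(notes, observation_window, lexicon, patient_ids)
    return out["fall"].rename("history_of_falls")


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and the derived proportions; ppv is None when tp+fp=0."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    @property
    def ppv(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def specificity(self) -> float | None:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else None


def validate_detector(
    predicted: pd.Series, gold: pd.Series, positive: object = 1
) -> ConfusionMetrics:
    """Confusion metrics of detector output against gold labels.

    Works at note level (labels) or patient level (binary indicators); the two
    series must be indexed by the same ids.
    """
    missing = predicted.index.symmetric_difference(gold.index)
    if len(missing):
        raise ValueError(f"prediction/gold id mismatch: {sorted(missing)[:10]}")
    gold = gold.loc[predicted.index]
    p = predicted.eq(positive).to_numpy()
    g = gold.eq(positive).to_numpy()
    return ConfusionMetrics(
        tp=int((p & g).sum()),
        fp=int((p & ~g).sum()),
        tn=int((~p & ~g).sum()),
        fn=int((~p & g).sum()),
    )
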