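"""OMOP-style patient store plus the trial-matching tables.

A deliberately reduced common-data-model: persons, coded clinical events
(condition/drug/procedure/measurement/device/observation), narrative notes,
and NOTE_NLP rows holding extractor output, together with the custom
trial-matching tables (TRIAL, CRITERION, MATCH_EVIDENCE, MATCH_CRITERION,
MATCH).  Persistence is one CSV per table (UTF-8, RFC-4180 quoting), which
keeps fixtures diffable and round-trips field-for-field.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

GENDERS = ("female", "male", "unknown")
DOMAINS = ("condition", "drug", "procedure", "measurement", "device", "observation")

# Clinical-event domain conventionally holding each extraction category.
DOMAIN_FOR_CATEGORY = {
    "condition": "condition",
    "medication": "drug",
    "procedure": "procedure",
    "investigation": "measurement",
    "device": "device",
    "demographic": "observation",
}


@dataclass(frozen=True)
class ContextAttributes:
    """Six independent binary contextual attributes of an extracted mention."""

    negated: bool = False
    uncertain: bool = False
    conditional: bool = False
    generic: bool = False
    historical: bool = False
    not_about_patient: bool = False

    FLAGS = ("negated", "uncertain", "conditional", "generic", "historical", "not_about_patient")

    def any(self) -> bool:
        return any(getattr(self, f) for f in self.FLAGS)

    def set_flags(self) -> tuple[str, ...]:
        return tuple(f for f in self.FLAGS if getattr(self, f))


@dataclass(frozen=True)
class Person:
    person_id: str
    gender: str = "unknown"
    birth_date: Optional[_dt.date] = None

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"person {self.person_id!r}: gender {self.gender!r} not in {GENDERS}")


@dataclass(frozen=True)
class ClinicalEvent:
    event_id: str
    person_id: str
    domain: str
    concept_id: str
    event_date: _dt.date
    value: Optional[float] = None
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"event {self.event_id!r}: domain {self.domain!r} not in {DOMAINS}")
        if self.domain != "measurement" and (self.value is not None or self.unit is not None):
            raise ValueError(f"event {self.event_id!r}: only measurement events may carry value/unit")


@dataclass(frozen=True)
class Note:
    note_id: str
    person_id: str
    note_date: _dt.date
    text: str


@dataclass(frozen=True)
class NoteNlpRow:
    """One extracted mention, the NOTE_NLP analogue."""

    note_id: str
    span_start: int
    span_end: int
    surface: str
    concept_id: str
    category: str
    attributes: ContextAttributes = field(default_factory=ContextAttributes)
    allergen_flag: bool = False
    numeric_value: Optional[float] = None
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.span_start < self.span_end):
            raise ValueError(
                f"note {self.note_id!r}: invalid span [{self.span_start}, {self.span_end})"
            )


@dataclass(frozen=True)
class TrialRecord:
    trial_id: str
    registry_id: str
    title: str
    principal_investigator: str


@dataclass(frozen=True)
class CriterionRecord:
    criterion_id: str
    trial_id: str
    definition: str  # serialized executable definition (JSON)


@dataclass(frozen=True)
class MatchEvidenceRow:
    """One row of evidence for a (person, trial, criterion) triplet.

    Both affirmed and attribute-flagged NLP evidence is recorded, with the
    attribute snapshot, so downstream review sees everything; qualification is
    decided later by the policy.
    """

    person_id: str
    trial_id: str
    criterion_id: str
    source: str  # "structured" | "nlp"
    ref: str  # event_id, or "<note_id>:<start>-<end>"
    concept_id: str
    date: Optional[_dt.date] = None
    concept_set: str = "primary"  # "primary" | "secondary" (temporal B side)
    attributes: ContextAttributes = field(default_factory=ContextAttributes)
    allergen_flag: bool = False
    numeric_value: Optional[float] = None
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source not in ("structured", "nlp"):
            raise ValueError(f"evidence source {self.source!r} must be 'structured' or 'nlp'")


@dataclass(frozen=True)
class MatchCriterionRow:
    person_id: str
    trial_id: str
    criterion_id: str
    met: bool
    evidence_count: int

    def __post_init__(self) -> None:
        if self.evidence_count < 0:
            raise ValueError("evidence_count must be non-negative")


@dataclass(frozen=True)
class MatchRow:
    person_id: str
    trial_id: str
    n_met: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_met <= self.n_total):
            raise ValueError(f"need 0 <= n_met <= n_total, got {self.n_met}/{self.n_total}")


@dataclass
class ClinicalStore:
    """In-memory store with referential validation."""

    persons: list[Person] = field(default_factory=list)
    events: list[ClinicalEvent] = field(default_factory=list)
    notes: list[Note] = field(default_factory=list)
    note_nlp: list[NoteNlpRow] = field(default_factory=list)
    trials: list[TrialRecord] = field(default_factory=list)
    criteria: list[CriterionRecord] = field(default_factory=list)
    match_evidence: list[MatchEvidenceRow] = field(default_factory=list)
    match_criteria: list[MatchCriterionRow] = field(default_factory=list)
    matches: list[MatchRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        pids = [p.person_id for p in self.persons]
        if len(pids) != len(set(pids)):
            dup = sorted({p for p in pids if pids.count(p) > 1})
            raise ValueError(f"duplicate person_id(s): {dup}")
        pid_set = set(pids)
        for i, ev in enumerate(self.events):
            if ev.person_id not in pid_set:
                raise ValueError(f"clinical_event row {i}: unknown person_id {ev.person_id!r}")
        nids = [n.note_id for n in self.notes]
        if len(nids) != len(set(nids)):
            dup = sorted({n for n in nids if nids.count(n) > 1})
            raise ValueError(f"duplicate note_id(s): {dup}")
        note_by_id = {n.note_id: n for n in self.notes}
        for i, n in enumerate(self.notes):
            if n.person_id not in pid_set:
                raise ValueError(f"note row {i}: unknown person_id {n.person_id!r}")
        for i, row in enumerate(self.note_nlp):
            note = note_by_id.get(row.note_id)
            if note is None:
                raise ValueError(f"note_nlp row {i}: unknown note_id {row.note_id!r}")
            if row.span_end > len(note.text):
                raise ValueError(f"note_nlp row {i}: span end {row.span_end} beyond note length {len(note.text)}")
            if note.text[row.span_start:row.span_end] != row.surface:
                raise ValueError(f"note_nlp row {i}: surface does not equal the note text slice")

    # -- indices -------------------------------------------------------------
    def person(self, person_id: str) -> Person:
        for p in self.persons:
            if p.person_id == person_id:
                return p
        raise KeyError(f"unknown person_id {person_id!r}")

    def note(self, note_id: str) -> Note:
        for n in self.notes:
            if n.note_id == note_id:
                return n
        raise KeyError(f"unknown note_id {note_id!r}")

    def notes_for(self, person_id: str) -> list[Note]:
        return sorted((n for n in self.notes if n.person_id == person_id), key=lambda n: (n.note_date, n.note_id))

    def nlp_rows_for(self, person_id: str) -> list[tuple[Note, NoteNlpRow]]:
        """NLP rows of a person's notes, with the owning note, date-ordered."""
        by_note: dict[str, list[NoteNlpRow]] = {}
        for row in self.note_nlp:
            by_note.setdefault(row.note_id, []).append(row)
        out: list[tuple[Note, NoteNlpRow]] = []
        for note in self.notes_for(person_id):
            rows = sorted(by_note.get(note.note_id, ()), key=lambda r: (r.span_start, r.span_end, r.category, r.concept_id))
            out.extend((note, r) for r in rows)
        return out

    def max_date(self) -> Optional[_dt.date]:
        dates = [e.event_date for e in self.events] + [n.note_date for n in self.notes]
        return max(dates) if dates else None


def query_events(
    store: ClinicalStore,
    person_id: str,
    domain: Optional[str],
    concept_set: Iterable[str],
) -> list[ClinicalEvent]:
    """The person's events with concept_id in ``concept_set`` (and matching
    domain when given), sorted by event_date then event_id."""
    store.person(person_id)
    concepts = set(concept_set)
    hits = [
        e
        for e in store.events
        if e.person_id == person_id
        and e.concept_id in concepts
        and (domain is None or e.domain == domain)
    ]
    return sorted(hits, key=lambda e: (e.event_date, e.event_id))


# ---------------------------------------------------------------------------
# CSV persistence
# ---------------------------------------------------------------------------

FILES = {
    "persons": "person.csv",
    "events": "clinical_event.csv",
    "notes": "note.csv",
    "note_nlp": "note_nlp.csv",
    "trials": "trial.csv",
    "criteria": "criterion.csv",
    "match_evidence": "match_evidence.csv",
    "match_criteria": "match_criterion.csv",
    "matches": "match.csv",
}

_BOOL = {"True": True, "False": False, "true": True, "false": False}


def _date_str(d: Optional[_dt.date]) -> str:
    return d.isoformat() if d is not None else ""


def _parse_date(s: str) -> Optional[_dt.date]:
    return _dt.date.fromisoformat(s) if s else None


def _num_str(v: Optional[float]) -> str:
    return repr(v) if v is not None else ""


def _parse_num(s: str) -> Optional[float]:
    return float(s) if s else None


def _attrs_cols(a: ContextAttributes) -> dict[str, str]:
    return {f: str(getattr(a, f)) for f in ContextAttributes.FLAGS}


def _attrs_from(row) -> ContextAttributes:
    return ContextAttributes(**{f: _BOOL[getattr(row, f)] for f in ContextAttributes.FLAGS})


def write_store(store: ClinicalStore, directory: str | Path) -> None:
    """Write every table as CSV into ``directory`` (created if absent)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def dump(rows: list[dict], columns: list[str], name: str) -> None:
        pd.DataFrame(rows, columns=columns).to_csv(directory / name, index=False)

    dump(
        [{"person_id": p.person_id, "gender": p.gender, "birth_date": _date_str(p.birth_date)} for p in store.persons],
        ["person_id", "gender", "birth_date"],
        FILES["persons"],
    )
    dump(
        [
            {
                "event_id": e.event_id,
                "person_id": e.person_id,
                "domain": e.domain,
                "concept_id": e.concept_id,
                "event_date": _date_str(e.event_date),
                "value": _num_str(e.value),
                "unit": e.unit or "",
            }
            for e in store.events
        ],
        ["event_id", "person_id", "domain", "concept_id", "event_date", "value", "unit"],
        FILES["events"],
    )
    dump(
        [
            {"note_id": n.note_id, "person_id": n.person_id, "note_date": _date_str(n.note_date), "text": n.text}
            for n in store.notes
        ],
        ["note_id", "person_id", "note_date", "text"],
        FILES["notes"],
    )
    dump(
        [
            {
                "note_id": r.note_id,
                "span_start": str(r.span_start),
                "span_end": str(r.span_end),
                "surface": r.surface,
                "concept_id": r.concept_id,
                "category": r.category,
                **_attrs_cols(r.attributes),
                "allergen_flag": str(r.allergen_flag),
                "numeric_value": _num_str(r.numeric_value),
                "unit": r.unit or "",
            }
            for r in store.note_nlp
        ],
        ["note_id", "span_start", "span_end", "surface", "concept_id", "category", *ContextAttributes.FLAGS, "allergen_flag", "numeric_value", "unit"],
        FILES["note_nlp"],
    )
    dump(
        [
            {"trial_id": t.trial_id, "registry_id": t.registry_id, "title": t.title, "principal_investigator": t.principal_investigator}
            for t in store.trials
        ],
        ["trial_id", "registry_id", "title", "principal_investigator"],
        FILES["trials"],
    )
    dump(
        [{"criterion_id": c.criterion_id, "trial_id": c.trial_id, "definition": c.definition} for c in store.criteria],
        ["criterion_id", "trial_id", "definition"],
        FILES["criteria"],
    )
    dump(
        [
            {
                "person_id": r.person_id,
                "trial_id": r.trial_id,
                "criterion_id": r.criterion_id,
                "source": r.source,
                "ref": r.ref,
                "concept_id": r.concept_id,
                "date": _date_str(r.date),
                "concept_set": r.concept_set,
                **_attrs_cols(r.attributes),
                "allergen_flag": str(r.allergen_flag),
                "numeric_value": _num_str(r.numeric_value),
                "unit": r.unit or "",
            }
            for r in store.match_evidence
        ],
        ["person_id", "trial_id", "criterion_id", "source", "ref", "concept_id", "date", "concept_set", *ContextAttributes.FLAGS, "allergen_flag", "numeric_value", "unit"],
        FILES["match_evidence"],
    )
    dump(
        [
            {
                "person_id": r.person_id,
                "trial_id": r.trial_id,
                "criterion_id": r.criterion_id,
                "met": str(r.met),
                "evidence_count": str(r.evidence_count),
            }
            for r in store.match_criteria
        ],
        ["person_id", "trial_id", "criterion_id", "met", "evidence_count"],
        FILES["match_criteria"],
    )
    dump(
        [
            {"person_id": r.person_id, "trial_id": r.trial_id, "n_met": str(r.n_met), "n_total": str(r.n_total)}
            for r in store.matches
        ],
        ["person_id", "trial_id", "n_met", "n_total"],
        FILES["matches"],
    )


def read_store(directory: str | Path) -> ClinicalStore:
    """Read a store written by :func:`write_store`; read∘write is the identity.

    ``note_nlp`` and the trial/match tables are optional files.
    """
    directory = Path(directory)

    def load(name: str, required: bool = True) -> Optional[pd.DataFrame]:
        path = directory / name
        if not path.exists():
            if required:
                raise FileNotFoundError(f"missing table file {path}")
            return None
        return pd.read_csv(path, dtype=str, keep_default_na=False)

    pdf = load(FILES["persons"])
    persons = [
        Person(r.person_id, r.gender, _parse_date(r.birth_date)) for r in pdf.itertuples(index=False)
    ]
    edf = load(FILES["events"])
    events = [
        ClinicalEvent(r.event_id, r.person_id, r.domain, r.concept_id, _parse_date(r.event_date), _parse_num(r.value), r.unit or None)
        for r in edf.itertuples(index=False)
    ]
    ndf = load(FILES["notes"])
    notes = [Note(r.note_id, r.person_id, _parse_date(r.note_date), r.text) for r in ndf.itertuples(index=False)]

    note_nlp: list[NoteNlpRow] = []
    nl = load(FILES["note_nlp"], required=False)
    if nl is not None:
        note_nlp = [
            NoteNlpRow(
                r.note_id, int(r.span_start), int(r.span_end), r.surface, r.concept_id, r.category,
                _attrs_from(r), _BOOL[r.allergen_flag], _parse_num(r.numeric_value), r.unit or None,
            )
            for r in nl.itertuples(index=False)
        ]
    trials: list[TrialRecord] = []
    tdf = load(FILES["trials"], required=False)
    if tdf is not None:
        trials = [TrialRecord(r.trial_id, r.registry_id, r.title, r.principal_investigator) for r in tdf.itertuples(index=False)]
    criteria: list[CriterionRecord] = []
    cdf = load(FILES["criteria"], required=False)
    if cdf is not None:
        criteria = [CriterionRecord(r.criterion_id, r.trial_id, r.definition) for r in cdf.itertuples(index=False)]
    match_evidence: list[MatchEvidenceRow] = []
    mev = load(FILES["match_evidence"], required=False)
    if mev is not None:
        match_evidence = [
            MatchEvidenceRow(
                r.person_id, r.trial_id, r.criterion_id, r.source, r.ref, r.concept_id,
                _parse_date(r.date), r.concept_set, _attrs_from(r), _BOOL[r.allergen_flag],
                _parse_num(r.numeric_value), r.unit or None,
            )
            for r in mev.itertuples(index=False)
        ]
    match_criteria: list[MatchCriterionRow] = []
    mc = load(FILES["match_criteria"], required=False)
    if mc is not None:
        match_criteria = [
            MatchCriterionRow(r.person_id, r.trial_id, r.criterion_id, _BOOL[r.met], int(r.evidence_count))
            for r in mc.itertuples(index=False)
        ]
    matches: list[MatchRow] = []
    mdf = load(FILES["matches"], required=False)
    if mdf is not None:
        matches = [MatchRow(r.person_id, r.trial_id, int(r.n_met), int(r.n_total)) for r in mdf.itertuples(index=False)]

    return ClinicalStore(persons, events, notes, note_nlp, trials, criteria, match_evidence, match_criteria, matches)
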