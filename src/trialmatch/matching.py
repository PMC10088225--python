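"""Patient-trial matching: evidence retrieval, criterion verdicts, scoring.

The three-level aggregation:

1. **MATCH_EVIDENCE** — every structured event and NLP mention relevant to a
   (person, trial, criterion) triplet is recorded with its attribute
   snapshot, affirmed and negated alike, so reviewers see both sides;
2. **MATCH_CRITERION** — the evidence is aggregated to one met/not-met
   verdict per criterion; *qualifying* evidence is decided by an
   :class:`EvidencePolicy` (by default an NLP mention qualifies only when it
   is affirmed: not negated, not uncertain, not conditional, not generic and
   about the patient; historical mentions are allowed);
3. **MATCH** — criterion verdicts are counted into a per-trial score:
   ``n_met`` of ``n_total`` criteria, the maximum meaning all criteria are
   met and zero meaning none are.

Patients are ranked per trial by score fraction (descending), ties broken by
person id, so study teams can focus on the most promising matches.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .clinical_store import (
    ClinicalStore,
    ContextAttributes,
    MatchCriterionRow,
    MatchEvidenceRow,
    MatchRow,
    Person,
    query_events,
)
from .criteria import Criterion, TrialDefinition, expand_concept_sets
from .vocabulary import (
    AGE_CONCEPT_ID,
    GENDER_BY_CONCEPT_ID,
    VocabularyStore,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvidencePolicy:
    """Which evidence qualifies toward a criterion verdict."""

    require_not_negated: bool = True
    require_not_uncertain: bool = True
    require_not_conditional: bool = True
    require_not_generic: bool = True
    require_about_patient: bool = True
    allow_historical: bool = True
    use_structured: bool = True
    use_nlp: bool = True

    def __post_init__(self) -> None:
        if not (self.use_structured or self.use_nlp):
            raise ValueError("at least one of use_structured/use_nlp must be true")


STRUCTURED_ONLY = EvidencePolicy(use_nlp=False)
NLP_ONLY = EvidencePolicy(use_structured=False)


@dataclass(frozen=True)
class MatchScore:
    person_id: str
    trial_id: str
    n_met: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_met <= self.n_total):
            raise ValueError(f"need 0 <= n_met <= n_total, got {self.n_met}/{self.n_total}")

    @property
    def score_fraction(self) -> float:
        return self.n_met / self.n_total if self.n_total else 0.0

    def as_row(self) -> MatchRow:
        return MatchRow(self.person_id, self.trial_id, self.n_met, self.n_total)


def _mention_ref(note_id: str, start: int, end: int) -> str:
    return f"{note_id}:{start}-{end}"


def find_evidence(
    criterion: Criterion,
    person_id: str,
    store: ClinicalStore,
    policy: EvidencePolicy,
    trial_id: str = "",
) -> list[MatchEvidenceRow]:
    """All evidence rows for one criterion and person.

    Concept sets must already be materialized (see
    :func:`trialmatch.criteria.expand_concept_sets`).  Every matching mention
    is recorded — qualification against the policy happens later — so the
    evidence table reflects affirmed and negated mentions alike.
    """
    store.person(person_id)
    rows: list[MatchEvidenceRow] = []

    def structured(concepts: Sequence[str], concept_set: str) -> None:
        if not policy.use_structured:
            return
        for ev in query_events(store, person_id, None, concepts):
            rows.append(
                MatchEvidenceRow(
                    person_id=person_id,
                    trial_id=trial_id,
                    criterion_id=criterion.criterion_id,
                    source="structured",
                    ref=ev.event_id,
                    concept_id=ev.concept_id,
                    date=ev.event_date,
                    concept_set=concept_set,
                    numeric_value=ev.value,
                    unit=ev.unit,
                )
            )

    def nlp(concepts: Sequence[str], concept_set: str) -> None:
        if not policy.use_nlp:
            return
        concept_ids = set(concepts)
        for note, r in store.nlp_rows_for(person_id):
            if r.concept_id in concept_ids:
                rows.append(
                    MatchEvidenceRow(
                        person_id=person_id,
                        trial_id=trial_id,
                        criterion_id=criterion.criterion_id,
                        source="nlp",
                        ref=_mention_ref(r.note_id, r.span_start, r.span_end),
                        concept_id=r.concept_id,
                        date=note.note_date,
                        concept_set=concept_set,
                        attributes=r.attributes,
                        allergen_flag=r.allergen_flag,
                        numeric_value=r.numeric_value,
                        unit=r.unit,
                    )
                )

    if criterion.kind in ("concept_presence", "value_range"):
        structured(criterion.concept_ids, "primary")
        nlp(criterion.concept_ids, "primary")
    elif criterion.kind == "temporal_order":
        structured(criterion.concept_ids, "primary")
        nlp(criterion.concept_ids, "primary")
        structured(criterion.second_concept_ids, "secondary")
        nlp(criterion.second_concept_ids, "secondary")
    elif criterion.kind == "age_threshold":
        nlp([AGE_CONCEPT_ID], "primary")
    elif criterion.kind == "gender_equals":
        nlp(sorted(GENDER_BY_CONCEPT_ID), "primary")
    rows.sort(key=lambda r: (r.concept_set, r.source, r.date or _dt.date.min, r.ref))
    return rows


def qualify(row: MatchEvidenceRow, criterion: Criterion, policy: EvidencePolicy) -> bool:
    """Does one evidence row qualify toward the criterion verdict?

    Structured rows always qualify (when structured evidence is in use); NLP
    rows qualify only when every policy-required attribute condition holds,
    and a historical mention only when the criterion or the policy allows
    history.
    """
    if row.source == "structured":
        return policy.use_structured
    if not policy.use_nlp:
        return False
    a = row.attributes
    if policy.require_not_negated and a.negated:
        return False
    if policy.require_not_uncertain and a.uncertain:
        return False
    if policy.require_not_conditional and a.conditional:
        return False
    if policy.require_not_generic and a.generic:
        return False
    if policy.require_about_patient and a.not_about_patient:
        return False
    if a.historical and not (criterion.allow_historical or policy.allow_historical):
        return False
    return True


def _compare(comparator: str, value: float, threshold: float) -> bool:
    return {
        "ge": value >= threshold,
        "gt": value > threshold,
        "le": value <= threshold,
        "lt": value < threshold,
        "eq": value == threshold,
    }[comparator]


def _age_at(birth: _dt.date, as_of: _dt.date) -> int:
    return as_of.year - birth.year - ((as_of.month, as_of.day) < (birth.month, birth.day))


def evaluate_criterion(
    criterion: Criterion,
    evidence: Sequence[MatchEvidenceRow],
    person: Person,
    policy: EvidencePolicy,
    as_of_date: _dt.date,
    trial_id: str = "",
) -> MatchCriterionRow:
    """Aggregate evidence rows into one criterion verdict.

    Inclusion criteria are met when the underlying predicate holds; exclusion
    criteria are met when it does not (e.g. "exclude all instances of a
    specific concept" is met when no qualifying evidence exists).
    Indeterminate criteria (e.g. an age rule with no birth date and no
    narrative age) count as not met and are logged.
    """
    qualifying = [r for r in evidence if qualify(r, criterion, policy)]
    indeterminate = False

    if criterion.kind == "concept_presence":
        satisfied = len(qualifying) > 0
    elif criterion.kind == "age_threshold":
        age: Optional[float] = None
        if person.birth_date is not None:
            age = _age_at(person.birth_date, as_of_date)
        else:
            age_rows = [r for r in qualifying if r.numeric_value is not None]
            if age_rows:
                age = max(age_rows, key=lambda r: (r.date or _dt.date.min, r.ref)).numeric_value
        if age is None:
            indeterminate = True
            satisfied = False
        else:
            satisfied = _compare(criterion.comparator, age, criterion.threshold)
    elif criterion.kind == "gender_equals":
        target = next(GENDER_BY_CONCEPT_ID[c] for c in criterion.concept_ids if c in GENDER_BY_CONCEPT_ID)
        gender: Optional[str] = person.gender if person.gender != "unknown" else None
        if gender is None:
            gender_rows = [r for r in qualifying if r.concept_id in GENDER_BY_CONCEPT_ID]
            if gender_rows:
                latest = max(gender_rows, key=lambda r: (r.date or _dt.date.min, r.ref))
                gender = GENDER_BY_CONCEPT_ID[latest.concept_id]
        if gender is None:
            indeterminate = True
            satisfied = False
        else:
            satisfied = gender == target
    elif criterion.kind == "temporal_order":
        first = [r.date for r in qualifying if r.concept_set == "primary" and r.date is not None]
        second = [r.date for r in qualifying if r.concept_set == "secondary" and r.date is not None]
        if not first or not second:
            indeterminate = True
            satisfied = False
        else:
            satisfied = min(first) < min(second)  # strict precedence; a tie is not met
    elif criterion.kind == "value_range":
        valued = [r for r in qualifying if r.numeric_value is not None]
        if criterion.unit is not None:
            valued = [r for r in valued if r.unit is None or r.unit.casefold() == criterion.unit.casefold()]
        satisfied = any(_compare(criterion.comparator, r.numeric_value, criterion.threshold) for r in valued)
    else:  # pragma: no cover - guarded by Criterion validation
        raise ValueError(f"unknown criterion kind {criterion.kind!r}")

    if indeterminate:
        logger.info(
            "criterion %s indeterminate for person %s: counted as not met",
            criterion.criterion_id, person.person_id,
        )
        met = False
    else:
        met = satisfied if criterion.polarity == "inclusion" else not satisfied
    return MatchCriterionRow(
        person_id=person.person_id,
        trial_id=trial_id,
        criterion_id=criterion.criterion_id,
        met=met,
        evidence_count=len(qualifying),
    )


def score_trial(
    person_id: str,
    trial: TrialDefinition,
    criterion_rows: Sequence[MatchCriterionRow],
    count_exclusions: bool = True,
) -> MatchScore:
    """Count met criteria into a trial-level score.

    ``count_exclusions=False`` drops exclusion criteria from both ``n_met``
    and ``n_total``.  A missing criterion row is a hard error.
    """
    by_id = {r.criterion_id: r for r in criterion_rows if r.person_id == person_id}
    counted = [c for c in trial.criteria if count_exclusions or c.polarity == "inclusion"]
    n_met = 0
    for c in counted:
        row = by_id.get(c.criterion_id)
        if row is None:
            raise ValueError(f"person {person_id!r}: missing criterion row for {c.criterion_id!r}")
        n_met += bool(row.met)
    return MatchScore(person_id, trial.trial_id, n_met, len(counted))


def rank_patients(trial_id: str, scores: Iterable[MatchScore]) -> list[MatchScore]:
    """Descending by score fraction, ties by ascending person_id; stable."""
    scores = [s for s in scores if s.trial_id == trial_id]
    return sorted(scores, key=lambda s: (-s.score_fraction, s.person_id))


@dataclass
class MatchResult:
    """Full output of a matching run: the three tables plus a review report."""

    evidence_rows: list[MatchEvidenceRow] = field(default_factory=list)
    criterion_rows: list[MatchCriterionRow] = field(default_factory=list)
    scores: list[MatchScore] = field(default_factory=list)

    def match_rows(self) -> list[MatchRow]:
        return [s.as_row() for s in self.scores]

    def report(self) -> dict:
        """JSON-serializable per-trial match report (ranked persons, verdicts,
        evidence references)."""
        trials = sorted({s.trial_id for s in self.scores})
        verdicts: dict[tuple[str, str], list[MatchCriterionRow]] = {}
        for row in self.criterion_rows:
            verdicts.setdefault((row.trial_id, row.person_id), []).append(row)
        evidence: dict[tuple[str, str, str], list[str]] = {}
        for ev in self.evidence_rows:
            evidence.setdefault((ev.trial_id, ev.person_id, ev.criterion_id), []).append(ev.ref)
        report = {}
        for tid in trials:
            ranked = rank_patients(tid, self.scores)
            report[tid] = [
                {
                    "person_id": s.person_id,
                    "n_met": s.n_met,
                    "n_total": s.n_total,
                    "score_fraction": s.score_fraction,
                    "criteria": [
                        {
                            "criterion_id": r.criterion_id,
                            "met": r.met,
                            "evidence_count": r.evidence_count,
                            "evidence": evidence.get((tid, s.person_id, r.criterion_id), []),
                        }
                        for r in sorted(verdicts.get((tid, s.person_id), []), key=lambda r: r.criterion_id)
                    ],
                }
                for s in ranked
            ]
        return report


def match_trials(
    store: ClinicalStore,
    vocabulary: VocabularyStore,
    trials: Sequence[TrialDefinition],
    policy: EvidencePolicy = EvidencePolicy(),
    as_of_date: Optional[_dt.date] = None,
    count_exclusions: bool = True,
) -> MatchResult:
    """Run the full matching pipeline for every person against every trial.

    ``as_of_date`` (for age computation) defaults to the latest event or note
    date in the store.
    """
    if as_of_date is None:
        as_of_date = store.max_date() or _dt.date.today()
    result = MatchResult()
    for trial in trials:
        expanded = expand_concept_sets(trial, vocabulary)
        for person in sorted(store.persons, key=lambda p: p.person_id):
            crit_rows = []
            for criterion in expanded.criteria:
                ev = find_evidence(criterion, person.person_id, store, policy, trial.trial_id)
                result.evidence_rows.extend(ev)
                crit_rows.append(
                    evaluate_criterion(criterion, ev, person, policy, as_of_date, trial.trial_id)
                )
            result.criterion_rows.extend(crit_rows)
            result.scores.append(score_trial(person.person_id, expanded, crit_rows, count_exclusions))
    return result
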