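"""Matching engine: evidence, qualification, verdicts, scores, ranking."""

from __future__ import annotations

import datetime as dt
import random

import pytest

from trialmatch.clinical_store import (
    ClinicalEvent,
    ClinicalStore,
    ContextAttributes,
    MatchEvidenceRow,
    Note,
    NoteNlpRow,
    Person,
)
from trialmatch.criteria import Criterion, TrialDefinition
from trialmatch.matching import (
    NLP_ONLY,
    STRUCTURED_ONLY,
    EvidencePolicy,
    MatchScore,
    evaluate_criterion,
    find_evidence,
    match_trials,
    qualify,
    rank_patients,
    score_trial,
)
from trialmatch.vocabulary import GENDER_CONCEPT_IDS

from _oracles import naive_criterion_verdicts

AS_OF = dt.date(2024, 6, 30)
DEFAULT = EvidencePolicy()


def presence(cid="CR1", concepts=("C_GVHD",), polarity="inclusion", **kw) -> Criterion:
    return Criterion(cid, polarity, "concept_presence", concept_ids=tuple(concepts), **kw)


def small_store(note_text="", nlp_rows=(), events=(), person=None) -> ClinicalStore:
    person = person or Person("P1", "female", dt.date(1990, 1, 1))
    notes = [Note("N1", "P1", dt.date(2024, 5, 1), note_text)] if note_text else []
    return ClinicalStore(persons=[person], events=list(events), notes=notes, note_nlp=list(nlp_rows))


class TestFindEvidence:
    def test_coded_event_yields_structured_row(self):
        store = small_store(events=[ClinicalEvent("E1", "P1", "condition", "C_GVHD", dt.date(2024, 1, 5))])
        rows = find_evidence(presence(), "P1", store, DEFAULT, "T1")
        assert len(rows) == 1 and rows[0].source == "structured" and rows[0].ref == "E1"

    def test_negated_mention_recorded_with_attribute_snapshot(self):
        row = NoteNlpRow("N1", 15, 19, "GVHD", "C_GVHD", "condition", ContextAttributes(negated=True))
        store = small_store("no evidence of GVHD", [row])
        evidence = find_evidence(presence(), "P1", store, DEFAULT, "T1")
        assert len(evidence) == 1
        assert evidence[0].source == "nlp" and evidence[0].attributes.negated

    def test_irrelevant_person_has_no_evidence(self):
        store = small_store(events=[ClinicalEvent("E1", "P1", "drug", "M_ASA", dt.date(2024, 1, 5))])
        assert find_evidence(presence(), "P1", store, DEFAULT) == []

    def test_structured_only_policy_skips_nlp(self):
        row = NoteNlpRow("N1", 0, 4, "GVHD", "C_GVHD", "condition")
        store = small_store("GVHD", [row])
        assert find_evidence(presence(), "P1", store, STRUCTURED_ONLY) == []


class TestQualify:
    def _nlp(self, **flags) -> MatchEvidenceRow:
        return MatchEvidenceRow("P1", "T1", "CR1", "nlp", "N1:0-4", "C_GVHD", dt.date(2024, 1, 1), attributes=ContextAttributes(**flags))

    def test_affirmed_mention_qualifies(self):
        assert qualify(self._nlp(), presence(), DEFAULT)

    @pytest.mark.parametrize("flag", ["negated", "uncertain", "conditional", "generic", "not_about_patient"])
    def test_flagged_mention_disqualified_by_default(self, flag):
        assert not qualify(self._nlp(**{flag: True}), presence(), DEFAULT)

    def test_historical_allowed_by_default(self):
        assert qualify(self._nlp(historical=True), presence(), DEFAULT)

    def test_historical_blocked_when_neither_criterion_nor_policy_allows(self):
        crit = presence(allow_historical=False)
        policy = EvidencePolicy(allow_historical=False)
        assert not qualify(self._nlp(historical=True), crit, policy)

    def test_structured_always_qualifies(self):
        row = MatchEvidenceRow("P1", "T1", "CR1", "structured", "E1", "C_GVHD", dt.date(2024, 1, 1))
        assert qualify(row, presence(), DEFAULT)


class TestEvaluateCriterion:
    def test_age_threshold_met_from_birth_date(self):
        crit = Criterion("CR1", "inclusion", "age_threshold", comparator="ge", threshold=18.0)
        person = Person("P1", "female", AS_OF.replace(year=AS_OF.year - 30))
        row = evaluate_criterion(crit, [], person, DEFAULT, AS_OF)
        assert row.met

    def test_age_indeterminate_counts_as_not_met(self):
        crit = Criterion("CR1", "inclusion", "age_threshold", comparator="ge", threshold=18.0)
        row = evaluate_criterion(crit, [], Person("P1"), DEFAULT, AS_OF)
        assert not row.met

    def test_age_falls_back_to_nlp_finding(self):
        crit = Criterion("CR1", "inclusion", "age_threshold", comparator="ge", threshold=18.0)
        ev = MatchEvidenceRow("P1", "T1", "CR1", "nlp", "N1:0-10", "DEMO_AGE", dt.date(2024, 1, 1), numeric_value=44.0)
        assert evaluate_criterion(crit, [ev], Person("P1"), DEFAULT, AS_OF).met

    def test_exclusion_with_no_qualifying_rows_is_met(self):
        row = evaluate_criterion(presence(polarity="exclusion"), [], Person("P1"), DEFAULT, AS_OF)
        assert row.met and row.evidence_count == 0

    def test_exclusion_with_affirmed_evidence_not_met(self):
        ev = MatchEvidenceRow("P1", "T1", "CR1", "nlp", "N1:0-4", "C_GVHD", dt.date(2024, 1, 1))
        row = evaluate_criterion(presence(polarity="exclusion"), [ev], Person("P1"), DEFAULT, AS_OF)
        assert not row.met and row.evidence_count == 1

    def test_exclusion_with_only_negated_evidence_stays_met(self):
        ev = MatchEvidenceRow(
            "P1", "T1", "CR1", "nlp", "N1:0-4", "C_GVHD", dt.date(2024, 1, 1),
            attributes=ContextAttributes(negated=True),
        )
        assert evaluate_criterion(presence(polarity="exclusion"), [ev], Person("P1"), DEFAULT, AS_OF).met

    def test_temporal_tie_is_not_met(self):
        crit = Criterion("CR1", "inclusion", "temporal_order", concept_ids=("A",), second_concept_ids=("B",))
        d = dt.date(2024, 1, 1)
        evs = [
            MatchEvidenceRow("P1", "T1", "CR1", "structured", "E1", "A", d, "primary"),
            MatchEvidenceRow("P1", "T1", "CR1", "structured", "E2", "B", d, "secondary"),
        ]
        assert not evaluate_criterion(crit, evs, Person("P1"), DEFAULT, AS_OF).met

    def test_temporal_strict_precedence_met(self):
        crit = Criterion("CR1", "inclusion", "temporal_order", concept_ids=("A",), second_concept_ids=("B",))
        evs = [
            MatchEvidenceRow("P1", "T1", "CR1", "structured", "E1", "A", dt.date(2024, 1, 1), "primary"),
            MatchEvidenceRow("P1", "T1", "CR1", "structured", "E2", "B", dt.date(2024, 2, 1), "secondary"),
        ]
        assert evaluate_criterion(crit, evs, Person("P1"), DEFAULT, AS_OF).met

    def test_value_range_with_unit_check(self):
        crit = Criterion("CR1", "inclusion", "value_range", concept_ids=("I_CREAT",), comparator="le", threshold=1.5, unit="mg/dL")
        ok = MatchEvidenceRow("P1", "T1", "CR1", "nlp", "N1:0-10", "I_CREAT", dt.date(2024, 1, 1), numeric_value=1.2, unit="mg/dL")
        bad = MatchEvidenceRow("P1", "T1", "CR1", "nlp", "N1:0-10", "I_CREAT", dt.date(2024, 1, 1), numeric_value=2.9, unit="mg/dL")
        assert evaluate_criterion(crit, [ok], Person("P1"), DEFAULT, AS_OF).met
        assert not evaluate_criterion(crit, [bad], Person("P1"), DEFAULT, AS_OF).met

    def test_structured_gender_takes_precedence_over_nlp(self):
        crit = Criterion("CR1", "inclusion", "gender_equals", concept_ids=(GENDER_CONCEPT_IDS["female"],))
        male_row = MatchEvidenceRow(
            "P1", "T1", "CR1", "nlp", "N1:0-3", GENDER_CONCEPT_IDS["male"], dt.date(2024, 1, 1)
        )
        person = Person("P1", "female")
        assert evaluate_criterion(crit, [male_row], person, DEFAULT, AS_OF).met


class TestScoringAndRanking:
    def _trial(self, n):
        return TrialDefinition("T1", criteria=tuple(presence(f"CR{i}") for i in range(n)))

    def _rows(self, n, met_ids):
        from trialmatch.clinical_store import MatchCriterionRow

        return [MatchCriterionRow("P1", "T1", f"CR{i}", f"CR{i}" in met_ids, 1) for i in range(n)]

    def test_all_twelve_met_scores_twelve(self):
        score = score_trial("P1", self._trial(12), self._rows(12, {f"CR{i}" for i in range(12)}))
        assert score.n_met == 12 and score.n_total == 12

    def test_none_met_scores_zero(self):
        score = score_trial("P1", self._trial(12), self._rows(12, set()))
        assert score.n_met == 0

    def test_seven_of_twentynine(self):
        met = {f"CR{i}" for i in range(7)}
        score = score_trial("P1", self._trial(29), self._rows(29, met))
        assert (score.n_met, score.n_total) == (7, 29)
        assert score.score_fraction == pytest.approx(7 / 29)

    def test_missing_criterion_row_is_hard_error(self):
        with pytest.raises(ValueError, match="missing criterion row"):
            score_trial("P1", self._trial(3), self._rows(2, set()))

    def test_exclusions_can_be_dropped_from_total(self):
        trial = TrialDefinition(
            "T1",
            criteria=(presence("CR0"), presence("CR1", polarity="exclusion")),
        )
        rows = self._rows(2, {"CR0", "CR1"})
        full = score_trial("P1", trial, rows, count_exclusions=True)
        incl = score_trial("P1", trial, rows, count_exclusions=False)
        assert (full.n_met, full.n_total) == (2, 2)
        assert (incl.n_met, incl.n_total) == (1, 1)

    def test_equal_scores_rank_by_person_id(self):
        scores = [MatchScore(p, "T1", 1, 2) for p in ("P3", "P1", "P2")]
        assert [s.person_id for s in rank_patients("T1", scores)] == ["P1", "P2", "P3"]

    def test_full_match_ranks_first(self):
        scores = [MatchScore("P9", "T1", 2, 2), MatchScore("P1", "T1", 1, 2)]
        assert rank_patients("T1", scores)[0].person_id == "P9"

    def test_random_scores_match_sort_oracle(self):
        rng = random.Random(5)
        scores = [MatchScore(f"P{i:02d}", "T1", rng.randint(0, 10), 10) for i in range(30)]
        got = [(s.person_id, s.n_met) for s in rank_patients("T1", scores)]
        want = [(s.person_id, s.n_met) for s in sorted(scores, key=lambda s: (-s.n_met / s.n_total, s.person_id))]
        assert got == want


class TestPipelineProperties:
    def test_verdicts_equal_naive_oracle_on_small_worlds(self, clean_world_extracted, noisy_world):
        from trialmatch.extraction import extract_all
        from trialmatch.vocabulary import build_full_lexicon

        noisy_world.clinical.note_nlp = extract_all(
            noisy_world.clinical.notes, build_full_lexicon(noisy_world.vocabulary)
        )
        for world in (clean_world_extracted, noisy_world):
            assert len(world.clinical.persons) <= 50
            result = match_trials(world.clinical, world.vocabulary, world.trials, DEFAULT, world.config.as_of)
            got = {(r.person_id, r.criterion_id): r.met for r in result.criterion_rows}
            for trial in world.trials:
                want = naive_criterion_verdicts(world.clinical, world.vocabulary, trial, DEFAULT, world.config.as_of)
                for key, met in want.items():
                    assert got[key] == met, key

    def test_adding_nlp_evidence_moves_verdicts_in_signed_direction(self, clean_world_extracted):
        world = clean_world_extracted
        base = match_trials(world.clinical, world.vocabulary, world.trials, STRUCTURED_ONLY, world.config.as_of)
        both = match_trials(world.clinical, world.vocabulary, world.trials, DEFAULT, world.config.as_of)
        base_met = {(r.person_id, r.trial_id, r.criterion_id): r.met for r in base.criterion_rows}
        kind = {
            (t.trial_id, c.criterion_id): c.polarity for t in world.trials for c in t.criteria
        }
        for r in both.criterion_rows:
            before = base_met[(r.person_id, r.trial_id, r.criterion_id)]
            polarity = kind[(r.trial_id, r.criterion_id)]
            if polarity == "inclusion":
                assert r.met >= before  # NLP can only add inclusion evidence
            elif before is False:
                assert r.met is False  # exclusions may only flip met -> not met

    def test_aggregation_is_a_fixed_point(self, clean_world_extracted):
        world = clean_world_extracted
        result = match_trials(world.clinical, world.vocabulary, world.trials, DEFAULT, world.config.as_of)
        met_by_pair: dict[tuple[str, str], int] = {}
        for r in result.criterion_rows:
            met_by_pair[(r.person_id, r.trial_id)] = met_by_pair.get((r.person_id, r.trial_id), 0) + int(r.met)
        for s in result.scores:
            assert s.n_met == met_by_pair.get((s.person_id, s.trial_id), 0)

    def test_planted_eligible_rank_above_non_eligible(self, clean_world_extracted):
        world = clean_world_extracted
        result = match_trials(world.clinical, world.vocabulary, world.trials, DEFAULT, world.config.as_of)
        for trial in world.trials:
            assigned = [p for p, t in world.truth.assigned_trial.items() if t == trial.trial_id]
            ranked = [s for s in rank_patients(trial.trial_id, result.scores) if s.person_id in assigned]
            labels = [world.truth.labels[(s.person_id, trial.trial_id)] for s in ranked]
            # all eligible patients precede all non-eligible patients
            assert labels == sorted(labels, reverse=True)
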