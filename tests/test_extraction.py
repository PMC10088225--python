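"""Extraction: segmentation, dictionary matching, context, demographics, values."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from trialmatch.clinical_store import Note
from trialmatch.extraction import (
    ExtractionConfig,
    apply_context,
    allergy_section_spans,
    default_trigger_rules,
    extract_demographics,
    extract_note,
    extract_values,
    match_concepts,
    segment_and_tokenize,
)
from trialmatch.vocabulary import Lexicon, build_full_lexicon, build_lexicon

from _oracles import brute_force_mentions


def note(text: str) -> Note:
    return Note("N1", "P1", dt.date(2024, 1, 1), text)


class TestSegmentation:
    def test_empty_text_gives_no_sentences(self):
        assert segment_and_tokenize("") == []

    def test_period_rule_splits_two_sentences(self):
        sents = segment_and_tokenize("No fever. On aspirin.")
        assert len(sents) == 2

    def test_newline_splits(self):
        assert len(segment_and_tokenize("line one\nline two")) == 2

    @given(st.text(alphabet=st.sampled_from(list("ab .!?\nX2-")), max_size=200))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_sentence_spans_partition_text(self, text):
        sents = segment_and_tokenize(text)
        if not text:
            assert sents == []
            return
        assert sents[0].start == 0
        assert sents[-1].end == len(text)
        for a, b in zip(sents, sents[1:]):
            assert a.end == b.start
        for s in sents:
            for ta, tb in s.token_spans:
                assert s.start <= ta < tb <= s.end


class TestConceptMatching:
    def test_longest_match_maps_to_child_concept(self, gvhd_vocab):
        lex = build_lexicon(gvhd_vocab, ["C0018133"], True, True)
        n = note("Patient has graft versus host disease of skin today.")
        cands = match_concepts(n, lex)
        assert len(cands) == 1
        assert cands[0].concept_id == "C1610605"
        assert n.text[cands[0].start:cands[0].end] == "graft versus host disease of skin"

    def test_no_lexicon_surface_gives_nothing(self, gvhd_vocab):
        lex = build_lexicon(gvhd_vocab, ["M_ASA"], False, False)
        assert match_concepts(note("nothing relevant here"), lex) == []

    def test_hyphen_and_case_variants_match(self, gvhd_vocab):
        lex = build_lexicon(gvhd_vocab, ["C0018133"], False, False)
        cands = match_concepts(note("Graft-versus-host disease was discussed."), lex)
        assert len(cands) == 1 and cands[0].concept_id == "C0018133"

    def test_word_boundary_anchoring(self, gvhd_vocab):
        lex = build_lexicon(gvhd_vocab, ["M_ASA"], False, False)
        assert match_concepts(note("superaspirinol is not aspirin2"), lex) == []

    def test_matches_equal_quadratic_scan_oracle(self, clean_world):
        lex = build_full_lexicon(clean_world.vocabulary)
        per_cat = lex.split_by_category()
        for n in clean_world.clinical.notes[:40]:
            cands = match_concepts(n, lex)
            for cat, sub in per_cat.items():
                got = {(c.start, c.end, c.concept_id) for c in cands if c.category == cat}
                assert got == brute_force_mentions(n.text, dict(sub.entries)), n.note_id

    def test_lexicon_growth_never_drops_disjoint_mentions(self, gvhd_vocab):
        small = build_lexicon(gvhd_vocab, ["M_ASA"], False, False)
        big = build_lexicon(gvhd_vocab, ["M_ASA", "I_CREAT"], False, False)
        n = note("aspirin given; creatinine stable.")
        got_small = {(c.start, c.end) for c in match_concepts(n, small)}
        got_big = {(c.start, c.end) for c in match_concepts(n, big)}
        assert got_small <= got_big


class TestContext:
    def _rows(self, text, lex):
        n = note(text)
        sents = segment_and_tokenize(n.text, n.note_id)
        cands = match_concepts(n, lex, sents)
        return apply_context(cands, sents, default_trigger_rules(), text=n.text)

    @pytest.fixture()
    def lex(self, gvhd_vocab):
        return build_lexicon(gvhd_vocab, ["C0018133"], True, True)

    def test_plain_mention_has_all_flags_false(self, lex):
        (row,) = self._rows("GVHD", lex)
        assert not row.attributes.any()

    def test_no_evidence_of_sets_negated(self, lex):
        (row,) = self._rows("no evidence of GVHD", lex)
        assert row.attributes.negated and not row.attributes.historical

    def test_family_history_sets_experiencer_not_historical(self, gvhd_vocab):
        lex = Lexicon({"heart failure": ("C_HF", "condition")})
        n = note("family history of heart failure")
        sents = segment_and_tokenize(n.text)
        cands = match_concepts(n, lex, sents)
        (row,) = apply_context(cands, sents, default_trigger_rules(), text=n.text)
        assert row.attributes.not_about_patient
        assert not row.attributes.historical  # longer trigger masks "history of"

    def test_backward_trigger(self, lex):
        (row,) = self._rows("GVHD was ruled out", lex)
        assert row.attributes.negated

    def test_terminator_blocks_scope(self, lex):
        (row,) = self._rows("no worsening but GVHD persists", lex)
        assert not row.attributes.negated

    def test_trigger_in_other_sentence_out_of_scope(self, lex):
        rows = self._rows("There is no fever. GVHD persists.", lex)
        assert len(rows) == 1 and not rows[0].attributes.negated

    def test_uncertain_and_historical_combine(self, lex):
        (row,) = self._rows("possible prior GVHD", lex)
        assert row.attributes.uncertain and row.attributes.historical


class TestDemographics:
    def test_age_and_gender_pattern(self):
        found = extract_demographics(note("63-year-old woman admitted"))
        kinds = {(f.kind, f.value) for f in found}
        assert ("age", 63) in kinds and ("gender", "female") in kinds

    @pytest.mark.parametrize("text,age", [("45 yo male", 45), ("aged 71 at presentation", 71)])
    def test_age_variants(self, text, age):
        assert any(f.kind == "age" and f.value == age for f in extract_demographics(note(text)))

    def test_out_of_range_age_suppressed(self):
        assert [f for f in extract_demographics(note("aged 200 specimen")) if f.kind == "age"] == []

    def test_man_not_matched_inside_woman(self):
        found = extract_demographics(note("the woman"))
        assert {f.value for f in found if f.kind == "gender"} == {"female"}

    def test_generator_planted_demographics_recovered_exactly(self, clean_world):
        gold = [
            a for a in clean_world.truth.annotations if a.category in ("age", "gender")
        ]
        by_note = {}
        for n in clean_world.clinical.notes:
            for f in extract_demographics(n):
                by_note.setdefault(n.note_id, set()).add((f.start, f.end, f.kind))
        for a in gold:
            assert (a.start, a.end, a.category) in by_note[a.note_id]


class TestValues:
    def _rows(self, text, lex):
        n = note(text)
        sents = segment_and_tokenize(n.text)
        cands = match_concepts(n, lex, sents)
        rows = apply_context(cands, sents, default_trigger_rules(), text=n.text)
        return extract_values(rows, cands, sents, n.text)

    @pytest.fixture()
    def lex(self, gvhd_vocab):
        return build_lexicon(gvhd_vocab, ["I_CREAT"], False, False)

    def test_adjacent_number_and_unit_attached(self, lex):
        (row,) = self._rows("creatinine 1.4 mg/dL", lex)
        assert row.numeric_value == 1.4 and row.unit == "mg/dL"

    def test_pending_result_has_no_value(self, lex):
        (row,) = self._rows("creatinine pending", lex)
        assert row.numeric_value is None

    def test_skip_word_level_tolerated(self, lex):
        (row,) = self._rows("creatinine level 2.1 mmol/L noted", lex)
        assert row.numeric_value == 2.1 and row.unit == "mmol/L"

    def test_generator_planted_values_recovered(self, clean_world_extracted):
        gold = {
            (a.note_id, a.start, a.end): (a.value, a.unit)
            for a in clean_world_extracted.truth.annotations
            if a.category == "investigation" and a.value is not None
        }
        rows = {
            (r.note_id, r.span_start, r.span_end): (r.numeric_value, r.unit)
            for r in clean_world_extracted.clinical.note_nlp
            if r.category == "investigation"
        }
        assert gold  # generator planted at least one lab sentence
        for key, want in gold.items():
            assert rows[key] == want


class TestAllergySection:
    def test_allergy_section_flags_medication(self, gvhd_vocab):
        lex = build_lexicon(gvhd_vocab, ["M_ASA"], False, False)
        n = note("Seen today.\n\nAllergies: aspirin")
        rows = extract_note(n, lex)
        med = [r for r in rows if r.category == "medication"]
        assert len(med) == 1 and med[0].allergen_flag

    def test_mention_outside_section_not_flagged(self, gvhd_vocab):
        lex = build_lexicon(gvhd_vocab, ["M_ASA"], False, False)
        n = note("Allergies: sulfa\n\ntaking aspirin daily")
        (row,) = [r for r in extract_note(n, lex) if r.category == "medication"]
        assert not row.allergen_flag

    def test_section_span_detection(self):
        spans = allergy_section_spans("Plan: rest\nAllergies: nuts\n\nMore text")
        assert len(spans) == 1
        a, b = spans[0]
        assert "nuts" in "Plan: rest\nAllergies: nuts\n\nMore text"[a:b]


class TestExtractNote:
    def test_empty_note_gives_no_rows(self, gvhd_vocab):
        lex = build_full_lexicon(gvhd_vocab)
        assert extract_note(note(""), lex) == []

    def test_deterministic_and_spans_valid(self, clean_world):
        lex = build_full_lexicon(clean_world.vocabulary)
        for n in clean_world.clinical.notes[:20]:
            r1 = extract_note(n, lex)
            r2 = extract_note(n, lex)
            assert r1 == r2
            for row in r1:
                assert n.text[row.span_start:row.span_end] == row.surface

    def test_composition_includes_component_outputs(self, gvhd_vocab):
        lex = build_full_lexicon(gvhd_vocab)
        n = note("71-year-old man with GVHD. creatinine 1.4 mg/dL.")
        rows = extract_note(n, lex)
        cats = sorted(r.category for r in rows)
        assert cats == ["condition", "demographic", "demographic", "investigation"]
        inv = next(r for r in rows if r.category == "investigation")
        assert inv.numeric_value == 1.4
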