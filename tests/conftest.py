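"""Shared fixtures: a small hand-built vocabulary and seeded synthetic worlds."""

from __future__ import annotations

import pytest

from trialmatch.vocabulary import Concept, VocabularyStore, build_full_lexicon
from trialmatch.synthetic import GeneratorConfig, clean_config, generate_world
from trialmatch.extraction import extract_all


@pytest.fixture(scope="session")
def gvhd_vocab() -> VocabularyStore:
    """Hand-built mini hierarchy around graft-versus-host disease."""
    concepts = [
        Concept("C0018133", "SC001", "SYNTH", "graft versus host disease", "condition", ("GVHD",)),
        Concept("C1610605", "SC002", "SYNTH", "graft versus host disease of skin", "condition", ("cutaneous GVHD",)),
        Concept("C_ACUTE", "SC003", "SYNTH", "acute graft versus host disease", "condition", ()),
        Concept("P_NBUVB", "SC004", "SYNTH", "narrowband UVB phototherapy", "procedure", ("NBUVB",)),
        Concept("M_ASA", "SC005", "SYNTH", "aspirin", "medication", ()),
        Concept("I_CREAT", "SC006", "SYNTH", "creatinine", "investigation", ()),
    ]
    edges = [("C1610605", "C0018133"), ("C_ACUTE", "C0018133")]
    return VocabularyStore(concepts, edges)


@pytest.fixture(scope="session")
def clean_world():
    """Small noise-free world: planted mentions all affirmed."""
    cfg = clean_config(seed=7, n_patients=24, n_trials=2, note_length_mean_words=60, note_length_bounds=(1, 400))
    return generate_world(cfg)


@pytest.fixture(scope="session")
def noisy_world():
    """Small world with default attribute noise rates."""
    cfg = GeneratorConfig(seed=13, n_patients=30, n_trials=3, note_length_mean_words=60, note_length_bounds=(1, 400))
    return generate_world(cfg)


@pytest.fixture(scope="session")
def clean_world_extracted(clean_world):
    """Clean world with NOTE_NLP rows populated by the real extractor."""
    lex = build_full_lexicon(clean_world.vocabulary)
    rows = extract_all(clean_world.clinical.notes, lex)
    clean_world.clinical.note_nlp = rows
    return clean_world
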