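"""Seeded synthetic world generator: vocabulary, trials, cohort, notes, gold.

Everything the pipeline consumes can be generated here with no external
data: a synthetic mini terminology (anchor concepts with an is-a hierarchy
plus pseudo-word filler concepts), trial definitions spanning all five rule
kinds, a patient cohort with coded events, template-based narrative notes
with *planted* concept mentions at controlled contextual-attribute rates,
and the matching gold standoff annotations and eligibility labels.

Construction guarantees label/evidence consistency: a patient labelled
eligible receives qualifying evidence for every criterion of their assigned
trial, and a non-eligible patient is built to decisively miss at least one
criterion, so the real matching pipeline recovers the labels exactly.
Planted mentions that are load-bearing for a label are always affirmed;
contextual-attribute rates (negation, uncertainty, history, family history)
apply to the non-load-bearing distractor mentions.

Note text is template-based (planted cue phrases, filler sentences from a
trigger-free word list), so gold spans are exact by construction and the
same seed regenerates byte-identical fixtures.
"""

from __future__ import annotations

import datetime as _dt
import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from .clinical_store import (
    ClinicalEvent,
    ClinicalStore,
    ContextAttributes,
    CriterionRecord,
    DOMAIN_FOR_CATEGORY,
    Note,
    Person,
    TrialRecord,
    write_store,
)
from .criteria import (
    Criterion,
    TrialDefinition,
    criterion_to_dict,
    save_trials,
)
from .evaluation import ReferenceAnnotation, write_gold
from .vocabulary import (
    AGE_CONCEPT_ID,
    GENDER_CONCEPT_IDS,
    Concept,
    VocabularyStore,
    write_vocabulary,
)

import json


# ---------------------------------------------------------------------------
# Anchor concepts (fixed, clinically flavoured) — all synthetic codes.
# ---------------------------------------------------------------------------

_ANCHORS: list[tuple[str, str, str, str, tuple[str, ...], Optional[str]]] = [
    # (concept_id, code, name, category, synonyms, parent)
    ("C_GVHD", "SYN0001", "graft versus host disease", "condition", ("GVHD",), None),
    ("C_GVHD_SKIN", "SYN0002", "graft versus host disease of skin", "condition", ("cutaneous graft versus host disease",), "C_GVHD"),
    ("C_HF", "SYN0003", "heart failure", "condition", ("congestive heart failure",), None),
    ("C_HFPEF", "SYN0004", "heart failure with preserved ejection fraction", "condition", ("HFpEF",), "C_HF"),
    ("C_ARVC", "SYN0005", "arrhythmogenic right ventricular cardiomyopathy", "condition", ("ARVC",), None),
    ("P_NBUVB", "SYN0006", "narrowband UVB phototherapy", "procedure", ("NBUVB", "narrow band UVB phototherapy"), None),
    ("P_HSCT", "SYN0007", "hematopoietic stem cell transplant", "procedure", ("stem cell transplant",), None),
    ("I_CREAT", "SYN0008", "creatinine", "investigation", ("serum creatinine",), None),
    ("I_HGB", "SYN0009", "hemoglobin", "investigation", (), None),
    ("M_ASA", "SYN0010", "aspirin", "medication", (), None),
    ("M_PCN", "SYN0011", "penicillin", "medication", (), None),
    ("D_PACE", "SYN0012", "pacemaker", "device", ("cardiac pacemaker",), None),
    ("D_ICD", "SYN0013", "implantable cardioverter defibrillator", "device", (), None),
    (AGE_CONCEPT_ID, "SYN0098", "age in years", "demographic", (), None),
    (GENDER_CONCEPT_IDS["female"], "SYN0099", "female gender", "demographic", (), None),
    (GENDER_CONCEPT_IDS["male"], "SYN0100", "male gender", "demographic", (), None),
]

# Penicillin is reserved for allergy-section planting and never enters trial
# concept pools, so allergen flags cannot interfere with eligibility labels.
_ALLERGY_CONCEPT = "M_PCN"

_SYLLABLES = (
    "bar", "den", "fal", "gor", "hil", "jun", "kel", "lom", "mir", "nov",
    "pra", "quil", "ros", "tam", "vex", "win", "zan", "cor", "dul", "fen",
)
_NAME_SHAPES = {
    "condition": ("{w} syndrome", "{w} disease"),
    "medication": ("{w}inib", "{w}mycin"),
    "procedure": ("{w} ablation", "{w} therapy"),
    "investigation": ("{w} index", "{w} ratio"),
    "device": ("{w} implant", "{w} catheter"),
}
_UNITS = ("mg/dL", "mmol/L", "U/L", "%", "g/dL")

# Filler vocabulary: common clinical-note words that are neither lexicon
# surfaces nor trigger-phrase heads nor demographic cue words.
_FILLER_WORDS = (
    "the", "patient", "was", "seen", "in", "clinic", "and", "remains",
    "clinically", "stable", "plan", "to", "continue", "current", "management",
    "follow", "up", "scheduled", "for", "review", "records", "discussed",
    "care", "goals", "with", "team", "vital", "signs", "within", "normal",
    "limits", "tolerating", "diet", "well", "ambulating", "independently",
    "rest", "encouraged", "counseling", "provided", "questions", "answered",
)

_AFFIRMED_TEMPLATES = ("Patient has {s}.", "{S} noted on exam.", "Assessment shows {s}.")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic world; the defaults are the study conditions
    (note length distribution, criteria and concept counts per trial)."""

    seed: int = 0
    n_patients: int = 60
    n_trials: int = 2
    criteria_per_trial: tuple[int, int] = (7, 29)
    concepts_per_trial: tuple[int, int] = (2, 12)
    notes_per_patient: tuple[int, int] = (1, 3)
    note_length_mean_words: float = 423.0
    note_length_sigma: float = 1.1
    note_length_bounds: tuple[int, int] = (1, 9490)
    mention_rate: float = 0.9
    structured_rate: float = 0.7
    negation_rate: float = 0.10
    uncertainty_rate: float = 0.05
    historical_rate: float = 0.10
    family_history_rate: float = 0.03
    distractor_rate: float = 0.30
    allergy_rate: float = 0.10
    missing_birth_rate: float = 0.15
    eligible_fraction: float = 0.30
    n_extra_concepts: int = 5
    as_of: _dt.date = _dt.date(2024, 6, 30)

    def validate(self) -> None:
        for name in (
            "mention_rate", "structured_rate", "negation_rate", "uncertainty_rate",
            "historical_rate", "family_history_rate", "distractor_rate",
            "allergy_rate", "missing_birth_rate", "eligible_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("criteria_per_trial", "concepts_per_trial", "notes_per_patient", "note_length_bounds"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range ({lo}, {hi}) is empty or non-positive")
        if self.n_patients < 0 or self.n_trials < 0 or self.n_extra_concepts < 0:
            raise ValueError("counts must be non-negative")
        if self.n_patients > 0 and self.n_trials < 1:
            raise ValueError("patients need at least one trial to be assigned to")
        if self.note_length_mean_words <= 0 or self.note_length_sigma <= 0:
            raise ValueError("note length parameters must be positive")


def clean_config(**overrides) -> GeneratorConfig:
    """A config with no contextual-attribute noise: planted mentions are all
    affirmed, so extraction should score P = R = 1 against the gold."""
    base = dict(
        negation_rate=0.0,
        uncertainty_rate=0.0,
        historical_rate=0.0,
        family_history_rate=0.0,
        mention_rate=1.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@dataclass
class GroundTruth:
    """Per-patient eligibility labels, assigned trials, and gold annotations."""

    labels: dict[tuple[str, str], bool] = field(default_factory=dict)
    assigned_trial: dict[str, str] = field(default_factory=dict)
    annotations: list[ReferenceAnnotation] = field(default_factory=list)
    distractor_annotations: list[ReferenceAnnotation] = field(default_factory=list)
    designated_eligible: tuple[str, ...] = ()


@dataclass
class World:
    vocabulary: VocabularyStore
    trials: list[TrialDefinition]
    clinical: ClinicalStore
    truth: GroundTruth
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------


def build_synthetic_vocabulary(rng: random.Random, n_extra_per_category: int = 5) -> VocabularyStore:
    """Anchor concepts plus pseudo-word filler concepts with some is-a edges."""
    concepts: list[Concept] = []
    edges: list[tuple[str, str]] = []
    for cid, code, name, category, synonyms, parent in _ANCHORS:
        concepts.append(Concept(cid, code, "SYNTH", name, category, synonyms))
        if parent:
            edges.append((cid, parent))
    used_names = {c.preferred_name for c in concepts}
    counter = 100
    for category, shapes in _NAME_SHAPES.items():
        for _ in range(n_extra_per_category):
            while True:
                w = "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(2, 3)))
                name = rng.choice(shapes).format(w=w, s=w)
                if name not in used_names:
                    break
            used_names.add(name)
            cid = f"SYN_{category[:4].upper()}{counter:03d}"
            counter += 1
            concepts.append(Concept(cid, f"SYN{counter:04d}", "SYNTH", name, category, ()))
            if category == "condition" and rng.random() < 0.4:
                child_name = "severe " + name
                if child_name not in used_names:
                    used_names.add(child_name)
                    child_id = cid + "_SEV"
                    concepts.append(Concept(child_id, f"SYN{counter:04d}S", "SYNTH", child_name, category, ()))
                    edges.append((child_id, cid))
    return VocabularyStore(concepts, edges)


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------


def _build_trial(
    rng: random.Random,
    cfg: GeneratorConfig,
    vocab: VocabularyStore,
    index: int,
) -> tuple[TrialDefinition, dict[str, dict]]:
    """One trial definition plus its planting plan (criterion_id -> spec)."""
    presence_pool = sorted(
        cid
        for cid, c in vocab.concepts.items()
        if c.category in ("condition", "medication", "procedure", "device")
        and cid != _ALLERGY_CONCEPT
    )
    inv_pool = sorted(cid for cid, c in vocab.concepts.items() if c.category == "investigation")
    n_concepts = rng.randint(*cfg.concepts_per_trial)
    n_rules = rng.randint(*cfg.criteria_per_trial)

    n_inv = min(len(inv_pool), rng.randint(0, max(0, n_concepts // 4)))
    n_pres = min(len(presence_pool), n_concepts - n_inv)
    chosen_pres = rng.sample(presence_pool, n_pres)
    chosen_inv = rng.sample(inv_pool, n_inv)

    # Allocate presence concepts to roles: temporal pair, exclusions, inclusions.
    roles = list(chosen_pres)
    temporal_pair: Optional[tuple[str, str]] = None
    if len(roles) >= 4 and rng.random() < 0.7:
        temporal_pair = (roles.pop(), roles.pop())
    exclusions: list[str] = []
    if len(roles) >= 3 and rng.random() < 0.6:
        exclusions.append(roles.pop())
    if not roles:  # always at least one inclusion concept
        roles = [chosen_pres[0]] if chosen_pres else [rng.choice(presence_pool)]
        exclusions = [e for e in exclusions if e not in roles]
        temporal_pair = None

    criteria: list[Criterion] = []
    plan: dict[str, dict] = {}
    k = 0

    def cid_next() -> str:
        nonlocal k
        k += 1
        return f"T{index:02d}_CR{k:02d}"

    c = cid_next()
    criteria.append(Criterion(c, "inclusion", "age_threshold", comparator="ge", threshold=18.0))
    plan[c] = {"type": "age", "comparator": "ge", "threshold": 18.0}
    if rng.random() < 0.5:
        target = rng.choice(("female", "male"))
        c = cid_next()
        criteria.append(Criterion(c, "inclusion", "gender_equals", concept_ids=(GENDER_CONCEPT_IDS[target],)))
        plan[c] = {"type": "gender", "target": target}
    for concept in roles:
        c = cid_next()
        expand = bool(vocab.children(concept)) and rng.random() < 0.7
        criteria.append(Criterion(c, "inclusion", "concept_presence", concept_ids=(concept,), include_descendants=expand))
        plan[c] = {"type": "presence_incl", "concept": concept}
    for concept in exclusions:
        c = cid_next()
        criteria.append(Criterion(c, "exclusion", "concept_presence", concept_ids=(concept,), include_descendants=True))
        plan[c] = {"type": "presence_excl", "concept": concept}
    for concept in chosen_inv:
        unit = rng.choice(_UNITS)
        comparator = rng.choice(("ge", "le"))
        threshold = round(rng.uniform(5.0, 60.0), 1)
        delta = round(rng.uniform(2.0, 8.0), 1)
        ok = threshold + delta if comparator == "ge" else max(0.1, threshold - delta)
        bad = max(0.1, threshold - delta) if comparator == "ge" else threshold + delta
        c = cid_next()
        criteria.append(Criterion(c, "inclusion", "value_range", concept_ids=(concept,), comparator=comparator, threshold=threshold, unit=unit))
        plan[c] = {"type": "value", "concept": concept, "unit": unit, "ok": ok, "bad": bad}
    if temporal_pair is not None:
        a, b = temporal_pair
        c = cid_next()
        criteria.append(Criterion(c, "inclusion", "temporal_order", concept_ids=(a,), second_concept_ids=(b,)))
        plan[c] = {"type": "temporal", "a": a, "b": b}
    if len(criteria) < n_rules:
        c = cid_next()
        criteria.append(Criterion(c, "inclusion", "age_threshold", comparator="le", threshold=85.0))
        plan[c] = {"type": "age", "comparator": "le", "threshold": 85.0}
    # Pad to the target rule count with descendant-expansion variants of the
    # inclusion presence rules (planting always uses the seed concept itself,
    # which satisfies both variants).
    flip = True
    while len(criteria) < n_rules:
        concept = roles[(len(criteria)) % len(roles)]
        c = cid_next()
        expand = flip and bool(vocab.children(concept))
        criteria.append(Criterion(c, "inclusion", "concept_presence", concept_ids=(concept,), include_descendants=expand))
        plan[c] = {"type": "presence_incl", "concept": concept}
        flip = not flip
    if len(criteria) > n_rules:
        criteria = criteria[:n_rules]
    trial = TrialDefinition(
        trial_id=f"T{index:02d}",
        registry_id=f"NCT{rng.randint(0, 99_999_999):08d}",
        title=f"Synthetic interventional study {index:02d}",
        principal_investigator=rng.choice(("A. Rivera", "B. Chen", "C. Okafor", "D. Novak")),
        criteria=tuple(criteria),
    )
    return trial, plan


def _trial_universe(trial: TrialDefinition, vocab: VocabularyStore) -> frozenset[str]:
    out: set[str] = set()
    for c in trial.criteria:
        for cid in (*c.concept_ids, *c.second_concept_ids):
            if cid in vocab:
                out |= vocab.descendants(cid)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Note assembly
# ---------------------------------------------------------------------------


@dataclass
class _MentionItem:
    concept_id: str
    category: str
    surface: str
    flags: ContextAttributes = field(default_factory=ContextAttributes)
    value: Optional[float] = None
    unit: Optional[str] = None
    noise: bool = False  # distractor (not load-bearing for any label)


def _fmt_value(v: float) -> str:
    return f"{v:g}"


def _mention_sentence(rng: random.Random, item: _MentionItem) -> tuple[str, int, int]:
    """Render one planted mention; returns (sentence, start, end) of the
    surface within the sentence."""
    f = item.flags
    if item.value is not None:
        lead = item.surface[0].upper() + item.surface[1:]
        tail = rng.choice((" level", ""))
        unit = f" {item.unit}" if item.unit else ""
        sent = f"{lead}{tail} {_fmt_value(item.value)}{unit}."
        return sent, 0, len(item.surface)
    words: list[str] = []
    if f.not_about_patient:
        words.append("family history of")
    elif f.negated:
        words.append("no evidence of")
    if f.uncertain:
        words.append("possible")
    if f.historical:
        words.append("prior")
    if words:
        lead = " ".join(words)
        lead = lead[0].upper() + lead[1:]
        sent = f"{lead} {item.surface}."
        start = len(lead) + 1
        return sent, start, start + len(item.surface)
    template = rng.choice(_AFFIRMED_TEMPLATES)
    if "{S}" in template:
        cap = item.surface[0].upper() + item.surface[1:]
        start = template.index("{S}")
        return template.replace("{S}", cap), start, start + len(cap)
    start = template.index("{s}")
    return template.replace("{s}", item.surface), start, start + len(item.surface)


def _filler_sentence(rng: random.Random, n_words: int) -> str:
    words = [rng.choice(_FILLER_WORDS) for _ in range(n_words)]
    words[0] = words[0].capitalize()
    return " ".join(words) + "."


def _sample_note_words(rng: random.Random, cfg: GeneratorConfig) -> int:
    mu = math.log(cfg.note_length_mean_words) - cfg.note_length_sigma ** 2 / 2.0
    n = int(round(rng.lognormvariate(mu, cfg.note_length_sigma)))
    lo, hi = cfg.note_length_bounds
    return max(lo, min(hi, n))


def _assemble_note(
    rng: random.Random,
    note_id: str,
    items: Sequence[_MentionItem],
    target_words: int,
    demographic: Optional[tuple[int, str]] = None,
    allergy: Optional[_MentionItem] = None,
) -> tuple[str, list[ReferenceAnnotation]]:
    """Build note text from planted items plus filler; returns text and gold."""
    text = ""
    annotations: list[ReferenceAnnotation] = []

    def append_sentence(sent: str) -> int:
        nonlocal text
        if text:
            text += " " if rng.random() < 0.8 else "\n"
        base = len(text)
        text += sent
        return base

    if demographic is not None:
        age, gender = demographic
        word = "woman" if gender == "female" else "man"
        age_str = f"{age}-year-old"
        base = append_sentence(f"{age_str} {word} seen in clinic.")
        annotations.append(ReferenceAnnotation(note_id, base, base + len(age_str), "age", AGE_CONCEPT_ID, value=float(age)))
        gstart = base + len(age_str) + 1
        annotations.append(ReferenceAnnotation(note_id, gstart, gstart + len(word), "gender", GENDER_CONCEPT_IDS[gender]))
    for item in items:
        sent, s, e = _mention_sentence(rng, item)
        base = append_sentence(sent)
        annotations.append(
            ReferenceAnnotation(
                note_id, base + s, base + e, item.category, item.concept_id,
                attributes=item.flags, value=item.value, unit=item.unit,
            )
        )
    words = len(text.split())
    while words < target_words:
        n = rng.randint(6, 12)
        append_sentence(_filler_sentence(rng, n))
        words += n
    if allergy is not None:
        text += "\n\nAllergies: "
        base = len(text)
        text += allergy.surface
        annotations.append(
            ReferenceAnnotation(note_id, base, base + len(allergy.surface), allergy.category, allergy.concept_id, allergen=True)
        )
    if not text:
        text = _filler_sentence(rng, 1)
    # construction order: demographics, then one annotation per item, allergy
    # last — callers rely on this correspondence
    return text, annotations


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------


def generate_world(config: GeneratorConfig) -> World:
    """Generate a full synthetic world (vocabulary, trials, cohort, notes,
    gold) from one seed; same config, byte-identical outputs."""
    config.validate()
    rng = random.Random(config.seed)
    vocab = build_synthetic_vocabulary(rng, config.n_extra_concepts)
    trials: list[TrialDefinition] = []
    plans: list[dict[str, dict]] = []
    for i in range(config.n_trials):
        t, p = _build_trial(rng, config, vocab, i)
        trials.append(t)
        plans.append(p)
    universes = [_trial_universe(t, vocab) for t in trials]
    all_mentionable = sorted(
        cid for cid, c in vocab.concepts.items()
        if c.category != "demographic" and cid != _ALLERGY_CONCEPT
    )

    persons: list[Person] = []
    events: list[ClinicalEvent] = []
    notes: list[Note] = []
    truth = GroundTruth()
    event_counter = 0

    def add_event(pid: str, concept_id: str, date: _dt.date, value: Optional[float] = None, unit: Optional[str] = None) -> None:
        nonlocal event_counter
        event_counter += 1
        domain = DOMAIN_FOR_CATEGORY[vocab.concept(concept_id).category]
        if value is not None:
            domain = "measurement"
        events.append(ClinicalEvent(f"E{event_counter:06d}", pid, domain, concept_id, date, value, unit))

    def rand_date() -> _dt.date:
        return config.as_of - _dt.timedelta(days=rng.randint(0, 364))

    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        ti = i % config.n_trials
        trial, plan, universe = trials[ti], plans[ti], universes[ti]
        eligible = rng.random() < config.eligible_fraction
        violable = [c.criterion_id for c in trial.criteria]
        violated: set[str] = set()
        if not eligible:
            n_viol = rng.randint(1, min(3, len(violable)))
            picked = rng.sample(violable, n_viol)
            # keep at most one age criterion in the violated set (one shared age)
            age_ids = [c for c in picked if plan[c]["type"] == "age"]
            for extra in age_ids[1:]:
                picked.remove(extra)
            violated = set(picked)

        # --- demographics ---------------------------------------------------
        age_plans = [plan[c.criterion_id] for c in trial.criteria if plan[c.criterion_id]["type"] == "age"]
        age = rng.randint(25, 84)
        for c in trial.criteria:
            p = plan[c.criterion_id]
            if p["type"] != "age" or c.criterion_id not in violated:
                continue
            age = 10 if p["comparator"] == "ge" else 95
        gender = rng.choice(("female", "male"))
        for c in trial.criteria:
            p = plan[c.criterion_id]
            if p["type"] != "gender":
                continue
            target = p["target"]
            other = "male" if target == "female" else "female"
            gender = other if c.criterion_id in violated else target
        missing_birth = rng.random() < config.missing_birth_rate
        if missing_birth:
            birth = None
        else:
            birth = config.as_of.replace(year=config.as_of.year - age) - _dt.timedelta(days=rng.randint(0, 360))
            # ensure integer age at as_of equals `age`
            from_date = birth
            years = config.as_of.year - from_date.year - ((config.as_of.month, config.as_of.day) < (from_date.month, from_date.day))
            if years != age:
                birth = config.as_of.replace(year=config.as_of.year - age)
        persons.append(Person(pid, gender, birth))
        truth.assigned_trial[pid] = trial.trial_id
        truth.labels[(pid, trial.trial_id)] = eligible

        # --- plant evidence per criterion ------------------------------------
        note_items: list[_MentionItem] = []
        seen_presence: set[str] = set()
        for c in trial.criteria:
            p = plan[c.criterion_id]
            is_violated = c.criterion_id in violated
            if p["type"] == "presence_incl":
                concept = p["concept"]
                if concept in seen_presence:
                    continue  # evidence already planted for a variant rule
                seen_presence.add(concept)
                covering_violated = any(
                    plans[ti][c2.criterion_id].get("concept") == concept
                    and plans[ti][c2.criterion_id]["type"] == "presence_incl"
                    and c2.criterion_id in violated
                    for c2 in trial.criteria
                )
                if covering_violated:
                    # decisively absent; optionally a negated mention
                    if rng.random() < config.negation_rate:
                        note_items.append(_MentionItem(concept, vocab.concept(concept).category, _pick_surface(rng, vocab, concept), ContextAttributes(negated=True)))
                    continue
                planted = False
                if rng.random() < config.structured_rate:
                    add_event(pid, concept, rand_date())
                    planted = True
                if rng.random() < config.mention_rate or not planted:
                    note_items.append(_MentionItem(concept, vocab.concept(concept).category, _pick_surface(rng, vocab, concept)))
            elif p["type"] == "presence_excl":
                concept = p["concept"]
                if is_violated:
                    if rng.random() < 0.5:
                        add_event(pid, concept, rand_date())
                    else:
                        note_items.append(_MentionItem(concept, vocab.concept(concept).category, _pick_surface(rng, vocab, concept)))
                elif rng.random() < config.negation_rate:
                    note_items.append(_MentionItem(concept, vocab.concept(concept).category, _pick_surface(rng, vocab, concept), ContextAttributes(negated=True)))
            elif p["type"] == "value":
                concept = p["concept"]
                value = p["bad"] if is_violated else p["ok"]
                planted = False
                if rng.random() < config.structured_rate:
                    add_event(pid, concept, rand_date(), value=value, unit=p["unit"])
                    planted = True
                if rng.random() < config.mention_rate or not planted:
                    note_items.append(_MentionItem(concept, "investigation", _pick_surface(rng, vocab, concept), value=value, unit=p["unit"]))
            elif p["type"] == "temporal":
                d1, d2 = sorted((rand_date(), rand_date()))
                if d1 == d2:
                    d2 = d2 + _dt.timedelta(days=1)
                if is_violated:
                    if rng.random() < 0.5:
                        d1 = d2  # tie: strict precedence fails
                    else:
                        d1, d2 = d2, d1
                add_event(pid, p["a"], d1)
                add_event(pid, p["b"], d2)
            # age/gender handled through person fields / demographic sentences

        # --- distractors ------------------------------------------------------
        n_notes = rng.randint(*config.notes_per_patient)
        distractor_pool = [cid for cid in all_mentionable if cid not in universe]
        note_buckets: list[list[_MentionItem]] = [[] for _ in range(n_notes)]
        for item in note_items:
            note_buckets[rng.randrange(n_notes)].append(item)
        for b in range(n_notes):
            for _ in range(3):
                if rng.random() < config.distractor_rate and distractor_pool:
                    concept = rng.choice(distractor_pool)
                    family = rng.random() < config.family_history_rate
                    flags = ContextAttributes(
                        negated=(not family) and rng.random() < config.negation_rate,
                        uncertain=rng.random() < config.uncertainty_rate,
                        historical=rng.random() < config.historical_rate,
                        not_about_patient=family,
                    )
                    note_buckets[b].append(
                        _MentionItem(concept, vocab.concept(concept).category, _pick_surface(rng, vocab, concept), flags, noise=True)
                    )

        # --- notes ------------------------------------------------------------
        note_dates = sorted(rand_date() for _ in range(n_notes))
        for j in range(n_notes):
            note_id = f"{pid}_N{j}"
            demographic = (age, gender) if j == 0 else None
            allergy = None
            if rng.random() < config.allergy_rate:
                allergy = _MentionItem(_ALLERGY_CONCEPT, "medication", vocab.concept(_ALLERGY_CONCEPT).preferred_name)
            text, anns = _assemble_note(
                rng, note_id, note_buckets[j], _sample_note_words(rng, config), demographic, allergy
            )
            notes.append(Note(note_id, pid, note_dates[j], text))
            truth.annotations.extend(anns)
            base = 2 if demographic is not None else 0
            for item, ann in zip(note_buckets[j], anns[base:]):
                if item.noise:
                    truth.distractor_annotations.append(ann)

    store = ClinicalStore(
        persons=persons,
        events=events,
        notes=notes,
        trials=[TrialRecord(t.trial_id, t.registry_id, t.title, t.principal_investigator) for t in trials],
        criteria=[
            CriterionRecord(c.criterion_id, t.trial_id, json.dumps(criterion_to_dict(c), sort_keys=True))
            for t in trials
            for c in t.criteria
        ],
    )
    return World(vocab, trials, store, truth, config)


def _pick_surface(rng: random.Random, vocab: VocabularyStore, concept_id: str) -> str:
    return rng.choice(vocab.concept(concept_id).names())


# ---------------------------------------------------------------------------
# Known-eligible replication scenario
# ---------------------------------------------------------------------------


def gvhd_phototherapy_world(
    seed: int = 0,
    n_eligible: int = 9,
    n_unknown: int = 301,
    gvhd_note_count: int = 294,
    nbuvb_note_count: int = 30,
    mean_words: float = 423.0,
    sigma: float = 1.1,
) -> World:
    """A seeded replication of the graft-versus-host-disease / narrowband-UVB
    phototherapy matching scenario.

    Every patient carries a *coded* GVHD diagnosis and nobody has a coded
    phototherapy procedure; the therapy exists only in note text.  The
    designated eligible patients get affirmed narrative mentions of both the
    diagnosis and the therapy; among the patients of unknown eligibility, a
    fixed number get a narrative GVHD mention and a fixed number a narrative
    phototherapy mention.  Detection therefore requires the NLP path.
    """
    rng = random.Random(seed)
    vocab = build_synthetic_vocabulary(rng, 0)
    trial = TrialDefinition(
        trial_id="T_GVHD_NBUVB",
        registry_id="N/A",
        title="Narrowband UVB phototherapy for cutaneous graft-versus-host disease",
        principal_investigator="E. Ward",
        criteria=(
            Criterion("CR_GVHD", "inclusion", "concept_presence", concept_ids=("C_GVHD",), include_descendants=True),
            Criterion("CR_NBUVB", "inclusion", "concept_presence", concept_ids=("P_NBUVB",), include_descendants=True),
        ),
    )
    n_total = n_eligible + n_unknown
    pids = [f"P{i:04d}" for i in range(n_total)]
    designated = sorted(rng.sample(pids, n_eligible))
    unknowns = [p for p in pids if p not in designated]
    gvhd_in_note = set(rng.sample(unknowns, min(gvhd_note_count, len(unknowns))))
    nbuvb_in_note = set(rng.sample(unknowns, min(nbuvb_note_count, len(unknowns))))

    cfg = GeneratorConfig(seed=seed, n_patients=n_total, note_length_mean_words=mean_words, note_length_sigma=sigma)
    as_of = cfg.as_of
    persons: list[Person] = []
    events: list[ClinicalEvent] = []
    notes: list[Note] = []
    truth = GroundTruth(designated_eligible=tuple(designated))
    gvhd_surfaces = vocab.concept("C_GVHD").names() + vocab.concept("C_GVHD_SKIN").names()
    nbuvb_surfaces = vocab.concept("P_NBUVB").names()

    for i, pid in enumerate(pids):
        gender = rng.choice(("female", "male"))
        age = rng.randint(20, 80)
        birth = as_of.replace(year=as_of.year - age)
        persons.append(Person(pid, gender, birth))
        events.append(
            ClinicalEvent(f"E{i:06d}", pid, "condition", "C_GVHD", as_of - _dt.timedelta(days=rng.randint(30, 360)))
        )
        items: list[_MentionItem] = []
        if pid in designated or pid in gvhd_in_note:
            concept = rng.choice(("C_GVHD", "C_GVHD", "C_GVHD_SKIN"))
            surfaces = vocab.concept(concept).names()
            items.append(_MentionItem(concept, "condition", rng.choice(surfaces)))
        if pid in designated or pid in nbuvb_in_note:
            items.append(_MentionItem("P_NBUVB", "procedure", rng.choice(nbuvb_surfaces)))
        rng.shuffle(items)
        note_id = f"{pid}_N0"
        text, anns = _assemble_note(rng, note_id, items, _sample_note_words(rng, cfg), demographic=(age, gender))
        notes.append(Note(note_id, pid, as_of - _dt.timedelta(days=rng.randint(0, 360)), text))
        truth.annotations.extend(anns)
        truth.assigned_trial[pid] = trial.trial_id
        truth.labels[(pid, trial.trial_id)] = pid in designated

    store = ClinicalStore(
        persons=persons,
        events=events,
        notes=notes,
        trials=[TrialRecord(trial.trial_id, trial.registry_id, trial.title, trial.principal_investigator)],
        criteria=[
            CriterionRecord(c.criterion_id, trial.trial_id, json.dumps(criterion_to_dict(c), sort_keys=True))
            for c in trial.criteria
        ],
    )
    return World(vocab, [trial], store, truth, cfg)


# ---------------------------------------------------------------------------
# Fixture IO
# ---------------------------------------------------------------------------


def write_fixture(world: World, directory: str | Path) -> list[Path]:
    """Write every artifact of a world as plain-text files; deterministic for
    a fixed config, and round-trips through the module readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_vocabulary(world.vocabulary, directory / "concepts.csv", directory / "relations.csv")
    save_trials(world.trials, directory / "trials.json")
    write_store(world.clinical, directory)
    write_gold(world.truth.annotations, directory / "gold_annotations.tsv")
    import pandas as pd

    labels = pd.DataFrame(
        [
            {"person_id": pid, "trial_id": tid, "eligible": str(flag)}
            for (pid, tid), flag in sorted(world.truth.labels.items())
        ],
        columns=["person_id", "trial_id", "eligible"],
    )
    labels.to_csv(directory / "labels.csv", index=False)
    return sorted(p for p in directory.iterdir() if p.is_file())
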