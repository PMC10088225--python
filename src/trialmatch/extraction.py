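"""Dictionary- and pattern-based information extraction over clinical notes.

The extractor is deliberately rule-based and deterministic:

* sentence segmentation on terminal punctuation and newlines, with token
  spans, such that sentence spans partition the note text;
* dictionary concept matching against per-category lexicons — longest match
  wins within a category, non-overlapping within a category, case-insensitive
  and word-boundary anchored; overlaps across categories are permitted;
* a trigger/scope contextual-attribute classifier in the style of the ConText
  family of algorithms: each trigger phrase asserts one of six binary
  attributes (negated, uncertain, conditional, generic, historical,
  not-about-patient) over mentions within a directional token scope, bounded
  by terminator phrases and sentence boundaries;
* pattern-based demographics (age, gender);
* numeric result-value attachment for investigation mentions;
* allergy-section detection, flagging mentions inside it as allergens.

Output rows are NOTE_NLP analogues (:class:`~trialmatch.clinical_store.NoteNlpRow`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .clinical_store import ContextAttributes, Note, NoteNlpRow
from .vocabulary import (
    AGE_CONCEPT_ID,
    GENDER_CONCEPT_IDS,
    Lexicon,
    normalize_surface,
)

logger = logging.getLogger(__name__)

ATTRIBUTES = ContextAttributes.FLAGS
DIRECTIONS = ("forward", "backward", "bidirectional")

TOKEN_RE = re.compile(r"\d+\.\d+|\w+(?:[-'/.]\w+)*|[^\w\s]")
_SENT_BOUND = re.compile(r"(?<=[.!?])[ \t]+|\n+")
NUMBER_RE = re.compile(r"^\d+(?:\.\d+)?$")
UNIT_RE = re.compile(r"^[A-Za-zμ%][A-Za-z0-9μ%/^.-]*$")
_VALUE_SKIP = {"is", "was", "of", "level", "levels", "result", "results", "value", "at", "=", ":"}
_UNIT_STOP = {"and", "with", "on", "in", "the", "a", "today", "noted", "stable", "pending"}

MAX_AGE = 130


@dataclass(frozen=True)
class TriggerRule:
    """One contextual-attribute trigger phrase with its directional scope."""

    phrase: str
    attribute: str
    direction: str = "forward"
    max_scope_tokens: int = 6
    terminators: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.phrase:
            raise ValueError("trigger phrase must be non-empty")
        if self.attribute not in ATTRIBUTES:
            raise ValueError(f"unknown attribute {self.attribute!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.max_scope_tokens < 1:
            raise ValueError("max_scope_tokens must be >= 1")


def load_trigger_rules(path: str | Path) -> list[TriggerRule]:
    """Read trigger rules from TSV: phrase, attribute, direction, scope, terminators."""
    rules: list[TriggerRule] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            phrase, attribute, direction, scope, terms = line.split("\t")
            rules.append(
                TriggerRule(phrase, attribute, direction, int(scope), tuple(t for t in terms.split("|") if t))
            )
    return rules


_default_rules: Optional[list[TriggerRule]] = None


def default_trigger_rules() -> list[TriggerRule]:
    """The trigger set shipped with the package."""
    global _default_rules
    if _default_rules is None:
        ref = resources.files("trialmatch").joinpath("data/context_triggers.tsv")
        with resources.as_file(ref) as path:
            _default_rules = load_trigger_rules(path)
    return list(_default_rules)


@dataclass(frozen=True)
class Sentence:
    """One sentence: character span plus token spans, all absolute offsets."""

    start: int
    end: int
    token_spans: tuple[tuple[int, int], ...]
    note_id: Optional[str] = None


@dataclass(frozen=True)
class DemographicFinding:
    note_id: Optional[str]
    kind: str  # "age" | "gender"
    value: object  # int years, or "female"/"male"
    start: int
    end: int
    surface: str


@dataclass(frozen=True)
class MentionCandidate:
    note_id: Optional[str]
    start: int
    end: int
    surface: str
    concept_id: str
    category: str
    sent_index: int
    tok_start: int  # token index within sentence
    tok_end: int  # exclusive


@dataclass(frozen=True)
class ExtractionConfig:
    value_window_tokens: int = 6
    demographics: bool = True


def segment_and_tokenize(text: str, note_id: Optional[str] = None) -> list[Sentence]:
    """Split text into sentences whose spans partition the text.

    Boundary whitespace belongs to the preceding sentence, so the spans are
    contiguous and cover the text exactly.  Splits at terminal punctuation
    followed by space/tab and at newlines.  Deterministic.
    """
    if not text:
        return []
    starts = [0]
    for m in _SENT_BOUND.finditer(text):
        if m.end() < len(text):
            starts.append(m.end())
    starts = sorted(set(starts))
    sentences = []
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else len(text)
        if e <= s:
            continue
        tokens = tuple((s + m.start(), s + m.end()) for m in TOKEN_RE.finditer(text[s:e]))
        sentences.append(Sentence(s, e, tokens, note_id))
    return sentences


def _as_category_lexicons(lexicons: Lexicon | Mapping[str, Lexicon]) -> dict[str, Lexicon]:
    if isinstance(lexicons, Lexicon):
        return lexicons.split_by_category()
    return dict(lexicons)


def match_concepts(
    note: Note,
    lexicons: Lexicon | Mapping[str, Lexicon],
    sentences: Optional[Sequence[Sentence]] = None,
) -> list[MentionCandidate]:
    """Dictionary concept matching.

    Longest match wins and matches never overlap within a category; matches in
    different categories may overlap.  Matching is per sentence, token-aligned
    (hence word-boundary anchored) and uses the lexicon's surface
    normalization, so hyphen/case variants of a surface form are found.
    """
    if sentences is None:
        sentences = segment_and_tokenize(note.text, note.note_id)
    text = note.text
    out: list[MentionCandidate] = []
    for category, lex in sorted(_as_category_lexicons(lexicons).items()):
        if not lex.entries:
            continue
        max_words = max(len(k.split()) for k in lex.entries)
        first_words = {k.split(" ", 1)[0] for k in lex.entries}
        for si, sent in enumerate(sentences):
            toks = sent.token_spans
            norm = [normalize_surface(text[a:b]) for a, b in toks]
            i = 0
            while i < len(toks):
                head = norm[i].split(" ", 1)[0] if norm[i] else ""
                if head not in first_words:
                    i += 1
                    continue
                matched = False
                for size in range(min(max_words, len(toks) - i), 0, -1):
                    if not norm[i + size - 1]:  # edge token is pure punctuation
                        continue
                    a, b = toks[i][0], toks[i + size - 1][1]
                    key = normalize_surface(text[a:b])
                    hit = lex.entries.get(key)
                    if hit is not None:
                        out.append(
                            MentionCandidate(note.note_id, a, b, text[a:b], hit[0], category, si, i, i + size)
                        )
                        i += size
                        matched = True
                        break
                if not matched:
                    i += 1
    out.sort(key=lambda c: (c.start, c.end, c.category, c.concept_id))
    return out


def _phrase_tokens(phrase: str) -> list[str]:
    return [normalize_surface(t.group()) for t in TOKEN_RE.finditer(phrase)]


def _find_occurrences(norm_tokens: Sequence[str], phrase: str) -> list[tuple[int, int]]:
    """Token index ranges where the phrase occurs as a contiguous subsequence."""
    ptoks = _phrase_tokens(phrase)
    if not ptoks:
        return []
    n, m = len(norm_tokens), len(ptoks)
    return [(i, i + m) for i in range(n - m + 1) if list(norm_tokens[i:i + m]) == ptoks]


def apply_context(
    candidates: Sequence[MentionCandidate],
    sentences: Sequence[Sentence],
    rules: Optional[Sequence[TriggerRule]] = None,
    text: Optional[str] = None,
) -> list[NoteNlpRow]:
    """Assign contextual attributes to concept mentions.

    A mention acquires a rule's attribute when a trigger phrase occurs in the
    same sentence and the mention lies within the rule's directional scope
    (at most ``max_scope_tokens`` tokens away, not crossing a terminator).
    A trigger occurrence strictly contained in a longer occurrence of another
    rule is suppressed (longest trigger wins), so e.g. "family history of"
    masks the "history of" trigger inside it.
    """
    if rules is None:
        rules = default_trigger_rules()
    # Per-sentence normalized tokens.
    norm_by_sent: dict[int, list[str]] = {}

    def norm_tokens(si: int) -> list[str]:
        if si not in norm_by_sent:
            sent = sentences[si]
            if text is not None:
                src = text
            else:
                raise ValueError("apply_context requires the note text")
            norm_by_sent[si] = [normalize_surface(src[a:b]) for a, b in sent.token_spans]
        return norm_by_sent[si]

    # Trigger and terminator occurrences per sentence.
    occ_by_sent: dict[int, list[tuple[TriggerRule, int, int]]] = {}
    term_by_sent: dict[int, list[tuple[TriggerRule, int, int]]] = {}
    sent_indices = sorted({c.sent_index for c in candidates})
    for si in sent_indices:
        toks = norm_tokens(si)
        occs: list[tuple[TriggerRule, int, int]] = []
        terms: list[tuple[TriggerRule, int, int]] = []
        for rule in rules:
            for a, b in _find_occurrences(toks, rule.phrase):
                occs.append((rule, a, b))
            for t in rule.terminators:
                for a, b in _find_occurrences(toks, t):
                    terms.append((rule, a, b))
        kept = [
            (rule, a, b)
            for rule, a, b in occs
            if not any(
                (a2 <= a and b <= b2 and (b2 - a2) > (b - a)) for _, a2, b2 in occs
            )
        ]
        occ_by_sent[si] = kept
        term_by_sent[si] = terms

    rows: list[NoteNlpRow] = []
    for cand in candidates:
        flags = {f: False for f in ATTRIBUTES}
        for rule, a, b in occ_by_sent.get(cand.sent_index, ()):
            terms = [(ta, tb) for r, ta, tb in term_by_sent[cand.sent_index] if r is rule]
            in_scope = False
            if rule.direction in ("forward", "bidirectional") and cand.tok_start >= b:
                gap = cand.tok_start - b
                blocked = any(b <= ta and tb <= cand.tok_start for ta, tb in terms)
                in_scope = gap <= rule.max_scope_tokens and not blocked
            if not in_scope and rule.direction in ("backward", "bidirectional") and cand.tok_end <= a:
                gap = a - cand.tok_end
                blocked = any(cand.tok_end <= ta and tb <= a for ta, tb in terms)
                in_scope = gap <= rule.max_scope_tokens and not blocked
            if in_scope:
                flags[rule.attribute] = True
        rows.append(
            NoteNlpRow(
                note_id=cand.note_id or "",
                span_start=cand.start,
                span_end=cand.end,
                surface=cand.surface,
                concept_id=cand.concept_id,
                category=cand.category,
                attributes=ContextAttributes(**flags),
            )
        )
    return rows


_AGE_PATTERNS = [
    re.compile(r"\b(\d{1,3})[- ](?:year|yr)s?[- ]old\b", re.IGNORECASE),
    re.compile(r"\b(\d{1,3})\s*(?:y/o|yo|y\.o\.)\b", re.IGNORECASE),
    re.compile(r"\baged?[:\s]\s*(\d{1,3})\b", re.IGNORECASE),
]
_FEMALE_RE = re.compile(r"\b(female|woman|lady|girl)\b", re.IGNORECASE)
_MALE_RE = re.compile(r"\b(male|man|gentleman|boy)\b", re.IGNORECASE)


def extract_demographics(note: Note) -> list[DemographicFinding]:
    """Pattern-based age and gender findings.

    Ages outside [0, 130] are suppressed (and logged) rather than emitted.
    """
    findings: list[DemographicFinding] = []
    taken: list[tuple[int, int]] = []
    for pat in _AGE_PATTERNS:
        for m in pat.finditer(note.text):
            if any(not (m.end() <= a or m.start() >= b) for a, b in taken):
                continue
            age = int(m.group(1))
            if age > MAX_AGE:
                logger.warning("note %s: implausible age %d suppressed", note.note_id, age)
                continue
            taken.append((m.start(), m.end()))
            findings.append(DemographicFinding(note.note_id, "age", age, m.start(), m.end(), m.group()))
    for regex, gender in ((_FEMALE_RE, "female"), (_MALE_RE, "male")):
        for m in regex.finditer(note.text):
            findings.append(DemographicFinding(note.note_id, "gender", gender, m.start(), m.end(), m.group()))
    findings.sort(key=lambda f: (f.start, f.end, f.kind))
    return findings


def extract_values(
    rows: Sequence[NoteNlpRow],
    candidates: Sequence[MentionCandidate],
    sentences: Sequence[Sentence],
    text: str,
    window: int = 6,
) -> list[NoteNlpRow]:
    """Attach the nearest following numeric value (and unit) to investigation
    mentions, within ``window`` tokens in the same sentence."""
    out = list(rows)
    for idx, (row, cand) in enumerate(zip(rows, candidates)):
        if cand.category != "investigation":
            continue
        sent = sentences[cand.sent_index]
        toks = sent.token_spans
        value = unit = None
        scanned = 0
        j = cand.tok_end
        while j < len(toks) and scanned < window:
            tok = text[toks[j][0]:toks[j][1]]
            low = tok.casefold()
            if value is None:
                if NUMBER_RE.match(tok):
                    value = float(tok)
                elif low not in _VALUE_SKIP and not re.match(r"^\W$", tok):
                    break  # an unrelated word intervenes before any number
            else:
                if UNIT_RE.match(tok) and low not in _UNIT_STOP and not NUMBER_RE.match(tok):
                    unit = tok
                break
            j += 1
            scanned += 1
        if value is not None:
            out[idx] = replace(row, numeric_value=value, unit=unit)
    return out


_HEADER_RE = re.compile(r"^[ \t]*([A-Za-z][A-Za-z ]{0,40}?)[ \t]*:", re.MULTILINE)
_BLANK_RE = re.compile(r"\n[ \t]*\n")


def allergy_section_spans(text: str) -> list[tuple[int, int]]:
    """Character spans of allergy sections: from a header line whose title
    starts with 'allerg' until the next header or blank line."""
    headers = list(_HEADER_RE.finditer(text))
    spans = []
    for i, m in enumerate(headers):
        if not m.group(1).casefold().startswith("allerg"):
            continue
        start = m.end()
        end = len(text)
        if i + 1 < len(headers):
            end = min(end, headers[i + 1].start())
        blank = _BLANK_RE.search(text, start)
        if blank:
            end = min(end, blank.start())
        spans.append((start, end))
    return spans


def extract_note(
    note: Note,
    lexicons: Lexicon | Mapping[str, Lexicon],
    rules: Optional[Sequence[TriggerRule]] = None,
    config: ExtractionConfig = ExtractionConfig(),
) -> list[NoteNlpRow]:
    """Full extraction over one note; composition of the component extractors.

    Deterministic: identical input and config yield identical rows in
    identical order (sorted by span, then category, then concept).
    """
    if not note.text:
        return []
    sentences = segment_and_tokenize(note.text, note.note_id)
    candidates = match_concepts(note, lexicons, sentences)
    rows = apply_context(candidates, sentences, rules, text=note.text)
    rows = extract_values(rows, candidates, sentences, note.text, config.value_window_tokens)
    if config.demographics:
        for f in extract_demographics(note):
            if f.kind == "age":
                concept_id, numeric = AGE_CONCEPT_ID, float(f.value)
            else:
                concept_id, numeric = GENDER_CONCEPT_IDS[f.value], None
            rows.append(
                NoteNlpRow(
                    note_id=note.note_id,
                    span_start=f.start,
                    span_end=f.end,
                    surface=f.surface,
                    concept_id=concept_id,
                    category="demographic",
                    numeric_value=numeric,
                )
            )
    allergy = allergy_section_spans(note.text)
    if allergy:
        rows = [
            replace(r, allergen_flag=True)
            if any(a <= r.span_start and r.span_end <= b for a, b in allergy)
            else r
            for r in rows
        ]
    rows.sort(key=lambda r: (r.span_start, r.span_end, r.category, r.concept_id))
    return rows


def extract_all(
    notes: Iterable[Note],
    lexicons: Lexicon | Mapping[str, Lexicon],
    rules: Optional[Sequence[TriggerRule]] = None,
    config: ExtractionConfig = ExtractionConfig(),
) -> list[NoteNlpRow]:
    """Extraction over many notes, concatenated in note order."""
    out: list[NoteNlpRow] = []
    for note in notes:
        out.extend(extract_note(note, lexicons, rules, config))
    return out
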