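"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by naive enumeration (BFS closures,
quadratic substring scans, exhaustive pairwise comparisons, per-evidence
re-evaluation) and share no code path with the package internals they check.
"""

from __future__ import annotations

import datetime as _dt
from collections import deque

from trialmatch.vocabulary import normalize_surface


def bfs_descendants(children: dict[str, list[str]], node: str) -> set[str]:
    """Reflexive descendant closure by plain breadth-first traversal."""
    seen = {node}
    queue = deque([node])
    while queue:
        for child in children.get(queue.popleft(), ()):
            if child not in seen:
                seen.add(child)
                queue.append(child)
    return seen


def _word_boundaries(text: str) -> tuple[list[int], list[int]]:
    def is_word(ch: str) -> bool:
        return ch.isalnum() or ch == "_"

    starts = [i for i, ch in enumerate(text) if is_word(ch) and (i == 0 or not is_word(text[i - 1]))]
    ends = [i + 1 for i, ch in enumerate(text) if is_word(ch) and (i + 1 == len(text) or not is_word(text[i + 1]))]
    return starts, ends


def brute_force_mentions(text: str, entries: dict[str, tuple[str, str]]) -> set[tuple[int, int, str]]:
    """All leftmost-longest non-overlapping dictionary matches of one
    category's entries, via a quadratic scan over word-boundary substrings.

    Returns {(start, end, concept_id)}.
    """
    if not entries:
        return set()
    starts, ends = _word_boundaries(text)
    max_chars = max(len(k) for k in entries) + 16
    all_matches = []
    for s in starts:
        for e in ends:
            if e <= s or e - s > max_chars:
                continue
            if "." in text[s:e] or "\n" in text[s:e]:
                continue  # the extractor never crosses sentence boundaries
            key = normalize_surface(text[s:e])
            if key in entries:
                all_matches.append((s, e, entries[key][0]))
    all_matches.sort(key=lambda m: (m[0], -m[1]))
    chosen: list[tuple[int, int, str]] = []
    last_end = -1
    for s, e, cid in all_matches:
        if s >= last_end:
            chosen.append((s, e, cid))
            last_end = e
    return set(chosen)


def pairwise_auc(scores, labels) -> float:
    """AUC by exhaustive enumeration of positive-negative pairs, ties 0.5."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Naive matching evaluator
# ---------------------------------------------------------------------------


def _naive_descendants(vocab, cid: str) -> set[str]:
    children: dict[str, list[str]] = {}
    for child, parent in vocab.is_a_edges:
        children.setdefault(parent, []).append(child)
    return bfs_descendants(children, cid)


def _naive_concepts(vocab, criterion, which: str) -> set[str]:
    ids = criterion.concept_ids if which == "primary" else criterion.second_concept_ids
    out: set[str] = set()
    for cid in ids:
        if criterion.include_descendants:
            out |= _naive_descendants(vocab, cid)
        else:
            out.add(cid)
    return out


def _naive_qualifies(attrs, criterion, policy) -> bool:
    if attrs.negated and policy.require_not_negated:
        return False
    if attrs.uncertain and policy.require_not_uncertain:
        return False
    if attrs.conditional and policy.require_not_conditional:
        return False
    if attrs.generic and policy.require_not_generic:
        return False
    if attrs.not_about_patient and policy.require_about_patient:
        return False
    if attrs.historical and not (criterion.allow_historical or policy.allow_historical):
        return False
    return True


def naive_criterion_verdicts(store, vocab, trial, policy, as_of: _dt.date) -> dict[tuple[str, str], bool]:
    """Met/not-met verdict per (person_id, criterion_id), computed by direct
    enumeration over every event and NLP row, with independent logic."""
    from trialmatch.vocabulary import AGE_CONCEPT_ID, GENDER_BY_CONCEPT_ID

    note_by_id = {n.note_id: n for n in store.notes}
    verdicts: dict[tuple[str, str], bool] = {}
    for person in store.persons:
        pid = person.person_id
        my_events = [e for e in store.events if e.person_id == pid] if policy.use_structured else []
        my_rows = (
            [r for r in store.note_nlp if note_by_id[r.note_id].person_id == pid]
            if policy.use_nlp
            else []
        )
        for criterion in trial.criteria:
            primary = _naive_concepts(vocab, criterion, "primary")
            secondary = _naive_concepts(vocab, criterion, "secondary")

            def q_events(concepts):
                return [e for e in my_events if e.concept_id in concepts]

            def q_rows(concepts):
                return [
                    r
                    for r in my_rows
                    if r.concept_id in concepts and _naive_qualifies(r.attributes, criterion, policy)
                ]

            satisfied = None
            if criterion.kind == "concept_presence":
                satisfied = bool(q_events(primary) or q_rows(primary))
            elif criterion.kind == "age_threshold":
                age = None
                if person.birth_date is not None:
                    b = person.birth_date
                    age = as_of.year - b.year - ((as_of.month, as_of.day) < (b.month, b.day))
                else:
                    cands = [
                        (note_by_id[r.note_id].note_date, r.numeric_value)
                        for r in q_rows({AGE_CONCEPT_ID})
                        if r.numeric_value is not None
                    ]
                    if cands:
                        age = max(cands)[1]
                if age is None:
                    verdicts[(pid, criterion.criterion_id)] = False
                    continue
                satisfied = _cmp(criterion.comparator, age, criterion.threshold)
            elif criterion.kind == "gender_equals":
                target = GENDER_BY_CONCEPT_ID[criterion.concept_ids[0]]
                gender = person.gender if person.gender != "unknown" else None
                if gender is None:
                    cands = [
                        (note_by_id[r.note_id].note_date, r.concept_id)
                        for r in q_rows(set(GENDER_BY_CONCEPT_ID))
                    ]
                    if cands:
                        gender = GENDER_BY_CONCEPT_ID[max(cands)[1]]
                if gender is None:
                    verdicts[(pid, criterion.criterion_id)] = False
                    continue
                satisfied = gender == target
            elif criterion.kind == "temporal_order":
                da = [e.event_date for e in q_events(primary)] + [note_by_id[r.note_id].note_date for r in q_rows(primary)]
                db = [e.event_date for e in q_events(secondary)] + [note_by_id[r.note_id].note_date for r in q_rows(secondary)]
                if not da or not db:
                    verdicts[(pid, criterion.criterion_id)] = False
                    continue
                satisfied = min(da) < min(db)
            elif criterion.kind == "value_range":
                vals = [(e.value, e.unit) for e in q_events(primary) if e.value is not None]
                vals += [(r.numeric_value, r.unit) for r in q_rows(primary) if r.numeric_value is not None]
                if criterion.unit is not None:
                    vals = [(v, u) for v, u in vals if u is None or u.casefold() == criterion.unit.casefold()]
                satisfied = any(_cmp(criterion.comparator, v, criterion.threshold) for v, _ in vals)
            met = satisfied if criterion.polarity == "inclusion" else not satisfied
            verdicts[(pid, criterion.criterion_id)] = met
    return verdicts


def _cmp(op, a, b):
    return {"ge": a >= b, "gt": a > b, "le": a <= b, "lt": a < b, "eq": a == b}[op]
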