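"""Scoring of extraction output and of trial-level matching.

Extraction is scored against gold standoff annotations: spans are aligned
per category (exact-span by default, or one-to-one greedy overlap matching),
yielding TP/FP/FN confusion counts per category, from which
recall = TP/(TP+FN), precision = TP/(TP+FP) and F1 are computed, with the
0/0 -> 0 convention throughout.  A micro row pools counts across categories;
macro rows average per-category metrics over the categories selected by the
macro policy (default: categories with at least one predicted positive,
i.e. TP+FP > 0).  Macro rows average the per-category values at report
precision (default three decimals), matching how such tables are
conventionally summarized.

Trial-level matching is scored with sensitivity, positive predictive value,
and a rank-based ROC AUC (tied scores credited 0.5 per positive-negative
pair).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .clinical_store import ContextAttributes, Note, NoteNlpRow
from .vocabulary import AGE_CONCEPT_ID, GENDER_BY_CONCEPT_ID


@dataclass(frozen=True)
class ReferenceAnnotation:
    """One gold standoff annotation: a span with a category, optionally a
    concept, context attributes, an allergen flag and a numeric value."""

    note_id: str
    start: int
    end: int
    category: str
    concept_id: Optional[str] = None
    attributes: Optional[ContextAttributes] = None
    allergen: bool = False
    value: Optional[float] = None
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"annotation in note {self.note_id!r}: invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class ConfusionCounts:
    category: str
    tp: int
    fp: int
    fn: int
    n_reference: Optional[int] = None  # informational; legacy tables may not satisfy tp+fn

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    recall = _safe_div(tp, tp + fn)
    precision = _safe_div(tp, tp + fp)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return recall, precision, f1


@dataclass(frozen=True)
class CategoryMetrics:
    category: str
    n_reference: Optional[int]
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f1: float


@dataclass(frozen=True)
class MetricsTable:
    """Per-category rows plus micro and macro summary rows."""

    rows: tuple[CategoryMetrics, ...]
    micro: tuple[float, float, float]
    macro: tuple[float, float, float]
    macro_policy: str
    macro_categories: tuple[str, ...]

    def to_dataframe(self, decimals: int = 3) -> pd.DataFrame:
        recs = [
            {
                "category": r.category,
                "n_reference": r.n_reference,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "recall": round(r.recall, decimals),
                "precision": round(r.precision, decimals),
                "f1": round(r.f1, decimals),
            }
            for r in self.rows
        ]
        for name, (rec, prec, f1) in (("micro", self.micro), ("macro", self.macro)):
            recs.append(
                {
                    "category": name,
                    "n_reference": None,
                    "tp": None,
                    "fp": None,
                    "fn": None,
                    "recall": round(rec, decimals),
                    "precision": round(prec, decimals),
                    "f1": round(f1, decimals),
                }
            )
        return pd.DataFrame(recs)

    def to_json(self, decimals: int = 3) -> str:
        return json.dumps(
            {
                "categories": [
                    {
                        "category": r.category,
                        "n_reference": r.n_reference,
                        "tp": r.tp,
                        "fp": r.fp,
                        "fn": r.fn,
                        "recall": round(r.recall, decimals),
                        "precision": round(r.precision, decimals),
                        "f1": round(r.f1, decimals),
                    }
                    for r in self.rows
                ],
                "micro": dict(zip(("recall", "precision", "f1"), (round(v, decimals) for v in self.micro))),
                "macro": dict(zip(("recall", "precision", "f1"), (round(v, decimals) for v in self.macro))),
                "macro_policy": self.macro_policy,
                "macro_categories": list(self.macro_categories),
            },
            indent=2,
        )


def compute_metrics(
    counts: Sequence[ConfusionCounts],
    macro_policy: str = "predicted",
    decimals: int = 3,
) -> MetricsTable:
    """Compute per-category, micro and macro recall/precision/F1.

    ``macro_policy``: ``"predicted"`` averages over categories with TP+FP > 0
    (categories the system never predicted do not drag precision and F1 to
    zero); ``"all"`` averages over every category.  Macro rows are means of
    the per-category values rounded to ``decimals``.
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    rows = tuple(
        CategoryMetrics(c.category, c.n_reference, c.tp, c.fp, c.fn, *_prf(c.tp, c.fp, c.fn))
        for c in counts
    )
    tp = sum(c.tp for c in counts)
    fp = sum(c.fp for c in counts)
    fn = sum(c.fn for c in counts)
    micro = _prf(tp, fp, fn)
    if macro_policy == "predicted":
        selected = [r for r in rows if r.tp + r.fp > 0]
    elif macro_policy == "all":
        selected = list(rows)
    else:
        raise ValueError(f"unknown macro_policy {macro_policy!r}")
    if selected:
        macro = tuple(
            float(np.mean([round(getattr(r, m), decimals) for r in selected]))
            for m in ("recall", "precision", "f1")
        )
    else:
        macro = (0.0, 0.0, 0.0)
    return MetricsTable(rows, micro, macro, macro_policy, tuple(r.category for r in selected))


# ---------------------------------------------------------------------------
# Span alignment
# ---------------------------------------------------------------------------

SpanItem = tuple[str, int, int, str]  # (note_id, start, end, category)


def prediction_items(rows: Iterable[NoteNlpRow]) -> list[SpanItem]:
    """Map NOTE_NLP rows to evaluation items.

    Demographic rows are split into ``age``/``gender`` categories by concept;
    everything else evaluates under its extraction category.
    """
    items: list[SpanItem] = []
    for r in rows:
        if r.category == "demographic":
            cat = "age" if r.concept_id == AGE_CONCEPT_ID else "gender"
        else:
            cat = r.category
        items.append((r.note_id, r.span_start, r.span_end, cat))
    return items


def reference_items(annotations: Iterable[ReferenceAnnotation]) -> list[SpanItem]:
    return [(a.note_id, a.start, a.end, a.category) for a in annotations]


def align(
    predicted: Sequence[NoteNlpRow] | Sequence[SpanItem],
    reference: Sequence[ReferenceAnnotation] | Sequence[SpanItem],
    policy: str = "exact_span",
    notes: Optional[Mapping[str, Note]] = None,
) -> list[ConfusionCounts]:
    """Align predicted spans with reference spans per category.

    ``exact_span``: a true positive needs identical (note, start, end,
    category).  ``overlap``: same-category overlapping spans are matched
    one-to-one greedily, preferring larger overlap, then earlier reference
    start, then earlier predicted start.  Unmatched predictions are FP,
    unmatched references FN.  When ``notes`` is given, reference spans beyond
    the note bounds are a hard error.
    """
    pred = prediction_items(predicted) if predicted and isinstance(predicted[0], NoteNlpRow) else [tuple(p) for p in predicted]
    if reference and isinstance(reference[0], ReferenceAnnotation):
        if notes is not None:
            for a in reference:
                note = notes.get(a.note_id)
                if note is None or a.end > len(note.text):
                    raise ValueError(f"reference span {a.start}-{a.end} out of bounds for note {a.note_id!r}")
        ref = reference_items(reference)
    else:
        ref = [tuple(r) for r in reference]

    categories = sorted({c for *_, c in pred} | {c for *_, c in ref})
    out: list[ConfusionCounts] = []
    for cat in categories:
        p = [x for x in pred if x[3] == cat]
        r = [x for x in ref if x[3] == cat]
        if policy == "exact_span":
            from collections import Counter

            pc, rc = Counter(p), Counter(r)
            tp = sum(min(pc[k], rc[k]) for k in pc.keys() & rc.keys())
        elif policy == "overlap":
            pairs = []
            for i, (pn, ps, pe, _) in enumerate(p):
                for j, (rn, rs, re_, _) in enumerate(r):
                    if pn == rn and ps < re_ and rs < pe:
                        pairs.append((-(min(pe, re_) - max(ps, rs)), rs, ps, i, j))
            pairs.sort()
            used_p: set[int] = set()
            used_r: set[int] = set()
            tp = 0
            for _, _, _, i, j in pairs:
                if i in used_p or j in used_r:
                    continue
                used_p.add(i)
                used_r.add(j)
                tp += 1
        else:
            raise ValueError(f"unknown alignment policy {policy!r}")
        out.append(ConfusionCounts(cat, tp, len(p) - tp, len(r) - tp, n_reference=len(r)))
    return out


# ---------------------------------------------------------------------------
# Gold standoff TSV
# ---------------------------------------------------------------------------

_GOLD_HEADER = "note_id\tstart\tend\tcategory\tconcept_id\tattribute_flags\tvalue\tunit"


def write_gold(annotations: Sequence[ReferenceAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_GOLD_HEADER + "\n")
        for a in annotations:
            flags = list(a.attributes.set_flags()) if a.attributes else []
            if a.allergen:
                flags.append("allergen")
            fh.write(
                "\t".join(
                    [
                        a.note_id,
                        str(a.start),
                        str(a.end),
                        a.category,
                        a.concept_id or "",
                        ";".join(flags) or "-",
                        "" if a.value is None else repr(a.value),
                        a.unit or "",
                    ]
                )
                + "\n"
            )


def read_gold(path: str | Path) -> list[ReferenceAnnotation]:
    annotations: list[ReferenceAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _GOLD_HEADER:
            raise ValueError(f"unexpected gold TSV header: {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            note_id, start, end, category, concept_id, flags, value, unit = line.split("\t")
            flag_set = set() if flags == "-" else set(flags.split(";"))
            attrs = ContextAttributes(**{f: f in flag_set for f in ContextAttributes.FLAGS})
            annotations.append(
                ReferenceAnnotation(
                    note_id,
                    int(start),
                    int(end),
                    category,
                    concept_id or None,
                    attrs,
                    allergen="allergen" in flag_set,
                    value=float(value) if value else None,
                    unit=unit or None,
                )
            )
    return annotations


# ---------------------------------------------------------------------------
# Trial-level accuracy
# ---------------------------------------------------------------------------


def match_accuracy(
    scores: Mapping[str, float],
    labels: Mapping[str, bool],
    threshold: float = 1.0,
) -> tuple[float, float]:
    """Sensitivity and positive predictive value of thresholded match scores.

    ``scores`` maps person_id to score fraction; a person is predicted
    positive when score >= threshold.  ``labels`` must cover every scored
    person.  0/0 cases yield 0.
    """
    missing = set(scores) - set(labels)
    if missing:
        raise ValueError(f"labels missing for persons: {sorted(missing)[:5]}")
    tp = fp = fn = 0
    for pid, score in scores.items():
        predicted = score >= threshold
        actual = labels[pid]
        if predicted and actual:
            tp += 1
        elif predicted and not actual:
            fp += 1
        elif actual:
            fn += 1
    return _safe_div(tp, tp + fn), _safe_div(tp, tp + fp)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-based ROC AUC: the probability a random positive outscores a
    random negative, ties credited 0.5 (computed via mid-ranks)."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires at least one positive and one negative label")
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0  # mid-rank, 1-based
        i = j + 1
    pos_rank_sum = float(ranks[y].sum())
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
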