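"""Mini clinical terminology: concepts, synonyms, is-a hierarchy, and lexicons.

This module plays the role a licensed terminology service (UMLS, SNOMED CT,
RxNorm) plays in production eligibility-surveillance systems, at desk scale:
a self-contained table of coded concepts with synonyms and an acyclic is-a
hierarchy.  Two things are derived from it:

* **descendant closure** — ``descendants`` returns the reflexive-transitive
  closure of a concept under is-a, used to expand "include children of the
  selected concept" style criteria;
* **lexicons** — ``build_lexicon`` turns a seed set of concepts into a
  surface-form dictionary (preferred names plus synonyms, optionally of all
  descendants) used by the dictionary-based extractor.
"""

from __future__ import annotations

import string
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

CATEGORIES: tuple[str, ...] = (
    "condition",
    "investigation",
    "medication",
    "procedure",
    "device",
    "demographic",
)

# Canonical demographic concept ids.  Demographic findings (age, gender) are
# pattern-extracted rather than dictionary-matched, but they still need concept
# ids so they can flow through NOTE_NLP rows and criteria.
AGE_CONCEPT_ID = "DEMO_AGE"
GENDER_FEMALE_CONCEPT_ID = "DEMO_GENDER_F"
GENDER_MALE_CONCEPT_ID = "DEMO_GENDER_M"
GENDER_CONCEPT_IDS: Mapping[str, str] = {
    "female": GENDER_FEMALE_CONCEPT_ID,
    "male": GENDER_MALE_CONCEPT_ID,
}
GENDER_BY_CONCEPT_ID: Mapping[str, str] = {v: k for k, v in GENDER_CONCEPT_IDS.items()}

_DASHES = str.maketrans({"-": " ", "‐": " ", "–": " ", "—": " "})
_EDGE_PUNCT = string.punctuation + string.whitespace

NORMALIZATION_POLICY = "casefold; dash->space; collapse whitespace; strip edge punctuation"


def normalize_surface(surface: str) -> str:
    """Normalize a surface form for dictionary lookup.

    Case-folds, maps dash characters to spaces (so ``graft-versus-host
    disease`` and ``graft versus host disease`` normalize identically),
    collapses internal whitespace, and strips leading/trailing punctuation.
    """
    s = surface.casefold().translate(_DASHES)
    s = " ".join(s.split())
    return s.strip(_EDGE_PUNCT)


@dataclass(frozen=True)
class Concept:
    """A coded clinical concept with synonyms."""

    concept_id: str
    code: str
    vocabulary_name: str
    preferred_name: str
    category: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise ValueError("concept_id must be non-empty")
        if not self.preferred_name:
            raise ValueError(f"concept {self.concept_id!r}: preferred_name must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"concept {self.concept_id!r}: category {self.category!r} not one of {CATEGORIES}"
            )

    def names(self, include_synonyms: bool = True) -> tuple[str, ...]:
        return (self.preferred_name, *self.synonyms) if include_synonyms else (self.preferred_name,)


class VocabularyStore:
    """Concepts plus an acyclic is-a hierarchy.

    ``is_a_edges`` are (child_id, parent_id) pairs.  Construction validates
    referential integrity and acyclicity; a detected cycle is reported with one
    concrete cycle path.
    """

    def __init__(self, concepts: Iterable[Concept], is_a_edges: Iterable[tuple[str, str]] = ()):
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.concept_id in self.concepts:
                raise ValueError(f"duplicate concept_id {c.concept_id!r}")
            self.concepts[c.concept_id] = c
        self.is_a_edges: tuple[tuple[str, str], ...] = tuple(sorted(set(is_a_edges)))
        self._children: dict[str, list[str]] = {cid: [] for cid in self.concepts}
        self._parents: dict[str, list[str]] = {cid: [] for cid in self.concepts}
        for child, parent in self.is_a_edges:
            for endpoint in (child, parent):
                if endpoint not in self.concepts:
                    raise ValueError(f"is-a edge ({child!r}, {parent!r}) references unknown concept {endpoint!r}")
            self._children[parent].append(child)
            self._parents[child].append(parent)
        for adj in (self._children, self._parents):
            for lst in adj.values():
                lst.sort()
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        indeg = {cid: len(self._parents[cid]) for cid in self.concepts}
        queue = deque(cid for cid, d in indeg.items() if d == 0)
        seen = 0
        while queue:
            cid = queue.popleft()
            seen += 1
            for child in self._children[cid]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if seen == len(self.concepts):
            return
        # Walk parent links from a node still on a cycle to exhibit one cycle.
        start = min(cid for cid, d in indeg.items() if d > 0)
        path, node = [start], start
        while True:
            node = min(p for p in self._parents[node] if indeg[p] > 0)
            if node in path:
                cycle = path[path.index(node):] + [node]
                raise ValueError(f"is-a hierarchy contains a cycle: {' -> '.join(cycle)}")
            path.append(node)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def concept(self, concept_id: str) -> Concept:
        try:
            return self.concepts[concept_id]
        except KeyError:
            raise KeyError(f"unknown concept_id {concept_id!r}") from None

    def children(self, concept_id: str) -> tuple[str, ...]:
        self.concept(concept_id)
        return tuple(self._children[concept_id])

    def parents(self, concept_id: str) -> tuple[str, ...]:
        self.concept(concept_id)
        return tuple(self._parents[concept_id])

    def descendants(self, concept_id: str) -> frozenset[str]:
        """Reflexive-transitive descendant closure of ``concept_id`` under is-a."""
        self.concept(concept_id)
        seen = {concept_id}
        queue = deque([concept_id])
        while queue:
            for child in self._children[queue.popleft()]:
                if child not in seen:
                    seen.add(child)
                    queue.append(child)
        return frozenset(seen)

    def descendant_depths(self, seeds: Sequence[str]) -> dict[str, int]:
        """Minimum is-a hop count from any seed, walking child edges (multi-source BFS)."""
        for s in seeds:
            self.concept(s)
        depths = {s: 0 for s in seeds}
        queue = deque(seeds)
        while queue:
            cid = queue.popleft()
            for child in self._children[cid]:
                if child not in depths:
                    depths[child] = depths[cid] + 1
                    queue.append(child)
        return depths


@dataclass(frozen=True)
class Lexicon:
    """Normalized surface form -> (concept_id, category) dictionary."""

    entries: Mapping[str, tuple[str, str]]
    normalization_policy: str = NORMALIZATION_POLICY

    def __len__(self) -> int:
        return len(self.entries)

    def categories(self) -> tuple[str, ...]:
        return tuple(sorted({cat for _, cat in self.entries.values()}))

    def split_by_category(self) -> dict[str, "Lexicon"]:
        buckets: dict[str, dict[str, tuple[str, str]]] = {}
        for surface, (cid, cat) in self.entries.items():
            buckets.setdefault(cat, {})[surface] = (cid, cat)
        return {cat: Lexicon(entries, self.normalization_policy) for cat, entries in sorted(buckets.items())}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for surface in sorted(self.entries):
                cid, cat = self.entries[surface]
                fh.write(f"{surface}\t{cid}\t{cat}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        entries: dict[str, tuple[str, str]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                surface, cid, cat = line.split("\t")
                entries[surface] = (cid, cat)
        return cls(entries)


def load_vocabulary(concept_table: str | Path, relation_table: str | Path | None = None) -> VocabularyStore:
    """Load a :class:`VocabularyStore` from CSV tables.

    The concept table needs columns ``concept_id,code,vocabulary,name,category,
    synonyms`` (synonyms pipe-delimited, empty allowed); the relation table
    needs ``child_id,parent_id``.
    """
    cdf = pd.read_csv(concept_table, dtype=str, keep_default_na=False)
    required = {"concept_id", "code", "vocabulary", "name", "category", "synonyms"}
    missing = required - set(cdf.columns)
    if missing:
        raise ValueError(f"concept table missing columns: {sorted(missing)}")
    concepts = [
        Concept(
            concept_id=row.concept_id,
            code=row.code,
            vocabulary_name=row.vocabulary,
            preferred_name=row.name,
            category=row.category,
            synonyms=tuple(s for s in row.synonyms.split("|") if s),
        )
        for row in cdf.itertuples(index=False)
    ]
    edges: list[tuple[str, str]] = []
    if relation_table is not None:
        rdf = pd.read_csv(relation_table, dtype=str, keep_default_na=False)
        rmissing = {"child_id", "parent_id"} - set(rdf.columns)
        if rmissing:
            raise ValueError(f"relation table missing columns: {sorted(rmissing)}")
        edges = [(r.child_id, r.parent_id) for r in rdf.itertuples(index=False)]
    return VocabularyStore(concepts, edges)


def write_vocabulary(store: VocabularyStore, concept_table: str | Path, relation_table: str | Path) -> None:
    """Inverse of :func:`load_vocabulary` (sorted, round-trip stable)."""
    cdf = pd.DataFrame(
        [
            {
                "concept_id": c.concept_id,
                "code": c.code,
                "vocabulary": c.vocabulary_name,
                "name": c.preferred_name,
                "category": c.category,
                "synonyms": "|".join(c.synonyms),
            }
            for c in sorted(store.concepts.values(), key=lambda c: c.concept_id)
        ],
        columns=["concept_id", "code", "vocabulary", "name", "category", "synonyms"],
    )
    cdf.to_csv(concept_table, index=False)
    rdf = pd.DataFrame(list(store.is_a_edges), columns=["child_id", "parent_id"])
    rdf.to_csv(relation_table, index=False)


def build_lexicon(
    store: VocabularyStore,
    seeds: Sequence[str],
    expand_descendants: bool = True,
    include_synonyms: bool = True,
) -> Lexicon:
    """Generate a lexicon from seed concepts.

    Each seed (and, with ``expand_descendants``, each is-a descendant)
    contributes its preferred name and, with ``include_synonyms``, all
    synonyms.  When two concepts contribute the same normalized surface, the
    concept closest to a seed (fewest is-a hops) wins; ties break on the
    lexicographically smallest concept_id.
    """
    for s in seeds:
        store.concept(s)
    if expand_descendants:
        depths = store.descendant_depths(list(seeds))
    else:
        depths = {s: 0 for s in seeds}
    best: dict[str, tuple[int, str]] = {}
    for cid in sorted(depths):
        concept = store.concept(cid)
        for name in concept.names(include_synonyms):
            key = normalize_surface(name)
            if not key:
                raise ValueError(f"concept {cid!r}: surface {name!r} is empty after normalization")
            cand = (depths[cid], cid)
            if key not in best or cand < best[key]:
                best[key] = cand
    entries = {
        surface: (cid, store.concept(cid).category)
        for surface, (_, cid) in sorted(best.items())
    }
    return Lexicon(entries)


def build_full_lexicon(store: VocabularyStore, include_synonyms: bool = True) -> Lexicon:
    """Lexicon over every non-demographic concept in the store."""
    seeds = sorted(cid for cid, c in store.concepts.items() if c.category != "demographic")
    return build_lexicon(store, seeds, expand_descendants=False, include_synonyms=include_synonyms)
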