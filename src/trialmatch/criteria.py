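"""Executable trial eligibility criteria and their JSON dialect.

A trial definition is a small JSON document: trial metadata plus a list of
criteria.  Each criterion has a polarity (inclusion/exclusion) and one of
five rule kinds:

* ``concept_presence`` — the patient has (inclusion) / must not have
  (exclusion) evidence of any concept in the set, optionally expanded to
  is-a descendants ("include children of the selected concept");
* ``age_threshold`` — e.g. age >= 18 years at the evaluation date;
* ``gender_equals`` — gender matches the demographic gender concept named in
  ``concept_ids``;
* ``temporal_order`` — the earliest evidence of concept set A strictly
  precedes the earliest evidence of concept set B (``second_concept_ids``);
* ``value_range`` — at least one measurement of a concept in the set
  satisfies comparator/threshold (optionally unit-checked).

The machine-readable schema ships in ``schemas/trial_definition.schema.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Optional, Sequence

from .vocabulary import GENDER_BY_CONCEPT_ID, VocabularyStore

POLARITIES = ("inclusion", "exclusion")
KINDS = ("concept_presence", "age_threshold", "gender_equals", "temporal_order", "value_range")
COMPARATORS = ("ge", "gt", "le", "lt", "eq")

_CRITERION_FIELDS = {
    "criterion_id", "polarity", "kind", "concept_ids", "include_descendants",
    "comparator", "threshold", "unit", "second_concept_ids", "allow_historical",
}
_TRIAL_FIELDS = {"trial_id", "registry_id", "title", "principal_investigator", "criteria"}


@dataclass(frozen=True)
class Criterion:
    criterion_id: str
    polarity: str
    kind: str
    concept_ids: tuple[str, ...] = ()
    include_descendants: bool = False
    comparator: Optional[str] = None
    threshold: Optional[float] = None
    unit: Optional[str] = None
    second_concept_ids: tuple[str, ...] = ()
    allow_historical: bool = True

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValueError(f"criterion {self.criterion_id!r}: polarity {self.polarity!r} not in {POLARITIES}")
        if self.kind not in KINDS:
            raise ValueError(f"criterion {self.criterion_id!r}: kind {self.kind!r} not in {KINDS}")
        if self.comparator is not None and self.comparator not in COMPARATORS:
            raise ValueError(f"criterion {self.criterion_id!r}: comparator {self.comparator!r} not in {COMPARATORS}")


@dataclass(frozen=True)
class TrialDefinition:
    trial_id: str
    registry_id: str = ""
    title: str = ""
    principal_investigator: str = ""
    criteria: tuple[Criterion, ...] = ()

    def __post_init__(self) -> None:
        if len(self.criteria) < 1:
            raise ValueError(f"trial {self.trial_id!r}: at least one criterion required")
        ids = [c.criterion_id for c in self.criteria]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"trial {self.trial_id!r}: duplicate criterion_id(s) {dup}")

    @property
    def n_total(self) -> int:
        return len(self.criteria)

    def criterion(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.criterion_id == criterion_id:
                return c
        raise KeyError(f"trial {self.trial_id!r}: unknown criterion {criterion_id!r}")


def _parse_criterion(obj: Mapping[str, Any], path: str, strict: bool) -> Criterion:
    if not isinstance(obj, Mapping):
        raise ValueError(f"{path}: expected an object")
    unknown = set(obj) - _CRITERION_FIELDS
    if unknown:
        msg = f"{path}: unknown field(s) {sorted(unknown)}"
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    for req in ("criterion_id", "polarity", "kind"):
        if req not in obj:
            raise ValueError(f"{path}.{req}: required field missing")
    return Criterion(
        criterion_id=str(obj["criterion_id"]),
        polarity=obj["polarity"],
        kind=obj["kind"],
        concept_ids=tuple(obj.get("concept_ids", ())),
        include_descendants=bool(obj.get("include_descendants", False)),
        comparator=obj.get("comparator"),
        threshold=None if obj.get("threshold") is None else float(obj["threshold"]),
        unit=obj.get("unit"),
        second_concept_ids=tuple(obj.get("second_concept_ids", ())),
        allow_historical=bool(obj.get("allow_historical", True)),
    )


def parse_trial_definition(document: str | Mapping[str, Any], strict: bool = True) -> TrialDefinition:
    """Parse a trial definition from JSON text (or an already-decoded mapping).

    In strict mode unknown fields are rejected, naming the JSON path; in
    lenient mode they produce a warning.
    """
    obj = json.loads(document) if isinstance(document, str) else document
    if not isinstance(obj, Mapping):
        raise ValueError("$: expected a JSON object")
    unknown = set(obj) - _TRIAL_FIELDS
    if unknown:
        msg = f"$: unknown field(s) {sorted(unknown)}"
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    if "trial_id" not in obj:
        raise ValueError("$.trial_id: required field missing")
    if "criteria" not in obj or not isinstance(obj["criteria"], Sequence):
        raise ValueError("$.criteria: required array missing")
    criteria = tuple(
        _parse_criterion(c, f"$.criteria[{i}]", strict) for i, c in enumerate(obj["criteria"])
    )
    return TrialDefinition(
        trial_id=str(obj["trial_id"]),
        registry_id=str(obj.get("registry_id", "")),
        title=str(obj.get("title", "")),
        principal_investigator=str(obj.get("principal_investigator", "")),
        criteria=criteria,
    )


def criterion_to_dict(c: Criterion) -> dict[str, Any]:
    return {
        "criterion_id": c.criterion_id,
        "polarity": c.polarity,
        "kind": c.kind,
        "concept_ids": list(c.concept_ids),
        "include_descendants": c.include_descendants,
        "comparator": c.comparator,
        "threshold": c.threshold,
        "unit": c.unit,
        "second_concept_ids": list(c.second_concept_ids),
        "allow_historical": c.allow_historical,
    }


def serialize_trial_definition(trial: TrialDefinition, indent: int = 2) -> str:
    doc = {
        "trial_id": trial.trial_id,
        "registry_id": trial.registry_id,
        "title": trial.title,
        "principal_investigator": trial.principal_investigator,
        "criteria": [criterion_to_dict(c) for c in trial.criteria],
    }
    return json.dumps(doc, indent=indent, sort_keys=True)


def load_trials(path) -> list[TrialDefinition]:
    """Load a JSON file holding either one trial object or an array of them."""
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if isinstance(obj, list):
        return [parse_trial_definition(t) for t in obj]
    return [parse_trial_definition(obj)]


def save_trials(trials: Sequence[TrialDefinition], path) -> None:
    docs = [json.loads(serialize_trial_definition(t)) for t in trials]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(docs, fh, indent=2, sort_keys=True)
        fh.write("\n")


def validate_criteria(trial: TrialDefinition, store: VocabularyStore) -> list[str]:
    """Validate a trial against a vocabulary; returns a list of issues
    (empty means valid).  Never raises for content problems."""
    issues: list[str] = []
    for c in trial.criteria:
        where = f"criterion {c.criterion_id!r}"
        for cid in (*c.concept_ids, *c.second_concept_ids):
            if cid not in store:
                issues.append(f"{where}: unresolved concept_id {cid!r}")
        if c.kind == "concept_presence":
            if not c.concept_ids:
                issues.append(f"{where}: concept_presence requires a non-empty concept set")
        elif c.kind == "age_threshold":
            if c.comparator is None or c.threshold is None:
                issues.append(f"{where}: age_threshold requires comparator and threshold")
        elif c.kind == "gender_equals":
            targets = [cid for cid in c.concept_ids if cid in GENDER_BY_CONCEPT_ID]
            if len(c.concept_ids) != 1 or not targets:
                issues.append(f"{where}: gender_equals requires exactly one demographic gender concept")
        elif c.kind == "temporal_order":
            if not c.concept_ids or not c.second_concept_ids:
                issues.append(f"{where}: temporal_order requires both concept sets non-empty")
        elif c.kind == "value_range":
            if not c.concept_ids:
                issues.append(f"{where}: value_range requires a non-empty concept set")
            if c.comparator is None or c.threshold is None:
                issues.append(f"{where}: value_range requires comparator and threshold")
        if c.second_concept_ids and c.kind != "temporal_order":
            issues.append(f"{where}: second_concept_ids only meaningful for temporal_order")
    return issues


def expand_concept_sets(trial: TrialDefinition, store: VocabularyStore) -> TrialDefinition:
    """Materialize descendant closures for criteria with ``include_descendants``.

    Monotone (sets only grow) and idempotent (a closure is its own closure).
    """
    new_criteria = []
    for c in trial.criteria:
        if not c.include_descendants:
            new_criteria.append(c)
            continue
        primary = set()
        for cid in c.concept_ids:
            primary |= store.descendants(cid)
        secondary = set()
        for cid in c.second_concept_ids:
            secondary |= store.descendants(cid)
        new_criteria.append(
            replace(
                c,
                concept_ids=tuple(sorted(primary)),
                second_concept_ids=tuple(sorted(secondary)),
            )
        )
    return replace(trial, criteria=tuple(new_criteria))
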