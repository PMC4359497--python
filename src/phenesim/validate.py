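"""Automated curation quality assurance for EQ statement tables.

Implements the machine-checkable rules used to keep a multi-species curation
effort consistent:

* R1 — the primary entity is a plant structure (PO, or GO cellular component)
  or a biological process (GO biological process branch);
* R2 — quality and qualifier come from PATO;
* R3 — the quality type matches the entity type: a structural entity takes a
  quality of a physical object, a process entity takes a quality of a
  process (membership is decided against configured PATO subtree roots);
* R4 — every id resolves to a known, non-obsolete term (alt_id usage is a
  warning pointing at the canonical id; obsolete ids are errors carrying the
  ``replaced_by`` hint);
* R5 — a supplied term label matches the ontology label (case- and
  whitespace-insensitive), which catches typographical errors;
* R6 — relation ids come from the Relation Ontology (RO/BFO namespaces).

Issues are data, never exceptions: validation of a dirty table yields a
report, and a dataset that passes is safe for every downstream module.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .eqdata import Dataset, EQStatement, LABEL_COLUMNS
from .ontology import IS_A, Ontology, ObsoleteTermError, UnknownTermError

RULES = {
    "R1": "primary entity must be PO (structural), GO cellular_component, or GO biological_process",
    "R2": "quality and qualifier must be PATO terms",
    "R3": "quality type must match entity type (structural vs process)",
    "R4": "all ids must resolve to known, non-obsolete terms",
    "R5": "supplied labels must match ontology labels",
    "R6": "relations must come from the Relation Ontology",
}

_ENTITY_SLOTS = ("primary_e1", "primary_e2", "secondary_e1", "secondary_e2")
_RELATION_SLOTS = ("rel_primary", "rel_secondary")
_QUALITY_SLOTS = ("quality", "qualifier")


@dataclass(frozen=True)
class ValidationIssue:
    row: int
    rule_id: str
    severity: str  # "error" | "warning"
    message: str
    offending_value: str

    def __post_init__(self) -> None:
        if self.rule_id not in RULES:
            raise ValueError(f"unknown rule id {self.rule_id}")
        if self.severity not in ("error", "warning"):
            raise ValueError(f"invalid severity {self.severity}")


@dataclass(frozen=True)
class ValidationConfig:
    """Namespace conventions and PATO subtree roots the rules check against.

    The quality-type roots default to unset, which disables R3 — real runs
    point them at PATO's *quality of a physical object* and *quality of a
    process* subtrees; synthetic runs point them into the generated quality
    ontology.
    """

    structural_entity_prefixes: frozenset[str] = frozenset({"PO"})
    go_prefix: str = "GO"
    process_namespace: str = "biological_process"
    component_namespace: str = "cellular_component"
    quality_prefix: str = "PATO"
    relation_prefixes: frozenset[str] = frozenset({"RO", "BFO"})
    structural_quality_root: str | None = None
    process_quality_root: str | None = None


DEFAULT_CONFIG = ValidationConfig()

_WS = re.compile(r"\s+")


def _norm_label(label: str) -> str:
    return _WS.sub(" ", label.strip().lower())


def _prefix(curie: str) -> str:
    return curie.split(":", 1)[0]


def _entity_type(curie: str, ont: Ontology, config: ValidationConfig) -> str | None:
    """"process", "structural", or None when the namespace rules say neither."""
    prefix = _prefix(curie)
    if prefix in config.structural_entity_prefixes:
        return "structural"
    if prefix == config.go_prefix and curie in ont:
        ns = ont.term(curie).namespace
        if ns == config.process_namespace:
            return "process"
        if ns == config.component_namespace:
            return "structural"
    return None


def validate_statement(
    eq: EQStatement,
    labels: Mapping[str, str],
    ont: Ontology,
    config: ValidationConfig = DEFAULT_CONFIG,
    row: int = 0,
) -> list[ValidationIssue]:
    """All rule violations for one EQ statement; an empty list means clean."""
    issues: list[ValidationIssue] = []

    def add(rule: str, severity: str, message: str, value: str) -> None:
        issues.append(ValidationIssue(row, rule, severity, message, value))

    filled = eq.filled_slots()

    # R4: id resolution, obsolescence, alt-id hygiene — checked for every slot
    resolvable: dict[str, str] = {}
    for slot, curie in filled.items():
        try:
            canonical = ont.resolve(curie)
        except UnknownTermError:
            add("R4", "error", f"{slot}: id does not resolve in the merged ontology", curie)
            continue
        term = ont.terms[canonical]
        if term.obsolete:
            hint = f"; replaced_by {term.replaced_by}" if term.replaced_by else ""
            add("R4", "error", f"{slot}: id is obsolete{hint}", curie)
            continue
        if ont.is_alt(curie):
            add("R4", "warning", f"{slot}: non-canonical id, use {canonical}", curie)
        resolvable[slot] = canonical

    # R1: primary entity namespace
    etype = _entity_type(eq.primary_e1, ont, config)
    if etype is None:
        add(
            "R1", "error",
            "primary_e1 is not a PO structure, GO cellular component, or GO biological process",
            eq.primary_e1,
        )

    # R2: quality (and qualifier) from PATO
    for slot in _QUALITY_SLOTS:
        curie = filled.get(slot)
        if curie and _prefix(curie) != config.quality_prefix:
            add("R2", "error", f"{slot} must be a {config.quality_prefix} term", curie)

    # R3: quality type matches entity type
    root = {
        "structural": config.structural_quality_root,
        "process": config.process_quality_root,
    }.get(etype or "", None)
    # type matching only applies to genuine PATO qualities (R2 covers the rest)
    if (
        root is not None
        and "quality" in resolvable
        and _prefix(eq.quality) == config.quality_prefix
    ):
        anc = ont.ancestors(resolvable["quality"], relations={IS_A}, reflexive=True)
        if root not in anc:
            add(
                "R3", "error",
                f"quality is not a {etype} quality (not under {root})",
                eq.quality,
            )

    # R5: label/id agreement
    for slot, supplied in labels.items():
        canonical = resolvable.get(slot)
        if canonical is None:
            continue
        actual = ont.terms[canonical].label
        if _norm_label(supplied) != _norm_label(actual):
            add(
                "R5", "error",
                f"{slot} label {supplied!r} does not match ontology label; "
                f"did you mean {actual!r}?",
                supplied,
            )

    # R6: relations from RO
    for slot in _RELATION_SLOTS:
        curie = filled.get(slot)
        if curie and _prefix(curie) not in config.relation_prefixes:
            add("R6", "error", f"{slot} must come from the Relation Ontology", curie)

    return issues


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]
    n_rows: int = 0

    @property
    def errors(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "error")

    @property
    def warnings(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "warning")

    @property
    def passed(self) -> bool:
        return not self.errors

    def summary(self) -> dict[str, int]:
        counts = {rule: 0 for rule in RULES}
        for issue in self.issues:
            counts[issue.rule_id] += 1
        return counts

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "n_rows": self.n_rows,
            "n_errors": len(self.errors),
            "n_warnings": len(self.warnings),
            "summary": self.summary(),
            "issues": [vars(i) for i in self.issues],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def validate_dataset(
    ds: Dataset,
    ont: Ontology,
    config: ValidationConfig = DEFAULT_CONFIG,
) -> ValidationReport:
    """Aggregate per-row issues over a whole curation table."""
    issues: list[ValidationIssue] = []
    n_rows = 0
    for rec in ds.genotypes:
        for phene in rec.atomized:
            n_rows += 1
            issues.extend(
                validate_statement(
                    phene.eq, phene.labels, ont, config,
                    row=phene.source_row if phene.source_row is not None else n_rows,
                )
            )
    return ValidationReport(tuple(issues), n_rows=n_rows)
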