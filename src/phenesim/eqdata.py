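"""Entity-Quality phenotype data model and the canonical curation table.

A mutant phenotype is decomposed into atomized free-text phenes, each
translated into a post-composed Entity-Quality (EQ) statement built from
species-independent ontology terms.  The generalized shape is

    [(primary E1) - R - (primary E2)] - [Q - QL] - [(secondary E1) - R - (secondary E2)]

with the primary entity (PO structure or GO process) and the PATO quality
mandatory, and every other slot optional.  A genotype's phenotype is the set
of its EQ statements; alleles with separately described phenotypes are
separate genotypes.

The canonical on-disk form is a UTF-8 TSV with one atomized statement per
row; ids are authoritative and term labels are carried only so validation
can catch typographical errors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: fixed slot order used by canonical keys and the TSV dialect
SLOT_ORDER = (
    "primary_e1",
    "rel_primary",
    "primary_e2",
    "quality",
    "qualifier",
    "secondary_e1",
    "rel_secondary",
    "secondary_e2",
)

#: TSV column holding each slot id
SLOT_COLUMNS = {
    "primary_e1": "e1_id",
    "rel_primary": "relp_id",
    "primary_e2": "e2_id",
    "quality": "q_id",
    "qualifier": "ql_id",
    "secondary_e1": "se1_id",
    "rel_secondary": "serel_id",
    "secondary_e2": "se2_id",
}

LABEL_COLUMNS = {"primary_e1": "e1_label", "primary_e2": "e2_label", "quality": "q_label"}

REQUIRED_COLUMNS = (
    "species", "gene_id", "genotype_id", "phenotype_name", "phene_text",
    "e1_id", "q_id",
)

ALL_COLUMNS = (
    "species", "gene_id", "gene_symbol", "genotype_id", "phenotype_name",
    "phene_text", "e1_id", "e1_label", "relp_id", "e2_id", "e2_label",
    "q_id", "q_label", "ql_id", "se1_id", "serel_id", "se2_id",
)


class DataError(Exception):
    """Base class for dataset ingestion problems."""


class SchemaError(DataError):
    pass


class RowError(DataError):
    pass


@dataclass(frozen=True)
class EQStatement:
    """One phene as a post-composed Entity-Quality statement."""

    primary_e1: str
    quality: str
    rel_primary: str | None = None
    primary_e2: str | None = None
    qualifier: str | None = None
    secondary_e1: str | None = None
    rel_secondary: str | None = None
    secondary_e2: str | None = None

    def __post_init__(self) -> None:
        if not self.primary_e1 or not self.quality:
            raise ValueError("primary_e1 and quality are required in every EQ statement")
        if self.primary_e2 and not self.rel_primary:
            raise ValueError("primary_e2 requires rel_primary")
        if self.secondary_e2 and not self.secondary_e1:
            raise ValueError("secondary_e2 requires secondary_e1")

    def filled_slots(self) -> dict[str, str]:
        """Slot name -> term id, for slots that are present, in canonical order."""
        out = {}
        for slot in SLOT_ORDER:
            value = getattr(self, slot)
            if value:
                out[slot] = value
        return out


def canonical_key(eq: EQStatement) -> str:
    """Deterministic serialization ``E1|relP|E2|Q|QL|sE1|relS|sE2``.

    Absent slots render as ``-``; two statements are equal iff their keys are.
    """
    return "|".join(getattr(eq, slot) or "-" for slot in SLOT_ORDER)


def eq_from_key(key: str) -> EQStatement:
    """Inverse of :func:`canonical_key`."""
    parts = key.split("|")
    if len(parts) != len(SLOT_ORDER):
        raise ValueError(f"not a canonical EQ key: {key!r}")
    return EQStatement(**{
        slot: (value if value != "-" else None)
        for slot, value in zip(SLOT_ORDER, parts)
    })


@dataclass(frozen=True)
class AtomizedPhene:
    """One curated row: free-text phene, its EQ statement, and carried labels."""

    text: str
    eq: EQStatement
    labels: Mapping[str, str] = field(default_factory=dict)
    source_row: int | None = None


@dataclass(frozen=True)
class GenotypeRecord:
    species: str
    gene_id: str
    genotype_id: str
    atomized: tuple[AtomizedPhene, ...]
    gene_symbol: str | None = None
    phenotype_name: str = ""

    def __post_init__(self) -> None:
        if not self.atomized:
            raise ValueError(f"genotype {self.genotype_id} has no atomized statements")

    @property
    def eq_keys(self) -> frozenset[str]:
        return frozenset(canonical_key(p.eq) for p in self.atomized)


@dataclass(frozen=True)
class Dataset:
    genotypes: tuple[GenotypeRecord, ...]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen_geno: set[str] = set()
        seen_pairs: set[tuple[str, str]] = set()
        for rec in self.genotypes:
            if rec.genotype_id in seen_geno:
                raise DataError(f"duplicate genotype_id {rec.genotype_id}")
            seen_geno.add(rec.genotype_id)
            for phene in rec.atomized:
                pair = (rec.genotype_id, canonical_key(phene.eq))
                if pair in seen_pairs:
                    raise DataError(
                        f"duplicate EQ statement for genotype {rec.genotype_id}: {pair[1]}"
                    )
                seen_pairs.add(pair)

    def __len__(self) -> int:
        return len(self.genotypes)

    def record(self, genotype_id: str) -> GenotypeRecord:
        for rec in self.genotypes:
            if rec.genotype_id == genotype_id:
                return rec
        raise KeyError(genotype_id)

    @property
    def species_map(self) -> dict[str, str]:
        return {rec.genotype_id: rec.species for rec in self.genotypes}

    @property
    def gene_map(self) -> dict[str, str]:
        return {rec.genotype_id: rec.gene_id for rec in self.genotypes}

    def n_statements(self) -> int:
        return sum(len(rec.atomized) for rec in self.genotypes)

    def unique_eq_keys(self) -> frozenset[str]:
        """Distinct canonical EQ keys across all genotypes (the "unique EQs" count)."""
        keys: set[str] = set()
        for rec in self.genotypes:
            keys |= rec.eq_keys
        return frozenset(keys)


def _row_eq(row: Mapping[str, str], lineno: int) -> EQStatement:
    values = {slot: (row.get(col, "") or "").strip() or None
              for slot, col in SLOT_COLUMNS.items()}
    if not values["primary_e1"]:
        raise RowError(f"line {lineno}: missing primary entity (e1_id)")
    if not values["quality"]:
        raise RowError(f"line {lineno}: missing quality (q_id)")
    try:
        return EQStatement(**values)
    except ValueError as exc:
        raise RowError(f"line {lineno}: {exc}") from exc


def read_dataset(
    path: str | Path,
    exclusions: Iterable[tuple[str, str]] | None = None,
) -> Dataset:
    """Read the canonical curation TSV into a :class:`Dataset`.

    One row per atomized statement; rows are aggregated per ``genotype_id``.
    ``exclusions`` is an optional collection of ``(genotype_id, canonical_key)``
    pairs to drop before aggregation (for statements flagged out of an
    analysis without editing the curated table).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment=None)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    excluded = frozenset(exclusions or ())
    order: list[str] = []
    rows_by_geno: dict[str, list[AtomizedPhene]] = {}
    meta: dict[str, dict[str, str]] = {}
    for idx, row in df.iterrows():
        lineno = int(idx) + 2  # header is line 1
        eq = _row_eq(row, lineno)
        gid = row["genotype_id"].strip()
        if not gid:
            raise RowError(f"line {lineno}: empty genotype_id")
        if (gid, canonical_key(eq)) in excluded:
            continue
        labels = {
            slot: row[col].strip()
            for slot, col in LABEL_COLUMNS.items()
            if col in df.columns and row[col].strip()
        }
        phene = AtomizedPhene(
            text=row["phene_text"].strip(), eq=eq, labels=labels, source_row=lineno
        )
        if gid not in rows_by_geno:
            order.append(gid)
            rows_by_geno[gid] = []
            meta[gid] = {
                "species": row["species"].strip(),
                "gene_id": row["gene_id"].strip(),
                "gene_symbol": (row.get("gene_symbol", "") or "").strip(),
                "phenotype_name": row["phenotype_name"].strip(),
            }
        rows_by_geno[gid].append(phene)

    records = tuple(
        GenotypeRecord(
            species=meta[gid]["species"],
            gene_id=meta[gid]["gene_id"],
            gene_symbol=meta[gid]["gene_symbol"] or None,
            genotype_id=gid,
            phenotype_name=meta[gid]["phenotype_name"],
            atomized=tuple(rows_by_geno[gid]),
        )
        for gid in order
    )
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    return Dataset(records, provenance={"source": str(path), "sha256": digest})


def to_frame(ds: Dataset) -> pd.DataFrame:
    """Dataset as a canonical-dialect DataFrame (one atomized statement per row)."""
    rows = []
    for rec in ds.genotypes:
        for phene in rec.atomized:
            row = {c: "" for c in ALL_COLUMNS}
            row.update(
                species=rec.species,
                gene_id=rec.gene_id,
                gene_symbol=rec.gene_symbol or "",
                genotype_id=rec.genotype_id,
                phenotype_name=rec.phenotype_name,
                phene_text=phene.text,
            )
            for slot, col in SLOT_COLUMNS.items():
                row[col] = getattr(phene.eq, slot) or ""
            for slot, col in LABEL_COLUMNS.items():
                if slot in phene.labels:
                    row[col] = phene.labels[slot]
            rows.append(row)
    return pd.DataFrame(rows, columns=ALL_COLUMNS)


def write_dataset(ds: Dataset, path: str | Path) -> None:
    to_frame(ds).to_csv(path, sep="\t", index=False)
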