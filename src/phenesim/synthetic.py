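"""Synthetic ontologies and curation datasets for controlled experiments.

Real runs need multi-megabyte PO/GO/PATO snapshots and a hand-curated EQ
table; for testing and benchmarking, this module generates the same shapes
at any size: rooted DAG ontologies with bounded fan-in, and multi-species
datasets whose genotypes draw phenes from a shared pool with a tunable
reuse probability (``overlap``), which directly controls how much semantic
overlap the downstream similarity network shows.

Everything is deterministic for a fixed seed; no global RNG state is used.
Defaults mirror the shape of a modest curation effort: six species, one to
five phenes per genotype (real curated genotypes average ~2 phenes), and a
moderate phene-reuse probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .eqdata import AtomizedPhene, Dataset, EQStatement, GenotypeRecord, canonical_key
from .ontology import IS_A, PART_OF, Ontology, Term
from .validate import ValidationConfig

ENTITY_PREFIX = "SE"
QUALITY_PREFIX = "SQ"


@dataclass(frozen=True)
class SimConfig:
    """Knobs for the generators; counts are per generated object."""

    n_terms: int = 60          # terms per ontology
    max_parents: int = 3       # fan-in bound for non-root terms
    depth: int = 5             # maximum term depth
    n_genotypes: int = 40
    phenes_min: int = 1
    phenes_max: int = 5
    n_species: int = 6
    overlap: float = 0.3       # probability a phene is reused from the pool
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_terms", "max_parents", "depth", "n_genotypes",
                     "phenes_min", "phenes_max", "n_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.phenes_max < self.phenes_min:
            raise ValueError("phenes_max must be >= phenes_min")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")


def synthetic_validation_config() -> ValidationConfig:
    """Validation config under which generated datasets are clean."""
    return ValidationConfig(
        structural_entity_prefixes=frozenset({ENTITY_PREFIX}),
        quality_prefix=QUALITY_PREFIX,
    )


def generate_ontology(
    cfg: SimConfig,
    prefix: str = ENTITY_PREFIX,
    namespace: str = "synthetic",
    part_of_fraction: float = 0.0,
    stream: int = 0,
) -> Ontology:
    """Rooted random DAG: every non-root term gets 1..max_parents parents
    drawn from strictly shallower terms.

    ``stream`` decorrelates multiple ontologies generated from one config
    (entity vs quality ontology) while staying reproducible.
    """
    rng = np.random.default_rng([cfg.seed, stream])
    ids = [f"{prefix}:{i:07d}" for i in range(cfg.n_terms)]
    terms = {
        tid: Term(tid, label=f"{namespace} term {i}", namespace=namespace)
        for i, tid in enumerate(ids)
    }
    depth_of = {ids[0]: 0}
    by_depth: dict[int, list[str]] = {0: [ids[0]]}
    edges: set[tuple[str, str, str]] = set()
    for tid in ids[1:]:
        d = int(rng.integers(1, cfg.depth + 1))
        while not any(by_depth.get(k) for k in range(d)):
            d -= 1  # cannot happen below d=1 since the root sits at depth 0
        shallower = [t for k in range(d) for t in by_depth.get(k, [])]
        k = int(rng.integers(1, cfg.max_parents + 1))
        k = min(k, len(shallower))
        parents = rng.choice(len(shallower), size=k, replace=False)
        for p in parents:
            rel = PART_OF if rng.random() < part_of_fraction else IS_A
            edges.add((tid, shallower[int(p)], rel))
        depth_of[tid] = d
        by_depth.setdefault(d, []).append(tid)
    return Ontology(terms, edges)


def generate_dataset(
    ont_entities: Ontology,
    ont_qualities: Ontology,
    cfg: SimConfig,
) -> Dataset:
    """Random multi-species EQ dataset over two synthetic ontologies.

    Each phene is an (entity term, quality term) pair; with probability
    ``overlap`` it is reused from the shared pool of phenes drawn so far,
    otherwise a fresh pair is drawn and added to the pool.  The result
    passes validation under :func:`synthetic_validation_config`.
    """
    if not ont_entities.terms or not ont_qualities.terms:
        raise ValueError("ontologies must be nonempty")
    rng = np.random.default_rng([cfg.seed, 997])
    entities = sorted(t for t, term in ont_entities.terms.items() if not term.obsolete)
    qualities = sorted(t for t, term in ont_qualities.terms.items() if not term.obsolete)

    pool: list[tuple[str, str]] = []

    def draw_phene() -> tuple[str, str]:
        if pool and rng.random() < cfg.overlap:
            return pool[int(rng.integers(len(pool)))]
        fresh = (
            entities[int(rng.integers(len(entities)))],
            qualities[int(rng.integers(len(qualities)))],
        )
        pool.append(fresh)
        return fresh

    records = []
    for i in range(cfg.n_genotypes):
        gid = f"g{i:04d}"
        species = f"species{int(rng.integers(cfg.n_species)) + 1}"
        k = int(rng.integers(cfg.phenes_min, cfg.phenes_max + 1))
        phenes: dict[str, AtomizedPhene] = {}
        attempts = 0
        while len(phenes) < k and attempts < 20 * k:
            attempts += 1
            entity, quality = draw_phene()
            eq = EQStatement(primary_e1=entity, quality=quality)
            key = canonical_key(eq)
            if key in phenes:
                continue
            phenes[key] = AtomizedPhene(
                text=f"{ont_entities.terms[entity].label} / "
                     f"{ont_qualities.terms[quality].label}",
                eq=eq,
                labels={
                    "primary_e1": ont_entities.terms[entity].label,
                    "quality": ont_qualities.terms[quality].label,
                },
            )
        records.append(GenotypeRecord(
            species=species,
            gene_id=gid,
            genotype_id=gid,
            phenotype_name=f"synthetic phenotype {i}",
            atomized=tuple(phenes.values()),
        ))
    return Dataset(tuple(records), provenance={"source": "synthetic",
                                               "seed": str(cfg.seed)})


# -- emission ------------------------------------------------------------------


def write_obo(ont: Ontology, path: str | Path) -> None:
    """Emit a minimal OBO 1.2 file round-trippable by :func:`parse_obo`."""
    parents: dict[str, list[tuple[str, str]]] = {}
    for child, parent, rel in sorted(ont.edges):
        parents.setdefault(child, []).append((parent, rel))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {Path(path).stem}\n")
        for tid in sorted(ont.terms):
            term = ont.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: {term.label}\n")
            if term.namespace:
                fh.write(f"namespace: {term.namespace}\n")
            for alt in sorted(term.alt_ids):
                fh.write(f"alt_id: {alt}\n")
            if term.obsolete:
                fh.write("is_obsolete: true\n")
            if term.replaced_by:
                fh.write(f"replaced_by: {term.replaced_by}\n")
            for parent, rel in parents.get(tid, ()):
                if rel == IS_A:
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


def simulate_to_dir(cfg: SimConfig, out_dir: str | Path) -> dict[str, str]:
    """Emit entity OBO, quality OBO, dataset TSV and a manifest JSON."""
    from .eqdata import write_dataset

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ont_e = generate_ontology(cfg, ENTITY_PREFIX, "synthetic_entity",
                              part_of_fraction=0.2, stream=0)
    ont_q = generate_ontology(cfg, QUALITY_PREFIX, "synthetic_quality", stream=1)
    ds = generate_dataset(ont_e, ont_q, cfg)
    paths = {
        "entities": str(out / "entities.obo"),
        "qualities": str(out / "qualities.obo"),
        "dataset": str(out / "dataset.tsv"),
        "manifest": str(out / "manifest.json"),
    }
    write_obo(ont_e, paths["entities"])
    write_obo(ont_q, paths["qualities"])
    write_dataset(ds, paths["dataset"])
    manifest = {"config": asdict(cfg), "files": paths,
                "n_genotypes": len(ds), "n_statements": ds.n_statements()}
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return paths
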