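"""Inferred phene sets via slot-wise ontology closure.

A phene asserted by a curator implies every generalisation of itself: "male
and female infertility" of the whole plant implies "complete sterility" of
the whole plant, because the quality is a descendant of complete sterility
in PATO.  For the EQ grammar used here, reasoning with the class expression
``has-part some (E and has-quality some Q)`` produces exactly the named
superclasses obtained by replacing each filled slot with one of its
reflexive ancestors, so the closure is computed directly on the merged term
graph:

* entity slots generalise over ``is_a`` and ``part_of`` (plus ``bridge``
  edges when enabled);
* quality, qualifier and relation slots generalise over ``is_a`` only;
* unfilled slots stay unfilled — no slot is dropped or added.

A genotype's profile is the union of the closures of its asserted EQ
statements; the Jaccard similarity of two genotypes is computed over these
inferred sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from .eqdata import Dataset, EQStatement, GenotypeRecord, canonical_key, eq_from_key
from .ontology import BRIDGE, IS_A, PART_OF, Ontology

ENTITY_SLOTS = frozenset({"primary_e1", "primary_e2", "secondary_e1", "secondary_e2"})

#: default per-genotype cap on the inferred set; a shallow ontology with many
#: filled slots can blow up combinatorially, which usually signals curation
#: at too general a level rather than a need for a bigger cap
DEFAULT_CAP = 10_000


class ClosureCapError(Exception):
    def __init__(self, genotype_id: str, cap: int):
        super().__init__(
            f"inferred phene set of genotype {genotype_id} exceeds the cap of "
            f"{cap}; curate deeper (more specific) terms or raise the cap"
        )
        self.genotype_id = genotype_id
        self.cap = cap


def slot_relations(slot: str, use_bridges: bool = False) -> frozenset[str]:
    """Edge relations traversed when generalising a given slot."""
    if slot in ENTITY_SLOTS:
        rels = {IS_A, PART_OF}
        if use_bridges:
            rels.add(BRIDGE)
        return frozenset(rels)
    return frozenset({IS_A})


@dataclass(frozen=True)
class PhenotypeProfile:
    """A genotype's asserted EQ keys and their closure (the inferred phenes)."""

    genotype_id: str
    asserted: frozenset[str]
    inferred: frozenset[str]

    def __post_init__(self) -> None:
        if not self.asserted <= self.inferred:
            raise ValueError("asserted phenes must be a subset of inferred phenes")


def subsumes(
    general: EQStatement,
    specific: EQStatement,
    ont: Ontology,
    use_bridges: bool = False,
) -> bool:
    """True iff ``general`` is an equal-or-more-general phene than ``specific``.

    Every slot filled in ``general`` must be filled in ``specific`` with a
    term of which the general term is a reflexive ancestor; slots absent in
    ``general`` are unconstrained.
    """
    for slot, gen_term in general.filled_slots().items():
        spec_term = getattr(specific, slot)
        if not spec_term:
            return False
        rels = slot_relations(slot, use_bridges)
        if ont.resolve(gen_term) not in ont.ancestors(spec_term, rels, reflexive=True):
            return False
    return True


def canonicalize(eq: EQStatement, ont: Ontology) -> EQStatement:
    """Replace every filled slot with its canonical (alt-resolved) id."""
    return EQStatement(**{
        slot: ont.resolve(term) for slot, term in eq.filled_slots().items()
    })


def infer_statement(
    eq: EQStatement, ont: Ontology, use_bridges: bool = False
) -> set[EQStatement]:
    """Cross-product closure of one statement (includes the statement itself)."""
    slots = eq.filled_slots()
    choices = [
        sorted(ont.ancestors(term, slot_relations(slot, use_bridges), reflexive=True))
        for slot, term in slots.items()
    ]
    names = list(slots)
    out: set[EQStatement] = set()
    for combo in itertools.product(*choices):
        try:
            out.add(EQStatement(**dict(zip(names, combo))))
        except ValueError:
            # a combination that violates the EQ grammar (cannot happen when
            # the source statement is valid, since slots are never dropped)
            continue
    return out


def infer_profile(
    rec: GenotypeRecord,
    ont: Ontology,
    cap: int = DEFAULT_CAP,
    use_bridges: bool = False,
) -> PhenotypeProfile:
    """Build the genotype's inferred phene set P_geno by closure."""
    asserted: set[str] = set()
    inferred: set[str] = set()
    for phene in rec.atomized:
        asserted.add(canonical_key(canonicalize(phene.eq, ont)))
        for eq in infer_statement(phene.eq, ont, use_bridges):
            inferred.add(canonical_key(eq))
            if len(inferred) > cap:
                raise ClosureCapError(rec.genotype_id, cap)
    return PhenotypeProfile(rec.genotype_id, frozenset(asserted), frozenset(inferred))


def infer_dataset(
    ds: Dataset,
    ont: Ontology,
    cap: int = DEFAULT_CAP,
    use_bridges: bool = False,
) -> list[PhenotypeProfile]:
    return [infer_profile(rec, ont, cap, use_bridges) for rec in ds.genotypes]
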