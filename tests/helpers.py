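"""Independent oracles used by the property tests.

These deliberately avoid the package's closure machinery: ancestor sets are
recomputed by naive recursive enumeration over the raw edge list, and
subsumption is re-derived from those naive sets, so agreement with the
package is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

from phenesim.eqdata import EQStatement
from phenesim.infer import slot_relations
from phenesim.ontology import Ontology


def naive_ancestors(
    edges: set[tuple[str, str, str]],
    term: str,
    relations: frozenset[str],
    reflexive: bool = False,
) -> frozenset[str]:
    """Recursive definition: ancestors(t) = union over parents p of {p} + ancestors(p)."""

    def recurse(node: str) -> set[str]:
        out: set[str] = set()
        for child, parent, rel in edges:
            if child == node and rel in relations:
                out.add(parent)
                out |= recurse(parent)
        return out

    result = recurse(term)
    if reflexive:
        result.add(term)
    return frozenset(result)


def naive_subsumes(
    general: EQStatement, specific: EQStatement, ont: Ontology
) -> bool:
    """Slot-wise subsumption re-derived from naive ancestor sets."""
    for slot, gen_term in general.filled_slots().items():
        spec_term = getattr(specific, slot)
        if not spec_term:
            return False
        anc = naive_ancestors(
            set(ont.edges), spec_term, slot_relations(slot), reflexive=True
        )
        if gen_term not in anc:
            return False
    return True


def jaccard(a: frozenset, b: frozenset) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 1.0
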