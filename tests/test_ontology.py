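"""Ontology parsing, merging, and ancestor-closure semantics."""

from __future__ import annotations

import itertools

import pytest

from helpers import naive_ancestors
from phenesim.ontology import (
    CycleError,
    IS_A,
    MergeError,
    OboParseError,
    ObsoleteTermError,
    Ontology,
    PART_OF,
    Term,
    UnknownTermError,
    merge,
    parse_obo,
)
from phenesim.synthetic import SimConfig, generate_ontology


def write_obo_text(tmp_path, text, name="test.obo"):
    path = tmp_path / name
    path.write_text("format-version: 1.2\nontology: test\n\n" + text)
    return path


class TestParseObo:
    def test_terms_and_edges(self, tmp_path):
        path = write_obo_text(tmp_path, (
            "[Term]\nid: X:0000001\nname: a\n\n"
            "[Term]\nid: X:0000002\nname: b\nis_a: X:0000001\n\n"
            "[Term]\nid: X:0000003\nname: c\nrelationship: part_of X:0000001\n"
        ))
        ont = parse_obo(path)
        assert len(ont) == 3
        assert ont.edges == {
            ("X:0000002", "X:0000001", IS_A),
            ("X:0000003", "X:0000001", PART_OF),
        }
        assert ont.roots == {"X:0000001"}

    def test_alt_id_resolves_to_canonical(self, tmp_path):
        path = write_obo_text(tmp_path, "[Term]\nid: X:0000001\nname: a\nalt_id: X:0000099\n")
        ont = parse_obo(path)
        assert ont.resolve("X:0000099") == "X:0000001"
        assert ont.is_alt("X:0000099")
        assert not ont.is_alt("X:0000001")

    def test_obsolete_term_kept_but_closed_out(self, tmp_path):
        path = write_obo_text(tmp_path, (
            "[Term]\nid: X:0000001\nname: a\n\n"
            "[Term]\nid: X:0000002\nname: old\nis_obsolete: true\n"
            "replaced_by: X:0000001\nis_a: X:0000001\n"
        ))
        ont = parse_obo(path)
        term = ont.terms["X:0000002"]
        assert term.obsolete and term.replaced_by == "X:0000001"
        assert not ont.edges  # obsolete terms contribute no edges
        with pytest.raises(ObsoleteTermError):
            ont.ancestors("X:0000002")

    def test_duplicate_id_rejected_with_line_number(self, tmp_path):
        path = write_obo_text(tmp_path, (
            "[Term]\nid: X:0000001\nname: a\n\n"
            "[Term]\nid: X:0000001\nname: a again\n"
        ))
        with pytest.raises(OboParseError, match=r":9: duplicate term id X:0000001"):
            parse_obo(path)

    def test_non_curie_id_rejected(self, tmp_path):
        path = write_obo_text(tmp_path, "[Term]\nid: not a curie\nname: a\n")
        with pytest.raises(OboParseError):
            parse_obo(path)


class TestMerge:
    def test_disjoint_union(self):
        a = Ontology([Term("A:1", "a1"), Term("A:2", "a2")], {("A:2", "A:1", IS_A)})
        b = Ontology([Term("B:1", "b1"), Term("B:2", "b2")], {("B:2", "B:1", IS_A)})
        merged = merge([a, b])
        assert len(merged) == 4
        assert merged.edges == a.edges | b.edges

    def test_bridge_edge_added(self):
        a = Ontology([Term("GO:1", "proc")], set())
        b = Ontology([Term("PO:1", "struct")], set())
        merged = merge([a, b], bridges=[("GO:1", "PO:1")])
        assert ("GO:1", "PO:1", "bridge") in merged.edges

    def test_bridge_unknown_id_error_names_it(self):
        a = Ontology([Term("GO:1", "proc")], set())
        with pytest.raises(MergeError, match="PO:9"):
            merge([a], bridges=[("GO:1", "PO:9")])

    def test_conflicting_labels_rejected(self):
        a = Ontology([Term("X:1", "one label")], set())
        b = Ontology([Term("X:1", "another label")], set())
        with pytest.raises(MergeError):
            merge([a, b])

    def test_associative_up_to_set_equality(self):
        onts = [
            Ontology([Term(f"{p}:1", p), Term(f"{p}:2", p + "2")],
                     {(f"{p}:2", f"{p}:1", IS_A)})
            for p in ("A", "B", "C")
        ]
        left = merge([merge(onts[:2]), onts[2]])
        right = merge([onts[0], merge(onts[1:])])
        assert left.terms == right.terms and left.edges == right.edges


class TestAncestors:
    @pytest.fixture()
    def chain(self):
        return Ontology(
            [Term("X:a", "a"), Term("X:b", "b"), Term("X:c", "c")],
            {("X:a", "X:b", IS_A), ("X:b", "X:c", IS_A)},
        )

    def test_chain_closure(self, chain):
        assert chain.ancestors("X:a", {IS_A}) == {"X:b", "X:c"}

    def test_root_is_empty_nonreflexive(self, chain):
        assert chain.ancestors("X:c", {IS_A}) == frozenset()

    def test_reflexivity_flag(self, chain):
        assert "X:a" not in chain.ancestors("X:a", {IS_A})
        assert "X:a" in chain.ancestors("X:a", {IS_A}, reflexive=True)

    def test_diamond_counts_apex_once(self):
        ont = Ontology(
            [Term(f"X:{x}", x) for x in "abcd"],
            {("X:a", "X:b", IS_A), ("X:a", "X:c", IS_A),
             ("X:b", "X:d", IS_A), ("X:c", "X:d", IS_A)},
        )
        expected = naive_ancestors(set(ont.edges), "X:a", frozenset({IS_A}))
        assert ont.ancestors("X:a", {IS_A}) == expected == {"X:b", "X:c", "X:d"}

    def test_relation_filter(self):
        ont = Ontology(
            [Term("X:a", "a"), Term("X:b", "b"), Term("X:c", "c")],
            {("X:a", "X:b", IS_A), ("X:a", "X:c", PART_OF)},
        )
        assert ont.ancestors("X:a", {IS_A}) == {"X:b"}
        assert ont.ancestors("X:a", {IS_A, PART_OF}) == {"X:b", "X:c"}

    def test_unknown_term_raises(self, chain):
        with pytest.raises(UnknownTermError):
            chain.ancestors("X:missing")

    def test_parent_ancestors_nested(self, mini_ont):
        """For every child and parent: ancestors(child) >= ancestors(parent) + {parent}."""
        for child, parent, rel in mini_ont.edges:
            anc = mini_ont.ancestors(child)
            assert parent in anc
            assert mini_ont.ancestors(parent) <= anc


class TestClosureOracle:
    def test_matches_naive_dfs_on_random_dags(self):
        """Closure equals brute-force recursive enumeration on 100 random DAGs."""
        for seed in range(100):
            cfg = SimConfig(n_terms=25, max_parents=3, depth=4, seed=seed)
            ont = generate_ontology(cfg, part_of_fraction=0.3)
            edges = set(ont.edges)
            for term in ont.terms:
                for rels in ({IS_A}, {IS_A, PART_OF}):
                    assert ont.ancestors(term, rels) == naive_ancestors(
                        edges, term, frozenset(rels)
                    ), (seed, term, rels)


def test_cycle_detection():
    with pytest.raises(CycleError):
        Ontology(
            [Term("X:a", "a"), Term("X:b", "b")],
            {("X:a", "X:b", IS_A), ("X:b", "X:a", PART_OF)},
        )


def test_edges_must_reference_terms():
    with pytest.raises(Exception, match="endpoint"):
        Ontology([Term("X:a", "a")], {("X:a", "X:zz", IS_A)})
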