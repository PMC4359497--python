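"""Score distributions, classification averages, and pathway coverage."""

from __future__ import annotations

import math

import numpy as np
import pytest

from phenesim.analysis import (
    AnalysisError,
    CROSS_SPECIES,
    Classification,
    OVERALL,
    PathwayModel,
    bin_index,
    gene_pair_score,
    group_average,
    pathway_coverage,
    percent,
    possible_pairs,
    read_pathways,
    score_distribution,
)
from phenesim.infer import PhenotypeProfile
from phenesim.similarity import SimilarityMatrix, all_pairs


def profile(gid, *keys):
    ks = frozenset(keys)
    return PhenotypeProfile(gid, ks, ks)


def matrix_of(entries, ids=None):
    ids = ids or sorted({g for pair in entries for g in pair})
    return SimilarityMatrix(ids, entries)


class TestPercent:
    def test_rounds_half_up(self):
        assert percent(241042, 548888) == 44
        assert percent(71290, 548888) == 13
        assert percent(548888, 8213956) == 7
        assert percent(1, 200) == 1  # 0.5 rounds up

    def test_possible_pairs_is_square(self):
        assert possible_pairs(2866) == 8213956


class TestScoreDistribution:
    def test_extremes_land_in_outer_bins(self):
        m = matrix_of({("a", "b"): 0.05, ("a", "c"): 0.95})
        frame = score_distribution(m, {"a": "s1", "b": "s1", "c": "s1"})
        overall = frame[frame["scope"] == OVERALL]
        assert overall.loc[overall["bin"] == 1, "count"].item() == 1
        assert overall.loc[overall["bin"] == 10, "count"].item() == 1

    def test_score_one_in_top_bin(self):
        assert bin_index(1.0) == 9
        assert bin_index(0.1) == 0
        assert bin_index(0.10000001) == 1

    def test_species_vs_cross_species_scoping(self):
        m = matrix_of({("a", "b"): 0.5, ("a", "c"): 0.5, ("b", "c"): 0.95})
        species = {"a": "maize", "b": "maize", "c": "rice"}
        frame = score_distribution(m, species)
        scopes = set(frame["scope"].astype(str))
        assert scopes == {OVERALL, "maize", CROSS_SPECIES}
        maize = frame[frame["scope"] == "maize"]
        assert maize["count"].sum() == 1  # only the a-b pair is intra-maize
        cross = frame[frame["scope"] == CROSS_SPECIES]
        assert cross["count"].sum() == 2

    def test_per_scope_counts_sum_to_total(self):
        rng = np.random.default_rng(5)
        profiles = [
            profile(f"g{i}", *(f"p{k}" for k in rng.choice(20, size=4, replace=False)))
            for i in range(25)
        ]
        m = all_pairs(profiles)
        species = {f"g{i}": f"s{i % 3}" for i in range(25)}
        frame = score_distribution(m, species)
        overall_total = frame.loc[frame["scope"] == OVERALL, "count"].sum()
        scoped_total = frame.loc[frame["scope"] != OVERALL, "count"].sum()
        assert overall_total == len(m) == scoped_total

    def test_percentages_sum_to_100_up_to_rounding(self):
        m = matrix_of({("a", "b"): 0.05, ("a", "c"): 0.55, ("b", "c"): 0.95})
        frame = score_distribution(m, {"a": "s", "b": "s", "c": "s"})
        total = frame.loc[frame["scope"] == OVERALL, "percent"].sum()
        assert abs(total - 100) <= 5  # integer rounding slack across 10 bins

    def test_missing_species_is_error(self):
        m = matrix_of({("a", "b"): 0.5})
        with pytest.raises(AnalysisError):
            score_distribution(m, {"a": "s"})


class TestGroupAverage:
    def test_two_gene_label(self):
        m = matrix_of({("x1", "y1"): 0.4})
        cls = Classification(frozenset({("x", "class", "A"), ("y", "class", "A")}))
        out = group_average(m, cls, "class", {"x1": "x", "y1": "y"})
        assert out.loc[0, "mean_score"] == pytest.approx(0.4)
        assert out.loc[0, "n_pairs"] == 1

    def test_absent_pairs_count_as_zero(self):
        m = matrix_of({("x1", "y1"): 1.0, ("x1", "z1"): 0.5}, ids=["x1", "y1", "z1"])
        cls = Classification(frozenset(
            {("x", "class", "A"), ("y", "class", "A"), ("z", "class", "A")}
        ))
        out = group_average(m, cls, "class", {"x1": "x", "y1": "y", "z1": "z"})
        # pairs: (x,y)=1.0, (x,z)=0.5, (y,z) absent -> 0
        assert out.loc[0, "mean_score"] == pytest.approx(0.5)

    def test_singleton_label_undefined_mean(self):
        m = matrix_of({("x1", "y1"): 0.4})
        cls = Classification(frozenset({("x", "subset", "S")}))
        out = group_average(m, cls, "subset", {"x1": "x", "y1": "y"})
        assert out.loc[0, "n_pairs"] == 0
        assert math.isnan(out.loc[0, "mean_score"])

    def test_allele_aggregation_max_vs_mean(self):
        # gene x has two allele genotypes; max and mean must differ
        m = matrix_of({("x1", "y1"): 0.8, ("x2", "y1"): 0.2}, ids=["x1", "x2", "y1"])
        genes = {"x1": "x", "x2": "x", "y1": "y"}
        cls = Classification(frozenset({("x", "class", "A"), ("y", "class", "A")}))
        assert group_average(m, cls, "class", genes, agg="max").loc[0, "mean_score"] \
            == pytest.approx(0.8)
        assert group_average(m, cls, "class", genes, agg="mean").loc[0, "mean_score"] \
            == pytest.approx(0.5)

    def test_matches_exhaustive_oracle_and_row_order_invariance(self):
        rng = np.random.default_rng(9)
        profiles = [
            profile(f"g{i}", *(f"p{k}" for k in rng.choice(15, size=3, replace=False)))
            for i in range(20)
        ]
        m = all_pairs(profiles)
        gene_map = {f"g{i}": f"gene{i}" for i in range(20)}
        labels = {f"gene{i}": f"L{i % 4}" for i in range(20)}
        cls = Classification(frozenset(
            (gene, "subset", label) for gene, label in labels.items()
        ))
        out = group_average(m, cls, "subset", gene_map)
        for _, row in out.iterrows():
            genes = sorted(g for g, l in labels.items() if l == row["label"])
            pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
            expected = sum(
                m.get(a.replace("gene", "g"), b.replace("gene", "g"))
                for a, b in pairs
            ) / len(pairs)
            assert row["mean_score"] == pytest.approx(expected)
        # permutation invariance of the genotype->gene map ordering
        shuffled = dict(reversed(list(gene_map.items())))
        assert group_average(m, cls, "subset", shuffled).equals(out)

    def test_one_class_per_gene_enforced(self):
        with pytest.raises(AnalysisError):
            Classification(frozenset({("x", "class", "A"), ("x", "class", "B")}))


class TestPathwayCoverage:
    def test_half_covered(self):
        pw = PathwayModel(
            "pwy", frozenset(f"s{i}" for i in range(10)),
            frozenset((f"s{i}", f"g{i}") for i in range(5)),
        )
        assert pathway_coverage(pw, {f"g{i}" for i in range(5)}) == 0.5

    def test_multi_catalyst_step_counts_once(self):
        pw = PathwayModel(
            "pwy", frozenset({"s1", "s2"}),
            frozenset({("s1", "gA"), ("s1", "gB"), ("s2", "gC")}),
        )
        assert pathway_coverage(pw, {"gA", "gB"}) == 0.5

    def test_no_curated_catalysts(self):
        pw = PathwayModel("pwy", frozenset({"s1"}), frozenset({("s1", "gA")}))
        assert pathway_coverage(pw, set()) == 0.0

    def test_monotone_in_curated_genes(self):
        rng = np.random.default_rng(13)
        steps = frozenset(f"s{i}" for i in range(8))
        catalysts = frozenset(
            (f"s{int(rng.integers(8))}", f"g{i}") for i in range(12)
        )
        pw = PathwayModel("pwy", steps, catalysts)
        genes = [f"g{i}" for i in range(12)]
        prev = 0.0
        for k in range(len(genes) + 1):
            cov = pathway_coverage(pw, set(genes[:k]))
            assert cov >= prev
            prev = cov

    def test_empty_pathway_is_error(self):
        with pytest.raises(AnalysisError):
            pathway_coverage(PathwayModel("pwy", frozenset(), frozenset()), set())

    def test_read_pathways_tsv(self, tmp_path):
        path = tmp_path / "pw.tsv"
        path.write_text(
            "pathway_id\tstep_id\tgene_id\n"
            "pwy1\ts1\tgA\npwy1\ts2\t\npwy2\ts1\tgB\n"
        )
        pws = read_pathways(path)
        assert set(pws) == {"pwy1", "pwy2"}
        assert pathway_coverage(pws["pwy1"], {"gA"}) == 0.5
        assert pathway_coverage(pws["pwy2"], {"gB"}) == 1.0


def test_gene_pair_score_empty_when_no_genotypes():
    m = matrix_of({("a", "b"): 0.3})
    assert gene_pair_score(m, [], ["a"]) == 0.0
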