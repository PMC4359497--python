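"""Downstream analyses of the phenotype similarity network.

Covers the standard summaries run over an all-vs-all simphen matrix:

* binned score distributions, overall and split into per-species
  (both genotypes from the same species) and cross-species scopes;
* average within-group similarity against an external, manually curated
  gene classification (a group/class/subset hierarchy);
* metabolic pathway-step coverage — the fraction of a pathway's reaction
  steps catalyzed by at least one phenotype-curated gene.

Binning uses half-open intervals (0, 0.1], (0.1, 0.2], ..., (0.9, 1] so a
perfect score of 1 lands in the top bin and zero scores (which the sparse
matrix does not store) are excluded by construction.  Percentages are
rounded half-up to integers to match conventional report formatting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .similarity import SimilarityMatrix

CROSS_SPECIES = "cross-species"
OVERALL = "overall"


class AnalysisError(Exception):
    pass


def percent(part: int | float, whole: int | float) -> int:
    """Integer percentage, rounded half-up (241,042 of 548,888 -> 44)."""
    if whole == 0:
        raise AnalysisError("percentage of an empty total is undefined")
    ratio = Decimal(part) * 100 / Decimal(whole)
    return int(ratio.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def possible_pairs(n_genotypes: int) -> int:
    """Size of the conceptual all-vs-all matrix over n genotypes (n x n)."""
    return n_genotypes * n_genotypes


def bin_index(score: float, bins: int = 10) -> int:
    """0-based bin of a score in (0, 1] under (i/bins, (i+1)/bins] edges."""
    if not 0.0 < score <= 1.0:
        raise AnalysisError(f"score {score} outside (0, 1]")
    return min(bins - 1, math.ceil(score * bins) - 1)


def score_distribution(
    matrix: SimilarityMatrix,
    species_map: Mapping[str, str],
    bins: int = 10,
) -> pd.DataFrame:
    """Histogram of nonzero scores per scope.

    Scopes are ``overall``, one per species (pairs whose two genotypes share
    that species), and ``cross-species`` (pairs from different species).
    Self pairs are never present in the sparse matrix.  Returns a tidy frame
    with columns scope, bin, lower, upper, count, percent.
    """
    if bins < 1:
        raise AnalysisError("bins must be >= 1")
    counts: dict[str, list[int]] = {OVERALL: [0] * bins}
    for a, b, score in matrix:
        for g in (a, b):
            if g not in species_map:
                raise AnalysisError(f"genotype {g} missing from species map")
        scope = species_map[a] if species_map[a] == species_map[b] else CROSS_SPECIES
        idx = bin_index(score, bins)
        counts[OVERALL][idx] += 1
        counts.setdefault(scope, [0] * bins)[idx] += 1

    rows = []
    for scope, hist in counts.items():
        total = sum(hist)
        for i, count in enumerate(hist):
            rows.append({
                "scope": scope,
                "bin": i + 1,
                "lower": i / bins,
                "upper": (i + 1) / bins,
                "count": count,
                "percent": percent(count, total) if total else 0,
            })
    order = [OVERALL] + sorted(s for s in counts if s not in (OVERALL, CROSS_SPECIES))
    if CROSS_SPECIES in counts:
        order.append(CROSS_SPECIES)
    frame = pd.DataFrame(rows)
    frame["scope"] = pd.Categorical(frame["scope"], categories=order, ordered=True)
    return frame.sort_values(["scope", "bin"], ignore_index=True)


# -- external gene classification ---------------------------------------------

LEVELS = ("group", "class", "subset")


@dataclass(frozen=True)
class Classification:
    """Three-tiered manual phenotype grouping of genes.

    Each gene carries exactly one group, one class, and zero or more
    subsets; assignments are ``(gene_id, level, label)`` triples.
    """

    assignments: frozenset[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for level in ("group", "class"):
            seen: dict[str, str] = {}
            for gene, lvl, label in self.assignments:
                if lvl not in LEVELS:
                    raise AnalysisError(f"unknown classification level {lvl}")
                if lvl == level:
                    if gene in seen and seen[gene] != label:
                        raise AnalysisError(
                            f"gene {gene} has two {level} labels: "
                            f"{seen[gene]}, {label}"
                        )
                    seen[gene] = label

    def labels(self, level: str) -> list[str]:
        return sorted({lab for _, lvl, lab in self.assignments if lvl == level})

    def genes(self, level: str, label: str) -> frozenset[str]:
        return frozenset(
            g for g, lvl, lab in self.assignments if lvl == level and lab == label
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Classification":
        """Read ``gene_id, group, class, subsets`` (subsets ;-separated)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        triples: set[tuple[str, str, str]] = set()
        for _, row in df.iterrows():
            gene = row["gene_id"].strip()
            if row.get("group", "").strip():
                triples.add((gene, "group", row["group"].strip()))
            if row.get("class", "").strip():
                triples.add((gene, "class", row["class"].strip()))
            for subset in row.get("subsets", "").split(";"):
                if subset.strip():
                    triples.add((gene, "subset", subset.strip()))
        return cls(frozenset(triples))


def gene_pair_score(
    matrix: SimilarityMatrix,
    genotypes_a: Iterable[str],
    genotypes_b: Iterable[str],
    agg: str = "max",
) -> float:
    """Similarity of two genes = max (or mean) over their genotype pairs.

    Genotype pairs absent from the sparse matrix contribute score 0.
    """
    scores = [matrix.get(x, y) for x in genotypes_a for y in genotypes_b]
    if not scores:
        return 0.0
    if agg == "max":
        return max(scores)
    if agg == "mean":
        return sum(scores) / len(scores)
    raise AnalysisError(f"unknown aggregation {agg!r} (use 'max' or 'mean')")


def group_average(
    matrix: SimilarityMatrix,
    cls: Classification,
    level: str,
    gene_map: Mapping[str, str],
    agg: str = "max",
) -> pd.DataFrame:
    """Mean similarity over all same-label gene pairs, per label.

    ``gene_map`` maps genotype_id -> gene_id (a gene may have several allele
    genotypes).  Labels with fewer than two scorable genes are reported with
    ``n_pairs`` 0 and an undefined (NaN) mean.
    """
    if level not in ("class", "subset", "group"):
        raise AnalysisError(f"invalid level {level!r}")
    gene_genotypes: dict[str, list[str]] = {}
    for genotype, gene in gene_map.items():
        gene_genotypes.setdefault(gene, []).append(genotype)

    rows = []
    for label in cls.labels(level):
        genes = sorted(g for g in cls.genes(level, label) if g in gene_genotypes)
        pairs = [
            (genes[i], genes[j])
            for i in range(len(genes))
            for j in range(i + 1, len(genes))
        ]
        if not pairs:
            rows.append({"label": label, "n_genes": len(genes),
                         "n_pairs": 0, "mean_score": float("nan")})
            continue
        total = sum(
            gene_pair_score(matrix, gene_genotypes[a], gene_genotypes[b], agg)
            for a, b in pairs
        )
        rows.append({
            "label": label,
            "n_genes": len(genes),
            "n_pairs": len(pairs),
            "mean_score": total / len(pairs),
        })
    return pd.DataFrame(rows, columns=["label", "n_genes", "n_pairs", "mean_score"])


# -- pathway coverage ----------------------------------------------------------


@dataclass(frozen=True)
class PathwayModel:
    """A metabolic pathway as reaction steps with catalyzing genes."""

    pathway_id: str
    steps: frozenset[str]
    catalysts: frozenset[tuple[str, str]]  # (step_id, gene_id)

    def __post_init__(self) -> None:
        unknown = {s for s, _ in self.catalysts} - self.steps
        if unknown:
            raise AnalysisError(
                f"pathway {self.pathway_id}: catalysts reference unknown steps "
                f"{sorted(unknown)}"
            )


def read_pathways(path: str | Path) -> dict[str, PathwayModel]:
    """Read ``pathway_id, step_id, gene_id`` TSV (gene_id may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    steps: dict[str, set[str]] = {}
    catalysts: dict[str, set[tuple[str, str]]] = {}
    for _, row in df.iterrows():
        pid = row["pathway_id"].strip()
        step = row["step_id"].strip()
        steps.setdefault(pid, set()).add(step)
        gene = row.get("gene_id", "").strip()
        if gene:
            catalysts.setdefault(pid, set()).add((step, gene))
    return {
        pid: PathwayModel(pid, frozenset(s), frozenset(catalysts.get(pid, set())))
        for pid, s in steps.items()
    }


def pathway_coverage(pw: PathwayModel, curated_genes: Iterable[str]) -> float:
    """Fraction of steps catalyzed by >= 1 curated gene; each step counts once."""
    if not pw.steps:
        raise AnalysisError(f"pathway {pw.pathway_id} has no steps")
    curated = set(curated_genes)
    covered = {step for step, gene in pw.catalysts if gene in curated}
    return len(covered) / len(pw.steps)
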