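"""Pairwise semantic phenotype similarity (simphen) and the sparse network.

The similarity of two genotypes is the Jaccard index of their inferred phene
sets:

    simphen = |P_geno_A ∩ P_geno_B| / |P_geno_A ∪ P_geno_B|

A score of 1 means the two genotypes carry identical semantic phenotype
descriptions; 0 means no overlap at all.  The all-vs-all matrix over n
genotypes is conceptually n x n, but only scores strictly greater than zero
are stored (self-similarity is identically 1 and is not stored either), so
the network stays sparse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .infer import PhenotypeProfile

#: scores are printed with 10 decimal digits (e.g. 0.6666666667)
SCORE_DIGITS = 10


class SimilarityError(Exception):
    pass


def format_score(score: float) -> str:
    return f"{score:.{SCORE_DIGITS}f}"


def simphen(a: PhenotypeProfile, b: PhenotypeProfile) -> float:
    """Jaccard index of the two genotypes' inferred phene sets."""
    if not a.inferred or not b.inferred:
        raise SimilarityError("simphen is undefined for empty phenotype profiles")
    inter = len(a.inferred & b.inferred)
    if inter == 0:
        return 0.0
    return inter / len(a.inferred | b.inferred)


class SimilarityMatrix:
    """Sparse symmetric genotype-by-genotype store of simphen scores > 0."""

    def __init__(
        self,
        genotype_ids: Sequence[str],
        scores: Mapping[tuple[str, str], float],
        metadata: Mapping[str, str] | None = None,
    ) -> None:
        self.genotype_ids: tuple[str, ...] = tuple(genotype_ids)
        if len(set(self.genotype_ids)) != len(self.genotype_ids):
            raise SimilarityError("duplicate genotype_id in similarity matrix")
        known = set(self.genotype_ids)
        self._scores: dict[tuple[str, str], float] = {}
        for (a, b), score in scores.items():
            if a == b:
                raise SimilarityError(f"self pair stored for {a}")
            if a not in known or b not in known:
                raise SimilarityError(f"pair ({a}, {b}) references unknown genotype")
            if not 0.0 < score <= 1.0:
                raise SimilarityError(
                    f"stored scores must lie in (0, 1], got {score} for ({a}, {b})"
                )
            self._scores[(min(a, b), max(a, b))] = score
        self.metadata: dict[str, str] = dict(metadata or {})

    def __len__(self) -> int:
        return len(self._scores)

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        for (a, b), score in sorted(self._scores.items()):
            yield a, b, score

    def __contains__(self, genotype_id: str) -> bool:
        return genotype_id in self.genotype_ids

    def get(self, a: str, b: str) -> float:
        """Score for a pair; 1 for self pairs, 0 for unstored (disjoint) pairs."""
        if a == b:
            return 1.0
        return self._scores.get((min(a, b), max(a, b)), 0.0)

    def partners(self, genotype_id: str) -> list[tuple[str, float]]:
        out = []
        for (a, b), score in self._scores.items():
            if a == genotype_id:
                out.append((b, score))
            elif b == genotype_id:
                out.append((a, score))
        return out

    # -- serialization --------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write ``genotype_a<TAB>genotype_b<TAB>score`` rows, a < b, %.10f."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("genotype_a\tgenotype_b\tscore\n")
            for a, b, score in self:
                fh.write(f"{a}\t{b}\t{format_score(score)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        scores: dict[tuple[str, str], float] = {}
        ids: set[str] = set()
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("genotype_a"):
                raise SimilarityError(f"{path}: missing similarity TSV header")
            for line in fh:
                a, b, score = line.rstrip("\n").split("\t")
                ids.update((a, b))
                scores[(a, b)] = float(score)
        return cls(sorted(ids), scores)


def all_pairs(profiles: Sequence[PhenotypeProfile]) -> SimilarityMatrix:
    """Every unordered genotype pair with simphen > 0 (self pairs excluded)."""
    if not profiles:
        raise SimilarityError("all_pairs needs at least one profile")
    ids = [p.genotype_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise SimilarityError("duplicate genotype_id among profiles")
    scores: dict[tuple[str, str], float] = {}
    ordered = sorted(profiles, key=lambda p: p.genotype_id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            score = simphen(a, b)
            if score > 0.0:
                scores[(a.genotype_id, b.genotype_id)] = score
    return SimilarityMatrix(ids, scores)


def query_similar(
    matrix: SimilarityMatrix, genotype_id: str, top_k: int | None = None
) -> list[tuple[str, float]]:
    """Ranked neighbours of a genotype: descending score, then id ascending.

    The query genotype itself is excluded; at most ``top_k`` items returned.
    """
    if genotype_id not in matrix:
        raise KeyError(genotype_id)
    ranked = sorted(matrix.partners(genotype_id), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k] if top_k is not None else ranked
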