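# Methods

## Phenotype representation

A phenotype is treated as the set of its phenes, and a phene as a
post-composed Entity–Quality statement with eight ordered slots:

```
primary_e1 | rel_primary | primary_e2 | quality | qualifier | secondary_e1 | rel_secondary | secondary_e2
```

`primary_e1` (the affected structure or process) and `quality` are
mandatory; `primary_e2` requires `rel_primary`, and `secondary_e2` requires
`secondary_e1`. Statement identity is the canonical key — the slot values
joined with `|`, absent slots rendered `-` — so set operations over phenes
are exact string-set operations. Alleles with separately described
phenotypes are separate genotypes; where no allele information exists the
gene id doubles as the genotype id.

The canonical curation table is a UTF-8 TSV with one atomized statement per
row (columns `species, gene_id, gene_symbol, genotype_id, phenotype_name,
phene_text, e1_id, e1_label, relp_id, e2_id, e2_label, q_id, q_label,
ql_id, se1_id, serel_id, se2_id`). Ids are authoritative; labels are
carried only so validation can flag typographical drift. The reader accepts
an exclusion list of `(genotype_id, canonical key)` pairs so individual
statements can be kept out of an analysis without editing the curated file.

## Ontology model and closure semantics

OBO 1.2 files are parsed with `obonet` and merged into a single typed graph
whose edges are `(child, parent, relation)` triples with relation `is_a`,
`part_of`, or `bridge`. Rather than translating the ontologies to an OWL EL
profile and classifying `has-part some (E and has-quality some Q)`
expressions with a reasoner, generalisation is computed directly as graph
closure: for this EQ grammar the named superclasses of such an expression
are exactly the statements obtained by replacing each filled slot with a
reflexive ancestor of its term. Entity slots traverse `is_a` and `part_of`
(a phene of the vascular leaf is also a phene of the whole plant); quality,
qualifier and relation slots traverse `is_a` only, because PATO and RO are
in practice pure subsumption hierarchies. `bridge` edges — optional
two-column axioms linking a biological process to the structure it acts on
— are traversed only when explicitly enabled, since their effect depends
entirely on the axiom set supplied.

Design rules around the graph:

* the graph restricted to `is_a`/`part_of` must be acyclic; a cycle is a
  hard load error because closure semantics would otherwise be undefined;
* obsolete terms stay in the term map (for validation messages and
  `replaced_by` hints) but never carry edges and cannot be closed over;
* `alt_id` aliases are resolved to canonical ids at parse time; downstream
  code sees canonical ids only, and validation reports alias usage as a
  warning rather than silently substituting.

The qualifier participates in subsumption like every other slot. No
published guidance distinguishes it, and the uniform rule is the least
surprising; it also keeps the closure a pure slot-wise cross product.
Relational qualities ("lacks parts or has fewer parts of type") are
ordinary PATO terms here, not logical negation.

The per-genotype inferred set is capped (default 10,000 keys). The cross
product of slot ancestor sets grows multiplicatively with slot count and
term depth, and hitting the cap almost always means curation at too general
a term level; the error message says so rather than silently truncating.

## Validation rules

Six machine-checkable rules (R1–R6, listed in the README) are applied per
row; issues are data with row number, rule id, severity and offending
value, never exceptions. The structural/process partition of PATO is
configured as two subtree roots rather than hard-coded, because quality
typing is an ontology-versioning question; when the roots are unset the
type-match rule (R3) is skipped. R3 is only evaluated for genuine PATO
qualities — a wrong-namespace quality is already an R2 error. Label
comparison (R5) is case-insensitive and whitespace-normalised: it exists to
catch typos, not to canonicalise case conventions.

## Similarity and analyses

`simphen` is the Jaccard index over inferred phene sets. Scores are
computed for every unordered genotype pair and stored sparsely: zero scores
and self pairs (identically 1) are never materialised, matching how such
networks are distributed. Frequency-weighted measures (information-content
style) are deliberately out of scope. Ranked queries sort by descending
score with lexicographic genotype-id tie-break; scores serialise with ten
decimal digits.

Distribution binning uses `(0, 0.1], (0.1, 0.2], ..., (0.9, 1]` so a score
of 1 lands in the top bin and zeros are excluded by construction. A pair is
scoped to a species iff both genotypes share it, else to the cross-species
scope; the overall scope counts every stored pair once. Percentages are
rounded half-up to integers for report parity.

For comparison against a gene-level classification (one class per gene,
any number of subsets), the score between two genes is aggregated over
their allele genotypes — `max` by default, `mean` as an option — because
the external classification labels genes while the network scores
genotypes, and the better-characterised allele is usually the labelled
phenotype. Same-label gene pairs absent from the sparse matrix contribute
0; labels with fewer than two scorable genes report `n_pairs = 0` and an
undefined mean. Pathway-step coverage is the fraction of a pathway's steps
catalysed by at least one curated gene, each step counted once however many
curated genes catalyse it.

## Synthetic data

The generator emulates the *shape* of a curation effort, not its content:
rooted random DAG ontologies (every non-root term gets 1..`max_parents`
parents among strictly shallower terms, a mix of `is_a` and `part_of`
edges) and multi-species datasets whose genotypes draw (entity, quality)
phenes from a shared pool with reuse probability `overlap`. Defaults —
60-term ontologies of depth 5, 40 genotypes over 6 species, 1–5 phenes per
genotype — mirror a modest multi-species effort (curated genotypes average
about two phenes each). `overlap` directly controls expected semantic
overlap, which is what the stochastic tests exploit: across 20 replicate
seeds, mean pairwise simphen at `overlap = 0.9` must beat `overlap = 0` in
at least 15 (one-sided sign test, p < 0.05 under the null).

What the generator does *not* emulate: realistic PO/GO topology or term
granularity, correlated phenes within a genotype, curator disagreement, or
species-biased annotation depth. Passing tests on synthetic data therefore
demonstrate algorithmic correctness (closure, scoring, aggregation), not
that real curation will show any particular score distribution.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; independent streams decorrelate the entity
ontology, quality ontology and dataset draws from one seed. No global RNG
state is touched.

## Packaged fixtures

Three small hand-built fixtures make the worked examples executable: the
corngrass phenotype (five phenes, including the "narrow leaves" statement
reused by other phenotypes), the mac1 sterility example (the asserted
quality "male and female infertility" sits under "complete sterility" in
the mini quality ontology, so closure infers a complete-sterility phene),
and the anthocyanin quartet (c2/c1/r1/b1) whose mini ontology is
deliberately flat so the inferred sets equal the asserted sets and the
query against c2 lands exactly on 1, 2/3 and 1/2. Real PO/PATO/ChEBI ids
are used where published; the remaining ids are plausible placeholders and
the mini ontologies are miniature stand-ins, not extracts of the real
ontologies. Transcriptions of the published per-species annotation summary
and network headline counts are packaged as data inputs for the
report-parity arithmetic in `scripts/acceptance.py`.

## Numerical and scale choices

Everything here is exact set arithmetic over strings; the only numerics are
Jaccard ratios (double precision) and half-up integer percentages via
`decimal`. Test problem sizes — 100 random DAGs for the closure oracle, 100
random instances for the subsumption oracle, 1,000 triples for the
Jaccard-distance triangle inequality, 50 genotypes for the all-pairs
brute-force comparison, 20 replicates for the overlap sign test — keep the
full suite around a few seconds while exercising every code path at sizes
where brute-force oracles are feasible.

## Known limitations

* Closure is slot-wise only: it never drops slots, so a statement with a
  filled qualifier is not generalised to one without it, although the
  `subsumes` predicate does treat absent slots in the more general
  statement as unconstrained.
* Bridge axioms are a stand-in for published structure↔process logical
  definitions whose exact content is not distributed; they are off by
  default.
* Gene-level aggregation (`max`/`mean`) is a configuration choice; the
  historically used aggregation for published class/subset averages is not
  recorded anywhere we can check.
* The validator implements the six rules that are publicly documented;
  additional project-specific rules belong in configuration, not code.
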