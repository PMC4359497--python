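# phenesim

Cross-species plant phenomics through post-composed **Entity–Quality (EQ)
phenotype annotation**, ontology closure, and semantic similarity networks.

Mutant phenotypes curated for different plant species (Arabidopsis, maize,
rice, tomato, Medicago, soybean, ...) are written in species-specific free
text and cannot be compared directly. `phenesim` supports the workflow that
makes them comparable:

1. each free-text phenotype is decomposed into atomized *phenes*, and each
   phene becomes an EQ statement built from species-independent ontologies
   (PO for plant structures, GO for processes and cellular components, PATO
   for qualities, ChEBI for chemicals, RO for relations), following the
   generalized grammar

   ```
   [(primary E1) - R - (primary E2)] - [Q - QL] - [(secondary E1) - R - (secondary E2)]
   ```

   with primary E1 and Q mandatory and every other slot optional;
2. automated quality-assurance rules check each statement (entity namespace,
   PATO quality, quality-type/entity-type match, id resolution, label/id
   agreement, RO relations) and produce machine-readable reports;
3. each genotype's *inferred phene set* `P_geno` is computed by ontology
   closure — every statement implies each slot-wise generalisation of
   itself over `is_a`/`part_of` ancestors;
4. pairwise semantic phenotype similarity is a Jaccard index over inferred
   sets,

   ```
   simphen(A, B) = |P_geno_A ∩ P_geno_B| / |P_geno_A ∪ P_geno_B|
   ```

   stored sparsely (only scores > 0) for all-vs-all genotype networks and
   ranked similarity queries;
5. downstream analyses summarise the network: binned score distributions
   split into per-species and cross-species scopes, average within-group
   similarity against an external gene classification, and metabolic
   pathway-step coverage by phenotype-curated genes.

A synthetic-data module generates random rooted-DAG ontologies and
multi-species EQ datasets with a tunable phene-reuse probability, so the
whole pipeline is testable without downloading any ontology.

## Worked example

The package ships a hand-built fixture modelled on the maize anthocyanin
pathway: genotypes *c2*, *c1*, *r1*, *b1* with overlapping phenes such as
"lack of anthocyanins in aleurone" (aleurone layer, PO:0005360, *lacks
parts or has fewer parts of type*, PATO:0001999, anthocyanins,
CHEBI:38697). Querying the network for the genotypes most similar to *c2*:

```python
from phenesim import fixtures, infer, similarity

ont = fixtures.load_anthocyanin_ontology()
profiles = infer.infer_dataset(fixtures.load_anthocyanin(), ont)
matrix = similarity.all_pairs(profiles)
for genotype, score in similarity.query_similar(matrix, "c2", 3):
    print(genotype, similarity.format_score(score))
```

prints

```
c1 1.0000000000
r1 0.6666666667
b1 0.5000000000
```

*c1* shares both of *c2*'s phenes and nothing else (identical inferred
sets, score 1); *r1* adds one extra phene (2 shared of 3 total, 2/3); *b1*
adds two (2 of 4, 1/2). All three genes are regulators or enzymes of the
same flavonoid pathway, which is exactly the kind of functional
relationship the phenotype network is meant to surface.

The same machinery runs from the shell:

```bash
phenesim infer --dataset anthocyanin.tsv --obo anthocyanin_mini.obo --out profiles.tsv
phenesim simmatrix --profiles profiles.tsv --out sims.tsv
phenesim query --sims sims.tsv --genotype c2 --top 3
```

See `phenesim --help` for the full command list (`ontology-stats`,
`validate`, `infer`, `simmatrix`, `query`, `dist`, `groups`, `pathway`,
`simulate`, `convert`).

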