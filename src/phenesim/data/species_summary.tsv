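species	n_eqs	n_unique_eqs	n_genes	n_genotypes	n_phenotypes
Arabidopsis thaliana	5172	1260	2393	2393	1385
Zea mays	373	180	114	169	117
Oryza sativa	340	271	92	95	86
Solanum lycopersicum	269	174	72	128	90
Medicago truncatula	149	99	40	45	40
Glycine max	61	39	30	30	24
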