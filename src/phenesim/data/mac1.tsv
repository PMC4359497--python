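species	gene_id	gene_symbol	genotype_id	phenotype_name	phene_text	e1_id	e1_label	relp_id	e2_id	e2_label	q_id	q_label	ql_id	se1_id	serel_id	se2_id
Zea mays	GRMZM2G104092	mac1	mac1	multiple archesporial cells	male and female infertility	PO:0000003	whole plant				PATO:0090003	male and female infertility				
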