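species	gene_id	gene_symbol	genotype_id	phenotype_name	phene_text	e1_id	e1_label	relp_id	e2_id	e2_label	q_id	q_label	ql_id	se1_id	serel_id	se2_id
Zea mays	GRMZM2G022489	cg1	cg1	corngrass	narrow leaves	PO:0009025	vascular leaf				PATO:0000599	decreased width				
Zea mays	GRMZM2G022489	cg1	cg1	corngrass	extreme tillering	PO:0004356	tiller				PATO:0000470	increased amount				
Zea mays	GRMZM2G022489	cg1	cg1	corngrass	highly reduced ears	PO:0020136	ear inflorescence				PATO:0000587	decreased size				
Zea mays	GRMZM2G022489	cg1	cg1	corngrass	highly reduced tassel	PO:0020126	tassel inflorescence				PATO:0000587	decreased size				
Zea mays	GRMZM2G022489	cg1	cg1	corngrass	vegetative leaves in the ear	PO:0025034	leaf	BFO:0000050	PO:0020136	ear inflorescence	PATO:0000460	abnormal				
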