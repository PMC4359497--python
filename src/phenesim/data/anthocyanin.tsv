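species	gene_id	gene_symbol	genotype_id	phenotype_name	phene_text	e1_id	e1_label	relp_id	e2_id	e2_label	q_id	q_label	ql_id	se1_id	serel_id	se2_id
Zea mays	GRMZM2G422750	c2	c2	colorless kernel	lack of anthocyanins in aleurone	PO:0005360	aleurone layer				PATO:0001999	lacks parts or has fewer parts of type		CHEBI:38697		
Zea mays	GRMZM2G422750	c2	c2	colorless kernel	colorless pericarp	PO:0009084	pericarp				PATO:0090020	colorless				
Zea mays	GRMZM2G005066	c1	c1	colorless aleurone	lack of anthocyanins in aleurone	PO:0005360	aleurone layer				PATO:0001999	lacks parts or has fewer parts of type		CHEBI:38697		
Zea mays	GRMZM2G005066	c1	c1	colorless aleurone	colorless pericarp	PO:0009084	pericarp				PATO:0090020	colorless				
Zea mays	GRMZM5G822829	r1	r1	colored aleurone and plant	lack of anthocyanins in aleurone	PO:0005360	aleurone layer				PATO:0001999	lacks parts or has fewer parts of type		CHEBI:38697		
Zea mays	GRMZM5G822829	r1	r1	colored aleurone and plant	colorless pericarp	PO:0009084	pericarp				PATO:0090020	colorless				
Zea mays	GRMZM5G822829	r1	r1	colored aleurone and plant	reduced plant pigmentation	PO:0000003	whole plant				PATO:0090021	decreased pigmentation				
Zea mays	GRMZM2G172795	b1	b1	colored plant	lack of anthocyanins in aleurone	PO:0005360	aleurone layer				PATO:0001999	lacks parts or has fewer parts of type		CHEBI:38697		
Zea mays	GRMZM2G172795	b1	b1	colored plant	colorless pericarp	PO:0009084	pericarp				PATO:0090020	colorless				
Zea mays	GRMZM2G172795	b1	b1	colored plant	green stem	PO:0009047	stem				PATO:0000320	green				
Zea mays	GRMZM2G172795	b1	b1	colored plant	yellow anther	PO:0009066	anther				PATO:0090022	yellow				
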