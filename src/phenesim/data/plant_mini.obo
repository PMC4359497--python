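format-version: 1.2
ontology: plant_mini
default-namespace: plant_structure
remark: hand-built miniature plant anatomy ontology for packaged worked examples

[Term]
id: PO:0009011
name: plant structure

[Term]
id: PO:0000003
name: whole plant
is_a: PO:0009011 ! plant structure

[Term]
id: PO:0025034
name: leaf
is_a: PO:0009011 ! plant structure

[Term]
id: PO:0009025
name: vascular leaf
alt_id: PO:0000925
is_a: PO:0025034 ! leaf
relationship: part_of PO:0000003 ! whole plant

[Term]
id: PO:0009049
name: inflorescence
is_a: PO:0009011 ! plant structure

[Term]
id: PO:0020136
name: ear inflorescence
is_a: PO:0009049 ! inflorescence
relationship: part_of PO:0000003 ! whole plant

[Term]
id: PO:0020126
name: tassel inflorescence
is_a: PO:0009049 ! inflorescence
relationship: part_of PO:0000003 ! whole plant

[Term]
id: PO:0004356
name: tiller
is_a: PO:0009011 ! plant structure
relationship: part_of PO:0000003 ! whole plant

[Term]
id: PO:0009046
name: flower
is_a: PO:0009011 ! plant structure

[Term]
id: PO:0099999
name: leaf lamina (obsolete)
is_obsolete: true
replaced_by: PO:0025034
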