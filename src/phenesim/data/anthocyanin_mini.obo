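format-version: 1.2
ontology: anthocyanin_mini
default-namespace: anthocyanin_example
remark: deliberately flat (parentless) term set so the worked anthocyanin-pathway example has closure sets equal to its asserted sets

[Term]
id: PO:0005360
name: aleurone layer

[Term]
id: PO:0009084
name: pericarp

[Term]
id: PO:0000003
name: whole plant

[Term]
id: PO:0009047
name: stem

[Term]
id: PO:0009066
name: anther

[Term]
id: CHEBI:38697
name: anthocyanin cation

[Term]
id: PATO:0001999
name: lacks parts or has fewer parts of type

[Term]
id: PATO:0090020
name: colorless

[Term]
id: PATO:0090021
name: decreased pigmentation

[Term]
id: PATO:0000320
name: green

[Term]
id: PATO:0090022
name: yellow
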