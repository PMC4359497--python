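format-version: 1.2
ontology: ro_mini
default-namespace: relation
remark: hand-built miniature relation slice; part_of lives in the BFO namespace

[Term]
id: BFO:0000050
name: part_of

[Term]
id: RO:0002202
name: develops from
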