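format-version: 1.2
ontology: go_mini
remark: hand-built miniature GO slice (process and component branches) for packaged worked examples

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0009908
name: flower development
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0005575
name: cellular_component
namespace: cellular_component

[Term]
id: GO:0005634
name: nucleus
namespace: cellular_component
is_a: GO:0005575 ! cellular_component
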