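format-version: 1.2
ontology: pato_mini
default-namespace: quality
remark: hand-built miniature quality ontology for packaged worked examples; the sterility branch supports the complete-sterility inference example

[Term]
id: PATO:0000001
name: quality

[Term]
id: PATO:0001241
name: physical object quality
is_a: PATO:0000001 ! quality

[Term]
id: PATO:0001236
name: process quality
is_a: PATO:0000001 ! quality

[Term]
id: PATO:0000117
name: size
is_a: PATO:0001241 ! physical object quality

[Term]
id: PATO:0000587
name: decreased size
is_a: PATO:0000117 ! size

[Term]
id: PATO:0000921
name: width
is_a: PATO:0001241 ! physical object quality

[Term]
id: PATO:0000599
name: decreased width
is_a: PATO:0000921 ! width

[Term]
id: PATO:0000122
name: length
is_a: PATO:0001241 ! physical object quality

[Term]
id: PATO:0000574
name: decreased length
is_a: PATO:0000122 ! length

[Term]
id: PATO:0000070
name: amount
is_a: PATO:0001241 ! physical object quality

[Term]
id: PATO:0000470
name: increased amount
is_a: PATO:0000070 ! amount

[Term]
id: PATO:0001999
name: lacks parts or has fewer parts of type
is_a: PATO:0000070 ! amount

[Term]
id: PATO:0000014
name: color
is_a: PATO:0001241 ! physical object quality

[Term]
id: PATO:0000320
name: green
is_a: PATO:0000014 ! color

[Term]
id: PATO:0000460
name: abnormal
is_a: PATO:0001241 ! physical object quality

[Term]
id: PATO:0090001
name: sterile
is_a: PATO:0001241 ! physical object quality

[Term]
id: PATO:0090002
name: complete sterility
is_a: PATO:0090001 ! sterile

[Term]
id: PATO:0090003
name: male and female infertility
is_a: PATO:0090002 ! complete sterility

[Term]
id: PATO:0090004
name: male sterile
is_a: PATO:0090001 ! sterile

[Term]
id: PATO:0000502
name: delayed
is_a: PATO:0001236 ! process quality
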