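# bridge axioms: process term -> structure it acts on
GO:0009908	PO:0009046
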