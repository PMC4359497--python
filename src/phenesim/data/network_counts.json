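{
  "n_genotypes": 2866,
  "n_nonzero_pairs": 548888,
  "n_pairs_low_bin": 241042,
  "n_pairs_top_bin": 71290
}
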