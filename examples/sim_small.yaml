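n_founders: 200
n_per_generation: 200
n_sires: 10
n_dams: 100
n_loci: 300
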