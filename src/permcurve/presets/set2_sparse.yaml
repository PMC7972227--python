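# Zero-inflated design with sparse signal: as set2_dense but only the
# first 30 features are differential.
kind: zero_inflated
params: {n1: 30, n2: 30, p: 100, nsv: 30, pi: 0.1, mu: 1.0, var: 0.2,
         shift_max: 3.0, shift_min: 0.3}
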