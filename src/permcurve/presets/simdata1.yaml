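# Heterogeneous two-group design, mildest heterogeneity level:
# group 1 split into two subgroup blocks, group 2 homogeneous.
kind: subgroups
p: 100
rho: 0.5
blocks:
  - {n: 8, group: 1, kappa: 2, mean: [[6, 30], [4, 30], [1, 40]]}
  - {n: 22, group: 1, kappa: 36, mean: [[4, 30], [6, 30], [1, 40]]}
  - {n: 30, group: 2, kappa: 36, mean: [[15, 30], [0.5, 30], [1, 40]]}
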