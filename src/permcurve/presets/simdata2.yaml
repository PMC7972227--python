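# Intermediate heterogeneity: both groups split into two subgroup blocks;
# the last block draws its per-feature means from N(mu0, var0).
kind: subgroups
p: 100
rho: 0.5
blocks:
  - {n: 16, group: 1, kappa: 25, mean: [[8, 30], [2, 30], [1, 40]]}
  - {n: 14, group: 1, kappa: 24, mean: [[2, 30], [8, 30], [1, 40]]}
  - {n: 20, group: 2, kappa: 26, mean: [[15, 30], [0.5, 30], [1, 40]]}
  - {n: 10, group: 2, kappa: 24, random_mean: [[5, 1.2, 60], [1, 0.1, 40]]}
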