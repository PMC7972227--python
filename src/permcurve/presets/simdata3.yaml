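# Strongest heterogeneity level: small dispersions and a contrarian
# 6-sample block inside group 1.
kind: subgroups
p: 100
rho: 0.5
blocks:
  - {n: 24, group: 1, kappa: 14, mean: [[8, 30], [2, 30], [1, 40]]}
  - {n: 6, group: 1, kappa: 14, mean: [[1, 30], [10, 30], [1, 40]]}
  - {n: 20, group: 2, kappa: 14, mean: [[15, 30], [0.5, 30], [1, 40]]}
  - {n: 10, group: 2, kappa: 12, random_mean: [[5, 1.6, 60], [1, 0.3, 40]]}
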