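# Homogeneous NB-copula benchmark grid: correlation x signal density x
# group mean difference x dispersion, 30 samples per group, 100 features.
# Group-1 mean is 10 for the first nsv features; group-2 mean 1/6/10 gives
# mean differences 9/4/0.
kind: grid
rows:
  - {rho: 0.5, nsv: 30, mean1: 10, mean2: 1, kappa: 24}
  - {rho: 0.5, nsv: 30, mean1: 10, mean2: 1, kappa: 1}
  - {rho: 0.5, nsv: 30, mean1: 10, mean2: 6, kappa: 24}
  - {rho: 0.5, nsv: 30, mean1: 10, mean2: 6, kappa: 1}
  - {rho: 0.5, nsv: 30, mean1: 10, mean2: 10, kappa: 24}
  - {rho: 0.5, nsv: 30, mean1: 10, mean2: 10, kappa: 1}
  - {rho: 0.5, nsv: 90, mean1: 10, mean2: 1, kappa: 24}
  - {rho: 0.5, nsv: 90, mean1: 10, mean2: 1, kappa: 1}
  - {rho: 0.5, nsv: 90, mean1: 10, mean2: 6, kappa: 24}
  - {rho: 0.5, nsv: 90, mean1: 10, mean2: 6, kappa: 1}
  - {rho: 0.5, nsv: 90, mean1: 10, mean2: 10, kappa: 24}
  - {rho: 0.5, nsv: 90, mean1: 10, mean2: 10, kappa: 1}
  - {rho: 0.8, nsv: 30, mean1: 10, mean2: 1, kappa: 24}
  - {rho: 0.8, nsv: 30, mean1: 10, mean2: 1, kappa: 1}
  - {rho: 0.8, nsv: 30, mean1: 10, mean2: 6, kappa: 24}
  - {rho: 0.8, nsv: 30, mean1: 10, mean2: 6, kappa: 1}
  - {rho: 0.8, nsv: 30, mean1: 10, mean2: 10, kappa: 24}
  - {rho: 0.8, nsv: 30, mean1: 10, mean2: 10, kappa: 1}
  - {rho: 0.8, nsv: 90, mean1: 10, mean2: 1, kappa: 24}
  - {rho: 0.8, nsv: 90, mean1: 10, mean2: 1, kappa: 1}
  - {rho: 0.8, nsv: 90, mean1: 10, mean2: 6, kappa: 24}
  - {rho: 0.8, nsv: 90, mean1: 10, mean2: 6, kappa: 1}
  - {rho: 0.8, nsv: 90, mean1: 10, mean2: 10, kappa: 24}
  - {rho: 0.8, nsv: 90, mean1: 10, mean2: 10, kappa: 1}
defaults: {n1: 30, n2: 30, p: 100}
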