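# permcurve

Progressive label permutation for assessing the **strength and robustness**
of feature–group associations in microbiome abundance data.

Differential-abundance screens (e.g. a Wilcoxon rank-sum test per taxon)
answer *which features are significant*, but not *how robust* those calls
are: heterogeneity across subjects can mask a real group effect, and
multiple-testing corrections on hundreds of taxa are often over-conservative.
`permcurve` takes a different route. It progressively mixes the two group
labels — exchanging `k` randomly chosen samples from each group, for
`k = 0` (the observed data) up to `K = min(n1, n2)` — and re-tests every
feature at every mixing depth. Real signals decay visibly as mixing deepens;
noise does not care. The resulting p-value traces are summarized as a
U-shaped curve of significant-feature counts, scalar curve statistics, a
per-feature fragility index, and a robust-feature selection against the
fully mixed null.

## The method

For a samples × features table `X` and a binary grouping factor with group
sizes `n1`, `n2` (`N = n1 + n2`):

- **Scenario grid.** Depth `k` has `C(n1,k)·C(n2,k)` distinct label
  arrangements, maximal at the *full-mixing* depth
  `K_f = ⌈(n1·n2 − 1)/(n1 + n2 + 2)⌉` (for balanced groups,
  `⌈(n−1)/2⌉`), which serves as the fully mixed null. Summed over `k`,
  the arrangement counts obey the Vandermonde identity
  `Σ_k C(n1,k)·C(n2,k) = C(N, K)`.
- **Draw budget.** Each depth `k ≥ 1` is explored with
  `ν = round(N·(ln C(n1,k) + ln C(n2,k)))` independent draws (floored at 1,
  capped at the number of distinct arrangements); `k = 0` is the observed
  data, a single draw.
- **Traces.** Every draw yields one two-sided p-value per feature
  (Wilcoxon rank-sum by default; rank correlations for a continuous
  outcome; a known-σ Z-test and a custom hook are also available).
  Per feature and depth, draws are summarized by the median `p_j^m(k)`
  and 2.5–97.5% quantiles.
- **U-curve.** `nsig(k) = Σ_j 1{p_j^m(k) ≤ α}` with `α = 0.05` by default.
  The curve of `nsig(k)/p` against the mixing proportion `k/K` is U-shaped
  for balanced designs. Its summaries: **AOI** `= nsig(0)/p`, **AUMC**
  `= ∫ nsig/p d(k/K)` (trapezoid), the initial slope, and the mean slope
  of the first `K_f` segments.
- **Fragility.** `FI_j = min{k ≤ K_f : p_j^m(k) > α}` (capped at `K_f`),
  the number of label exchanges needed to break feature *j*'s
  significance; `sFI_j = FI_j / K_f`.
- **Selection.** Feature *j* is kept iff `p_j(0) ≤ α` **and**
  `−log10 p_j(0)` exceeds the 97.5% quantile of its `−log10 p` draws at
  `K_f` — its observed signal must beat its own fully-mixed null band.
- **Closed-form oracle.** For Gaussian groups with known common σ and
  standardized mean difference `δ = (m1 − m2)/σ ≥ 0`, the two-sided
  Z-test trajectory is available in closed form,
  `p(k) = 2Φ(−√(n1·n2 / (2(n1+n2))) · (1 − (n1+n2)k/(n1·n2)) · δ)` for
  `k ≤ K_f` and its mirrored branch after, and is used to validate the
  permutation engine exactly.

The package also ships the synthetic designs used for validation:
negative-binomial counts (variance `m + m²/κ`) coupled by a Gaussian
copula with AR(1) correlation `ρ^|i−j|`, blocked heterogeneous-subgroup
variants, and a zero-inflated lognormal generator.

## Worked example

`ProgressivePermutation` is a scikit-learn feature selector: `fit(X, y)`,
then `get_support()` / `transform(X)`, with all summaries as fitted
attributes.

```python
from permcurve import ProgressivePermutation, NBCopulaSpec, nb_copula_dataset

# 30+30 samples, 100 features; the first 30 have group means 10 vs 1
X, y = nb_copula_dataset(NBCopulaSpec(seed=1))
pp = ProgressivePermutation(random_state=1).fit(X, y)
print(pp.summary())
```

prints (abridged):

```
{'n1': 30, 'n2': 30, 'K': 30, 'K_f': 15, 'alpha': 0.05, 'seed': 1,
 'n_features': 100, 'nsig_observed': 32, 'aoi': 0.32,
 'aumc': 0.21166666666666673, 'slope0': 0.0,
 'slope_avg': -0.6400000000000001, 'n_selected': 31,
 'mean_scaled_fragility': 0.22266666666666665}
```

Reading this: 32 of 100 features are significant in the observed data
(the 30 truly shifted features plus two false positives at the nominal
5% level, so AOI = 0.32). The initial slope 0 says the signal is stable
under the first label exchange; the curve then falls to its minimum at
`K_f = 15` (average early slope −0.64 in proportion units). AUMC = 0.212
quantifies how much of that significance survives mixing. 31 features
beat their fully-mixed null bands and are selected. The most robust
features:

```python
pp.fragility_.to_frame().sort_values("rank").head(3)
```

```
feature  fragility_index  scaled_fragility  rank
     F1               11          0.733333     1
     F2               11          0.733333     2
     F3               11          0.733333     3
```

Each top feature tolerates 11 of the 15 exchanges to full mixing before
its median p-value crosses α. The same pipeline runs from the shell:

```bash
permcurve simulate --preset simdata1 --seed 1 --out sim/
permcurve run --table sim/table.tsv --metadata sim/metadata.tsv \
    --group-col group --seed 1 --out results/ --plots
permcurve analytic --n1 20 --n2 20 --delta 1.0
```

`run` writes `traces.tsv`, `curve.tsv`, `fragility.tsv`, `selection.tsv`,
`summary.json` and (optionally) the trace, U-curve, fragility and
coverage plots.

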