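# Methods

## The procedure

Given a samples × features abundance table and a binary grouping factor
with group sizes `n1`, `n2` (`N = n1 + n2`), progressive permutation
constructs one scenario per mixing depth `k = 0 … K = min(n1, n2)`. A draw
at depth `k` starts from the *original* labels (draws are never chained),
picks a uniform `k`-subset of each group and exchanges their labels, so
every draw preserves the group sizes and differs from the observed labels
in exactly `2k` positions. Depth `K_f = ⌈(n1·n2 − 1)/(n1 + n2 + 2)⌉`
maximizes the number of distinct arrangements `C(n1,k)·C(n2,k)` and is
treated as the fully mixed null.

Each depth `k ≥ 1` receives `ν_k = round(N·(ln C(n1,k) + ln C(n2,k)))`
draws. The logarithm is natural: the formula is a sampling budget, and any
fixed base only rescales it. Budgets are floored at 1 (a depth whose only
arrangement is forced still gets evaluated) and capped at the exact number
of distinct arrangements. Draws are sampled **with** replacement across the
arrangement space — collisions are vanishingly rare except at tiny depths,
where the cap applies anyway. Each draw's RNG stream derives from
`SeedSequence([seed, k, draw_index])`, so results are bit-reproducible and
independent of which depths are evaluated or in what order.

Per draw, every feature is tested for association with the permuted
grouping; per feature and depth, the draws are summarized by the median
p-value and its 2.5/97.5% quantiles. All downstream statistics — the
significant-count curve `nsig(k) = Σ_j 1{p_j^m(k) ≤ α}` (threshold
inclusive), AOI = `nsig(0)/p`, the trapezoidal AUMC of `nsig(k)/p` over
`k/K`, the initial and mean-of-first-`K_f`-segments slopes (both on the
proportion curve), the fragility index
`FI_j = min{k ≤ K_f : p_j^m(k) > α}` capped at `K_f` when significance
never breaks, `sFI_j = FI_j/K_f`, and the selection rule (observed
`p_j(0) ≤ α` **and** `−log10 p_j(0)` above the 97.5% quantile of the
feature's own `−log10 p` draws at `K_f`) — are computed from these
summaries. The curve's error bands come from per-draw significant counts,
while the curve point itself uses the median-p definition; the two views
coincide in expectation but not draw-by-draw.

## Tests

The default per-feature test is the two-sided Wilcoxon rank-sum
(Mann–Whitney) test: exact null distribution when `min(n1, n2) ≤ 25` and
the pooled feature is tie-free, otherwise the normal approximation with
tie and continuity correction (matching `scipy.stats.mannwhitneyu`
bit-for-bit; asserted in the suite). A pooled all-tied feature returns
p = 1 — zero-variance features are common in sparse tables and must not
poison counts with NaNs. Because pooled ranks and tie corrections do not
depend on the labels, all draws at one depth reduce to a single
membership-matrix × rank-matrix product, which is what makes full grids
(tens of thousands of draws) run in seconds.

A continuous outcome replaces label exchange by partial permutation: a
draw at depth `k` selects `k` samples uniformly and shuffles their outcome
values among themselves (an unconstrained uniform shuffle — forcing a
derangement would bias small depths), with the grid running to `k = N` as
the fully mixed scenario and budgets `round(N·ln C(N,k))`, the natural
continuous analogue of the binary budget. Spearman (default) or Kendall
rank correlations supply the p-values. A known-σ two-sample Z-test and an
arbitrary `(values, labels) → p` callable complete the registry; the
callable is the escape hatch for external machinery (e.g. model-based
differential-abundance p-values) without this package wrapping those
tools.

## The closed-form oracle

For Gaussian groups `N(m1, σ²)` vs `N(m2, σ²)` with known σ and
`δ = (m1 − m2)/σ ≥ 0`, exchanging `k` labels shrinks the expected mean
difference by `1 − (n1+n2)k/(n1·n2)`, giving
`p(k) = 2Φ(−√(n1·n2/(2(n1+n2))) · (1 − (n1+n2)k/(n1·n2)) · δ)` for
`k ≤ K_f`, with the sign mirrored after `K_f`. The formula is implemented
exactly as printed, including the factor 2 under the root; equivalently,
both branches equal `2Φ(−|expected standardized difference|/√2)`. The
fragility index of this trajectory inverts in closed form,
`FI = ⌊(1 − z_{α/2}/(c·δ))/a⌋ + 1` clipped to `[0, K_f]` with
`c = √(n1·n2/(2(n1+n2)))`, `a = (n1+n2)/(n1·n2)`, and is cross-checked
against a grid scan.

Validating the empirical engine against this oracle needs one care: the
closed form folds the *expected signed* statistic through `2Φ(−|·|)`,
whereas a per-draw two-sided p-value uses the realized `|z|` — near full
mixing the realized `|z|` is half-normal, so the median two-sided p is
about 0.5 while the closed form gives 1. The comparison therefore takes
the median *signed* z over draws and replicate features at each depth and
folds it through the same transform (medians commute with each monotone
branch), scaled with the oracle's own √2 convention. Agreement is within
Monte-Carlo tolerance (< 0.05 at 500 draws per scenario and 1000 feature
replicates) across the grid.

## Synthetic designs

`nb_copula_dataset` draws `Z ~ N(0, R)` with AR(1) correlation
`R_ij = ρ^|i−j|` (the printed `ρ^{i−j}` is asymmetric and cannot be a
correlation matrix; the AR(1) reading is standard) and transforms
feature-wise by the negative-binomial quantile function with size = κ,
mean = m, so the variance is `m + m²/κ` and marginals are exact (checked
by a Kolmogorov–Smirnov distance within the DKW band at n = 10⁴). The
default parameterization is the strong-signal benchmark: 30 samples per
group, 100 features, the first 30 with means 10 vs 1, κ = 24, ρ = 0.5.

`heterogeneous_dataset` composes per-subgroup NB-copula blocks with their
own mean vectors and dispersions. The shipped presets `simdata1/2/3`
realize three increasing heterogeneity levels (60 samples, 100 features,
60 truly differential); blocks whose means are drawn as `RN(μ0, σ0²)` draw
one value **per feature** (the natural reading of a random mean sequence),
truncated below at 0.01 to keep NB means positive.

`zero_inflated_dataset` sets each entry to zero with per-feature
probability `π_j`, otherwise draws a lognormal moment-matched to the
requested positive-part mean and variance and rounds to a count (rounding
can only add zeros, so the observed zero fraction is ≥ `π_j`);
non-positive means are structural zeros. The `set2_dense`/`set2_sparse`
presets fix `π = 0.1`, variance 0.2, baseline mean 1, and give the first
70 (resp. 30) features group-mean shifts decreasing linearly from 3.0 to
0.3 — a chosen concretization of "decreasing mean differences", since
only the qualitative design is specified.

An optional compositional step divides **all** entries by one global
constant, 1.1 × the largest sample sum. A per-sample total-sum scaling is
deliberately not the default: it breaks cross-sample rank invariance and
thereby changes every rank-based result, whereas the global constant
leaves them bit-identical (asserted end to end).

What the generators do *not* emulate: taxonomic structure, per-sample
sequencing-depth variation, and parameters fitted to any real cohort.
Passing tests therefore demonstrate correctness of the machinery and
behavior under controlled signal/noise/heterogeneity/zero-inflation
regimes, not performance claims about any particular real dataset.

## Numerical choices

- Quantiles use NumPy's default linear interpolation (type 7) throughout,
  for a fixed bit-reproducible convention.
- `−log10 p` floors p at 1e-300 before the logarithm.
- Significance is inclusive (`p ≤ α`), α = 0.05 by default.
- `FI` is searched on the evaluated grid only; with a thinned grid
  (`k_step > 1`) the resolution coarsens accordingly, but depths 0, `K_f`
  and `K` are always evaluated so AOI, the selection band and the
  symmetric endpoint never disappear. `K_f = 0` (singleton groups) makes
  `sFI` undefined: a warning is raised and only `FI` is returned.
- The estimator's `random_state` defaults to 0 rather than None: a
  permutation analysis should be reproducible unless the user opts out by
  choosing their own seed.
- Feature ranking for "top-m" summaries orders by observed p-value with a
  stable sort, so ties keep table order.

## Problem sizes

The validation suite runs the full pipeline (grids of 31 depths, roughly
50 000 draws × 100 features per run) in ~2.5 s per run via the batch rank
engine; the benchmark comparisons use 5 seeds for the strong-signal and
null rows and 10 seeds for the heterogeneous design, and the acceptance
script replicates the heterogeneous design 10 times. These sizes match
the designs the statistics are defined on; nothing is scaled down.

## Limitations

- No false-discovery-rate control or adjusted p-values: AOI, AUMC and
  fragility are descriptive. Features passing selection still include
  nominal-level false positives (each null feature beats its own 97.5%
  null band with probability ≈ 2.5%), so selected counts slightly exceed
  the true signal count on average.
- Designs whose differential features are exchangeable (identical means
  and dispersion) produce degenerate fragility levels — whole blocks of
  features break at the same depth — so the fragility *ranking* carries
  little information within such a block.
- Only two-group comparisons (or one continuous outcome) are supported;
  no multi-group scenario construction, no stratified or blocked
  permutations.
- The analytic oracle covers the known-σ Z-test only; for the Wilcoxon
  statistic the U-shape is an empirical observation, not a theorem of
  this package.
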