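"""Progressive permutation: traces, U-curve summaries, fragility, selection.

The centerpiece is :class:`ProgressivePermutation`, a scikit-learn style
feature selector.  ``fit(X, y)`` progressively mixes the two-group labels
``y`` (or partially permutes a continuous outcome), re-tests every feature
at each mixing depth ``k``, and summarizes the per-feature p-value traces:

* ``nsig(k)`` — the number of features whose median p-value over draws at
  depth ``k`` is at most ``alpha``;
* AOI — ``nsig(0)/p``, the proportion of features significant in the
  observed data;
* AUMC — the trapezoidal area under the proportion curve ``nsig(k)/p``
  against the mixing proportion ``k/K``; larger values mean the signal
  survives deeper mixing;
* slopes — the initial drop of the proportion curve and the average drop
  over the first ``K_f`` segments;
* fragility — per feature, the minimum depth at which its median p-value
  turns non-significant (capped at the full-mixing depth ``K_f``), with the
  scaled version ``sFI = FI / K_f``;
* selection — a feature is kept when it is significant in the observed data
  AND its observed signal strength ``-log10 p`` exceeds the 97.5% quantile
  of its signal strength under the fully mixed null at ``K_f``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from . import assoc
from .assoc import TestSpec, batch_pvalues
from .design import (
    GroupLabels,
    ScenarioGrid,
    continuous_scenario_draws,
    full_mixing_index,
    swap_matrix,
)

__all__ = [
    "TraceSet",
    "CurveSummary",
    "FragilityTable",
    "SelectionResult",
    "ProgressivePermutation",
    "run_progressive_permutation",
    "nsig_curve",
    "aoi",
    "aumc",
    "slopes",
    "fragility",
    "select_features",
    "scaled_fragility",
]

_TINY_P = 1e-300  # floor before -log10


def _neglog10(p):
    return -np.log10(np.maximum(p, _TINY_P))


@dataclass
class TraceSet:
    """Per-feature p-value summaries across mixing depths.

    ``p_median``, ``p_q025``, ``p_q975`` are (n_depths, n_features) arrays
    aligned with ``ks``; ``p_draws`` maps each depth to its raw
    (n_draws, n_features) p-value matrix.
    """

    ks: np.ndarray
    p_median: np.ndarray
    p_q025: np.ndarray
    p_q975: np.ndarray
    alpha: float
    K: int
    K_f: int
    budgets: dict
    feature_ids: np.ndarray
    p_draws: dict | None = None
    nsig_draws: dict | None = None

    def k_index(self, k: int) -> int:
        idx = np.flatnonzero(self.ks == k)
        if idx.size == 0:
            raise ValueError(f"depth k={k} was not evaluated")
        return int(idx[0])


@dataclass
class CurveSummary:
    """U-curve of significant-feature counts and its scalar summaries."""

    ks: np.ndarray
    mixing: np.ndarray  # k / K
    nsig: np.ndarray
    nsig_q025: np.ndarray
    nsig_q975: np.ndarray
    n_features: int
    aoi: float
    aumc: float
    slope0: float
    slope_avg: float


@dataclass
class FragilityTable:
    """Per-feature fragility indices, ranked most-robust first."""

    feature_ids: np.ndarray
    fi: np.ndarray
    sfi: np.ndarray | None
    ranking: np.ndarray  # feature indices by decreasing FI
    K_f: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature": self.feature_ids, "fragility_index": self.fi})
        if self.sfi is not None:
            df["scaled_fragility"] = self.sfi
        df["rank"] = np.empty(len(df), int)
        df.loc[self.ranking, "rank"] = np.arange(1, len(df) + 1)
        return df


@dataclass
class SelectionResult:
    """Robust features: significant observed signal outside the fully mixed
    null band."""

    feature_ids: np.ndarray
    selected: np.ndarray  # boolean mask
    observed_p: np.ndarray
    observed_neglogp: np.ndarray
    null_band_low: np.ndarray  # 2.5% quantile of -log10 p at K_f
    null_band_high: np.ndarray  # 97.5% quantile of -log10 p at K_f

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_ids,
                "p_observed": self.observed_p,
                "neglog10_p_observed": self.observed_neglogp,
                "null_neglog10_q025": self.null_band_low,
                "null_neglog10_q975": self.null_band_high,
                "selected": self.selected,
            }
        )


# ---------------------------------------------------------------------------
# pure summary operations (also used directly by tests and the CLI)


def nsig_curve(traces: TraceSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """nsig(k) from median p-values, plus per-draw quantile bands."""
    nsig = (traces.p_median <= traces.alpha).sum(axis=1)
    if traces.nsig_draws is not None:
        lo = np.array([np.quantile(traces.nsig_draws[k], 0.025) for k in traces.ks])
        hi = np.array([np.quantile(traces.nsig_draws[k], 0.975) for k in traces.ks])
    else:
        lo = hi = nsig.astype(float)
    return nsig, lo, hi


def aoi(nsig0: int, n_features: int) -> float:
    """Area of interest: the proportion of significant features in the
    observed data, ``nsig(0) / p``."""
    if n_features <= 0:
        raise ValueError("n_features must be positive")
    return nsig0 / n_features


def aumc(ks, nsig, K: int, n_features: int) -> float:
    """Trapezoidal area under the proportion curve ``nsig(k)/p`` against the
    mixing proportion ``k/K``."""
    ks = np.asarray(ks, dtype=float)
    if ks.size < 2:
        raise ValueError("AUMC needs at least two grid points")
    y = np.asarray(nsig, dtype=float) / n_features
    return float(np.trapezoid(y, ks / K))


def slopes(ks, nsig, K: int, K_f: int, n_features: int) -> tuple[float, float]:
    """Initial slope and the mean segment slope over the first ``K_f``
    depths, both on the proportion curve against ``k/K``."""
    ks = np.asarray(ks, dtype=float)
    y = np.asarray(nsig, dtype=float) / n_features
    x = ks / K
    slope0 = float((y[1] - y[0]) / (x[1] - x[0]))
    head = ks <= K_f
    xs, ys = x[head], y[head]
    if xs.size < 2:
        return slope0, slope0
    seg = np.diff(ys) / np.diff(xs)
    return slope0, float(seg.mean())


def fragility(traces: TraceSet) -> FragilityTable:
    """Fragility index per feature.

    ``FI_j`` is the smallest evaluated depth ``k <= K_f`` whose median
    p-value exceeds ``alpha``; a feature that stays significant through the
    full-mixing depth is capped at ``FI = K_f``.  Features non-significant
    in the observed data get ``FI = 0``.
    """
    head = traces.ks <= traces.K_f
    ks_head = traces.ks[head]
    broken = traces.p_median[head] > traces.alpha  # (n_head, p)
    any_break = broken.any(axis=0)
    first = np.argmax(broken, axis=0)
    fi = np.where(any_break, ks_head[first], traces.K_f)
    if traces.K_f == 0:
        warnings.warn("K_f = 0: scaled fragility is undefined", RuntimeWarning)
        sfi = None
    else:
        sfi = fi / traces.K_f
    order = np.argsort(-fi, kind="stable")
    return FragilityTable(traces.feature_ids, fi, sfi, order, traces.K_f)


def scaled_fragility(fi, K_f: int):
    """``sFI = FI / K_f``, the fragility index as a fraction of the
    full-mixing depth."""
    if K_f == 0:
        raise ValueError("scaled fragility is undefined for K_f = 0")
    return np.asarray(fi, dtype=float) / K_f


def select_features(traces: TraceSet) -> SelectionResult:
    """Keep features significant in the observed data whose signal strength
    exceeds the 97.5% null quantile at the full-mixing depth."""
    if traces.p_draws is None or traces.K_f not in traces.p_draws:
        raise ValueError("selection requires the raw draws at k = K_f")
    p0 = traces.p_median[traces.k_index(0)]
    null_neglogp = _neglog10(traces.p_draws[traces.K_f])
    lo = np.quantile(null_neglogp, 0.025, axis=0)
    hi = np.quantile(null_neglogp, 0.975, axis=0)
    obs = _neglog10(p0)
    selected = (p0 <= traces.alpha) & (obs > hi)
    return SelectionResult(traces.feature_ids, selected, p0, obs, lo, hi)


# ---------------------------------------------------------------------------


class ProgressivePermutation(BaseEstimator, SelectorMixin):
    """Robust differential-feature selection by progressive label permutation.

    Parameters
    ----------
    test : str, default "wilcoxon"
        One of ``wilcoxon``, ``ztest_known_sigma``, ``custom`` (binary
        grouping) or ``spearman``, ``kendall`` (continuous outcome).
    alpha : float, default 0.05
        Significance level applied to median p-values.
    k_step : int, default 1
        Thinning of the depth grid; 0, ``K_f`` and ``K`` are always kept.
    n_draws : int or None, default None
        Override of the per-depth draw budget; None uses the logarithmic
        budget ``round(N (ln C(n1,k) + ln C(n2,k)))`` capped at the number
        of distinct arrangements.
    sigma : float or None
        Known standard deviation, required for ``ztest_known_sigma``.
    test_func : callable or None
        ``(values, labels) -> p`` hook for ``test="custom"``; any external
        p-value machinery can be plugged in this way.
    store_draws : bool, default True
        Keep the raw per-draw p-value matrices on the fitted object.
    random_state : int, default 0
        Base seed; results are bit-reproducible given the same seed.

    Attributes
    ----------
    traces_ : TraceSet
    curve_ : CurveSummary
    fragility_ : FragilityTable
    selection_ : SelectionResult
    support_ : boolean mask of selected features
    n1_, n2_, K_, K_f_ : design constants

    Examples
    --------
    >>> from permcurve.simulate import NBCopulaSpec, nb_copula_dataset
    >>> X, y = nb_copula_dataset(NBCopulaSpec(seed=1))
    >>> pp = ProgressivePermutation(random_state=1).fit(X, y)
    >>> int(pp.selection_.selected.sum()) <= int((pp.traces_.p_median[0] <= 0.05).sum())
    True
    """

    def __init__(
        self,
        test: str = "wilcoxon",
        alpha: float = 0.05,
        k_step: int = 1,
        n_draws: int | None = None,
        sigma: float | None = None,
        test_func=None,
        use_continuity: bool = True,
        store_draws: bool = True,
        random_state: int = 0,
    ):
        self.test = test
        self.alpha = alpha
        self.k_step = k_step
        self.n_draws = n_draws
        self.sigma = sigma
        self.test_func = test_func
        self.use_continuity = use_continuity
        self.store_draws = store_draws
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------

    def _make_spec(self) -> TestSpec:
        options = {}
        if self.test == "ztest_known_sigma":
            options["sigma"] = self.sigma
        if self.test == "custom":
            options["func"] = self.test_func
        if self.test == "wilcoxon":
            options["use_continuity"] = self.use_continuity
        return TestSpec(self.test, options)

    def _validate_inputs(self, X, y):
        feature_ids = None
        if isinstance(X, pd.DataFrame):
            feature_ids = np.asarray(X.columns)
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x features)")
        if np.isnan(X).any():
            raise ValueError("X contains missing values")
        if feature_ids is None:
            feature_ids = np.arange(X.shape[1])
        y = np.asarray(getattr(y, "values", y))
        if y.shape[0] != X.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} samples but y has {y.shape[0]}"
            )
        return X, y, feature_ids

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        """Run the full progressive permutation on table ``X`` and grouping
        factor (or continuous outcome) ``y``."""
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        spec = self._make_spec()
        X, y, feature_ids = self._validate_inputs(X, y)
        seed = int(self.random_state)

        if spec.is_binary:
            levels = np.unique(y)
            if levels.size != 2:
                raise ValueError(
                    f"binary tests need exactly 2 groups, got {levels.size}"
                )
            labels = GroupLabels.from_array(np.where(y == levels[0], 1, 2))
            if min(labels.n1, labels.n2) < 2:
                raise ValueError("each group needs at least 2 samples")
            self.n1_, self.n2_ = labels.n1, labels.n2
            grid = ScenarioGrid(
                labels.n1, labels.n2, seed, self.k_step, self.n_draws
            )
            self.K_, self.K_f_ = grid.K, grid.K_f
            draw_fn = lambda k, nu: swap_matrix(labels, k, nu, seed)
        else:
            outcome = y.astype(float)
            N = outcome.size
            self.n1_ = self.n2_ = None
            self.K_ = self.K_f_ = N
            ks = sorted(set(range(0, N + 1, max(1, self.k_step))) | {0, N})
            budgets = {}
            for k in ks:
                if k == 0:
                    budgets[k] = 1
                elif self.n_draws is not None:
                    budgets[k] = max(1, self.n_draws)
                else:
                    # continuous analogue of the logarithmic budget:
                    # nu = round(N * ln C(N, k)), floored at 1
                    log_choices = (
                        math.lgamma(N + 1)
                        - math.lgamma(k + 1)
                        - math.lgamma(N - k + 1)
                    )
                    budgets[k] = max(1, round(N * log_choices))
            grid = None
            draw_fn = lambda k, nu: np.stack(
                continuous_scenario_draws(outcome, k, nu, seed)
            )

        if grid is not None:
            ks = list(grid.ks)
            budgets = grid.budgets

        precomputed = (
            assoc._rank_precompute(X) if spec.name == "wilcoxon" else None
        )
        p_median, p_q025, p_q975 = [], [], []
        p_draws, nsig_draws = {}, {}
        for k in ks:
            draws = draw_fn(k, budgets[k])
            pvals = batch_pvalues(X, draws, spec, precomputed)
            p_median.append(np.median(pvals, axis=0))
            p_q025.append(np.quantile(pvals, 0.025, axis=0))
            p_q975.append(np.quantile(pvals, 0.975, axis=0))
            nsig_draws[k] = (pvals <= self.alpha).sum(axis=1)
            if self.store_draws or k == self.K_f_:
                p_draws[k] = pvals

        traces = TraceSet(
            ks=np.asarray(ks),
            p_median=np.vstack(p_median),
            p_q025=np.vstack(p_q025),
            p_q975=np.vstack(p_q975),
            alpha=self.alpha,
            K=self.K_,
            K_f=self.K_f_,
            budgets=dict(budgets),
            feature_ids=feature_ids,
            p_draws=p_draws,
            nsig_draws=nsig_draws,
        )
        self.traces_ = traces

        nsig, lo, hi = nsig_curve(traces)
        n_features = X.shape[1]
        a0 = aoi(int(nsig[traces.k_index(0)]), n_features)
        area = aumc(traces.ks, nsig, self.K_, n_features)
        s0, s_avg = slopes(traces.ks, nsig, self.K_, self.K_f_, n_features)
        self.curve_ = CurveSummary(
            ks=traces.ks,
            mixing=traces.ks / self.K_,
            nsig=nsig,
            nsig_q025=lo,
            nsig_q975=hi,
            n_features=n_features,
            aoi=a0,
            aumc=area,
            slope0=s0,
            slope_avg=s_avg,
        )
        self.fragility_ = fragility(traces)
        self.selection_ = select_features(traces)
        self.support_ = self.selection_.selected
        # selection must always be a subset of the observed significant set
        assert not np.any(
            self.support_ & (traces.p_median[traces.k_index(0)] > self.alpha)
        )
        self.n_features_in_ = n_features
        if not self.store_draws:
            traces.p_draws = None
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = False
        tags.target_tags.required = True
        return tags

    # -- reporting ----------------------------------------------------------

    def summary(self) -> dict:
        """Scalar results in a JSON-friendly dict."""
        check_is_fitted(self, "curve_")
        mean_sfi = (
            float(np.mean(self.fragility_.sfi))
            if self.fragility_.sfi is not None
            else None
        )
        return {
            "n1": self.n1_,
            "n2": self.n2_,
            "K": self.K_,
            "K_f": self.K_f_,
            "alpha": self.alpha,
            "seed": int(self.random_state),
            "k_grid": [int(k) for k in self.traces_.ks],
            "n_features": self.curve_.n_features,
            "nsig_observed": int(self.curve_.nsig[0]),
            "aoi": self.curve_.aoi,
            "aumc": self.curve_.aumc,
            "slope0": self.curve_.slope0,
            "slope_avg": self.curve_.slope_avg,
            "n_selected": int(self.support_.sum()),
            "mean_scaled_fragility": mean_sfi,
        }


def run_progressive_permutation(
    table,
    labels_or_outcome,
    spec: TestSpec | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    k_step: int = 1,
    n_draws: int | None = None,
) -> ProgressivePermutation:
    """Functional wrapper over :class:`ProgressivePermutation`.

    Returns the fitted estimator, whose ``traces_``, ``curve_``,
    ``fragility_`` and ``selection_`` attributes carry all results.
    """
    spec = spec or TestSpec()
    est = ProgressivePermutation(
        test=spec.name,
        alpha=alpha,
        k_step=k_step,
        n_draws=n_draws,
        sigma=spec.options.get("sigma"),
        test_func=spec.options.get("func"),
        use_continuity=spec.options.get("use_continuity", True),
        random_state=seed,
    )
    return est.fit(table, labels_or_outcome)
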