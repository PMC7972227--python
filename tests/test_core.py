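"""Progressive-permutation orchestration: traces, U-curve summaries,
fragility, selection and the estimator contract."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from permcurve import (
    NBCopulaSpec,
    ProgressivePermutation,
    TestSpec,
    TraceSet,
    nb_copula_dataset,
    run_progressive_permutation,
    run_tests,
    scaled_fragility,
)
from permcurve.estimator import aoi, aumc, fragility, select_features, slopes


def make_traces(p_median, ks, K, K_f, alpha=0.05, p_draws=None):
    p_median = np.asarray(p_median, dtype=float)
    return TraceSet(
        ks=np.asarray(ks),
        p_median=p_median,
        p_q025=p_median,
        p_q975=p_median,
        alpha=alpha,
        K=K,
        K_f=K_f,
        budgets={},
        feature_ids=np.arange(p_median.shape[1]),
        p_draws=p_draws,
    )


class TestTraces:
    def test_k0_median_equals_observed_pvalues(self, small_fit, small_dataset):
        X, y = small_dataset
        observed = run_tests(X, y)
        assert np.array_equal(small_fit.traces_.p_median[0], observed)

    def test_quantile_bands_bracket_median(self, small_fit):
        tr = small_fit.traces_
        assert np.all(tr.p_q025 <= tr.p_median + 1e-12)
        assert np.all(tr.p_median <= tr.p_q975 + 1e-12)
        assert np.all((tr.p_median >= 0) & (tr.p_median <= 1))

    def test_balanced_full_depth_reproduces_observed(self, small_fit):
        # for n1 = n2, the depth-K draw is the global label swap, and a
        # label-symmetric two-sided test returns the k=0 p-values
        tr = small_fit.traces_
        assert np.array_equal(tr.p_median[tr.k_index(tr.K)], tr.p_median[0])


class TestCurveSummaries:
    def test_nsig_threshold_is_inclusive(self):
        traces = make_traces(np.full((3, 4), 0.05), [0, 1, 2], K=2, K_f=1)
        nsig = (traces.p_median <= traces.alpha).sum(axis=1)
        assert np.array_equal(nsig, [4, 4, 4])

    def test_aoi_is_observed_proportion(self):
        assert aoi(30, 100) == pytest.approx(0.30)
        assert aoi(0, 100) == 0.0
        assert aoi(100, 100) == 1.0
        with pytest.raises(ValueError):
            aoi(1, 0)

    def test_aumc_of_constant_curve(self):
        assert aumc([0, 1, 2, 3, 4], [50] * 5, K=4, n_features=100) == (
            pytest.approx(0.5)
        )
        with pytest.raises(ValueError):
            aumc([0], [10], K=4, n_features=100)

    def test_slopes_flat_and_linear(self):
        s0, savg = slopes([0, 1, 2, 3, 4], [20] * 5, K=4, K_f=2, n_features=100)
        assert (s0, savg) == (0.0, 0.0)
        # linearly decreasing proportion: both slopes equal
        s0, savg = slopes(
            [0, 1, 2, 3, 4], [100, 90, 80, 70, 60], K=4, K_f=2, n_features=100
        )
        assert s0 == pytest.approx(savg) == pytest.approx(-0.4)


class TestFragility:
    def test_nonsignificant_at_k0_gets_zero(self):
        traces = make_traces([[0.5], [0.01], [0.01]], [0, 1, 2], K=2, K_f=2)
        assert fragility(traces).fi[0] == 0

    def test_unbroken_significance_capped_at_full_mixing(self):
        traces = make_traces(
            [[0.01, 0.01], [0.01, 0.2], [0.01, 0.01]], [0, 1, 2], K=2, K_f=2
        )
        table = fragility(traces)
        assert table.fi[0] == 2  # cap at K_f
        assert table.fi[1] == 1
        assert np.array_equal(table.ranking, [0, 1])
        assert table.sfi == pytest.approx([1.0, 0.5])

    def test_fragility_ignores_depths_beyond_full_mixing(self):
        # breaking only after K_f does not count
        traces = make_traces(
            [[0.01], [0.01], [0.9]], [0, 1, 2], K=2, K_f=1
        )
        assert fragility(traces).fi[0] == 1

    def test_zero_full_mixing_depth_warns(self):
        traces = make_traces([[0.01]], [0], K=0, K_f=0)
        with pytest.warns(RuntimeWarning):
            table = fragility(traces)
        assert table.sfi is None

    def test_scaled_fragility_arithmetic(self):
        assert scaled_fragility([3, 15], 15) == pytest.approx([0.2, 1.0])
        with pytest.raises(ValueError):
            scaled_fragility([1], 0)


class TestSelection:
    def test_observed_nonsignificant_never_selected(self):
        p_draws = {1: np.full((40, 2), 0.5)}
        traces = make_traces(
            [[1.0, 1e-4], [0.5, 0.5]], [0, 1], K=2, K_f=1, p_draws=p_draws
        )
        result = select_features(traces)
        assert not result.selected[0]
        assert result.selected[1]

    def test_selection_requires_full_mixing_draws(self):
        traces = make_traces([[0.01], [0.5]], [0, 1], K=2, K_f=1)
        with pytest.raises(ValueError):
            select_features(traces)

    def test_selection_subset_of_observed_significant(self, strong_fits):
        for fitted in strong_fits.values():
            p0 = fitted.traces_.p_median[0]
            assert np.all(p0[fitted.support_] <= fitted.alpha)


class TestEstimatorContract:
    def test_bit_reproducible_across_fits(self, small_dataset):
        X, y = small_dataset
        a = ProgressivePermutation(n_draws=40, random_state=3).fit(X, y)
        b = ProgressivePermutation(n_draws=40, random_state=3).fit(X, y)
        assert np.array_equal(a.traces_.p_median, b.traces_.p_median)
        assert np.array_equal(a.traces_.p_q975, b.traces_.p_q975)
        assert np.array_equal(a.fragility_.fi, b.fragility_.fi)
        assert np.array_equal(a.support_, b.support_)
        assert a.curve_.aumc == b.curve_.aumc

    def test_global_rescaling_leaves_results_identical(self, small_dataset):
        # compositional rescaling by one global constant preserves ranks,
        # hence every Wilcoxon p-value, curve and selection bit-for-bit
        X, y = small_dataset
        a = ProgressivePermutation(n_draws=40, random_state=5).fit(X, y)
        b = ProgressivePermutation(n_draws=40, random_state=5).fit(
            X / (1.1 * X.to_numpy().sum(axis=1).max()), y
        )
        assert np.array_equal(a.traces_.p_median, b.traces_.p_median)
        assert np.array_equal(a.fragility_.fi, b.fragility_.fi)
        assert np.array_equal(a.support_, b.support_)

    def test_thinned_grid_keeps_anchors(self, small_dataset):
        X, y = small_dataset
        fitted = ProgressivePermutation(
            k_step=3, n_draws=30, random_state=1
        ).fit(X, y)
        assert {0, fitted.K_f_, fitted.K_} <= set(fitted.traces_.ks.tolist())

    def test_selector_interface(self, small_fit, small_dataset):
        X, _ = small_dataset
        mask = small_fit.get_support()
        assert mask.dtype == bool and mask.size == X.shape[1]
        reduced = small_fit.transform(X)
        assert reduced.shape == (X.shape[0], mask.sum())
        assert list(small_fit.get_feature_names_out()) == list(
            np.asarray(X.columns)[mask]
        )

    def test_clone_and_params_roundtrip(self):
        est = ProgressivePermutation(alpha=0.01, k_step=2, random_state=9)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_input_validation(self):
        est = ProgressivePermutation()
        with pytest.raises(ValueError):
            est.fit(np.zeros((4, 3)), [1, 1, 1, 1])  # one group only
        with pytest.raises(ValueError):
            est.fit(np.zeros((4, 3)), [1, 1, 2, 3])  # three groups
        with pytest.raises(ValueError):
            est.fit(np.zeros((4, 3)), [1, 2, 1, 2][:3])  # length mismatch
        with pytest.raises(ValueError):
            ProgressivePermutation(alpha=1.5).fit(
                np.zeros((4, 3)), [1, 1, 2, 2]
            )
        with pytest.raises(ValueError):
            est.fit(np.full((4, 3), np.nan), [1, 1, 2, 2])

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            ProgressivePermutation().fit(np.zeros((3, 2)), [1, 2, 2])

    def test_functional_wrapper_matches_estimator(self, small_dataset):
        X, y = small_dataset
        fitted = run_progressive_permutation(
            X, y, spec=TestSpec("wilcoxon"), seed=7, n_draws=60
        )
        direct = ProgressivePermutation(n_draws=60, random_state=7).fit(X, y)
        assert np.array_equal(
            fitted.traces_.p_median, direct.traces_.p_median
        )

    def test_custom_test_plugs_in(self, small_dataset):
        X, y = small_dataset
        fitted = ProgressivePermutation(
            test="custom",
            test_func=lambda v, labels: 1.0,
            n_draws=5,
            random_state=0,
        ).fit(X, y)
        assert fitted.curve_.nsig.sum() == 0
        assert fitted.support_.sum() == 0

    def test_summary_is_json_friendly(self, small_fit):
        import json

        s = small_fit.summary()
        json.dumps(s)
        assert s["K_f"] == small_fit.K_f_
        assert s["n_features"] == 20


class TestContinuousOutcomeMode:
    def test_grid_runs_to_full_permutation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 6))
        y = X[:, 0] * 2 + rng.normal(size=12) * 0.3
        fitted = ProgressivePermutation(
            test="spearman", n_draws=40, random_state=2
        ).fit(X, y)
        assert fitted.K_ == fitted.K_f_ == 12
        assert fitted.traces_.ks[0] == 0 and fitted.traces_.ks[-1] == 12
        # the strongly correlated feature is significant at k=0
        assert fitted.traces_.p_median[0, 0] < 0.05
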