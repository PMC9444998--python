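"""Clock construction: stratified folds, metrics, CV grid search, fitting."""

import numpy as np
import pandas as pd
import pytest

import cogclock as cc
from cogclock.clock import DEFAULT_AGE_BINS, results_to_frame
from cogclock.errors import ConfigError, DataError

from conftest import strong_signal_config


class TestStratifiedFolds:
    def test_divisible_cohort_equal_folds(self):
        ages = np.random.default_rng(0).uniform(19, 85, 35)
        folds = cc.stratified_folds(ages, n_folds=5)
        assert np.bincount(folds, minlength=5).tolist() == [7] * 5

    def test_uniform_bins_exact_stratification(self):
        # 10 participants in each of the 7 bins -> exactly 2 per bin per fold
        edges = np.asarray(DEFAULT_AGE_BINS)
        centers = (edges[:-1] + edges[1:]) / 2
        ages = np.repeat(centers, 10)
        folds = cc.stratified_folds(ages, n_folds=5, seed=4)
        for c in centers:
            per_fold = np.bincount(folds[ages == c], minlength=5)
            assert per_fold.tolist() == [2] * 5

    @pytest.mark.parametrize("seed", range(5))
    def test_per_bin_counts_differ_by_at_most_one(self, seed):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(15, 88, 118)
        folds = cc.stratified_folds(ages, n_folds=5, seed=seed)
        edges = np.asarray(DEFAULT_AGE_BINS)
        bins = np.clip(np.digitize(ages, edges[1:-1]), 0, 6)
        sizes = np.bincount(folds, minlength=5)
        assert sizes.max() - sizes.min() <= 1
        for b in range(7):
            counts = np.bincount(folds[bins == b], minlength=5)
            assert counts.max() - counts.min() <= 1

    def test_deterministic_given_seed(self):
        ages = np.random.default_rng(1).uniform(19, 85, 50)
        a = cc.stratified_folds(ages, seed=9)
        b = cc.stratified_folds(ages, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_too_few_participants_raises(self):
        with pytest.raises(DataError):
            cc.stratified_folds([30.0, 40.0], n_folds=5)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([20, 40, 60, 80.0])
        assert cc.evaluate_metrics(y, y) == pytest.approx((1.0, 0.0, 0.0))

    def test_ev_shift_invariance(self):
        y = np.array([20, 40, 60, 80.0])
        ev, mae, medae = cc.evaluate_metrics(y, y + 10)
        assert (ev, mae, medae) == pytest.approx((1.0, 10.0, 10.0))

    def test_hand_arithmetic_oracle(self):
        ev, mae, medae = cc.evaluate_metrics([20, 40, 60, 80], [25, 35, 65, 75])
        # errors [-5,5,-5,5]: Var(err)=25, Var(y)=500 -> EV = 1 - 25/500
        assert ev == pytest.approx(0.95)
        assert mae == pytest.approx(5.0)
        assert medae == pytest.approx(5.0)

    def test_constant_truth_gives_nan_ev(self):
        ev, _, _ = cc.evaluate_metrics([50, 50, 50], [48, 51, 50])
        assert np.isnan(ev)

    def test_matches_sklearn(self):
        from sklearn.metrics import (explained_variance_score, mean_absolute_error,
                                     median_absolute_error)
        rng = np.random.default_rng(3)
        y = rng.uniform(20, 80, 100)
        pred = y + rng.normal(0, 8, 100)
        ev, mae, medae = cc.evaluate_metrics(y, pred)
        assert ev == pytest.approx(explained_variance_score(y, pred), rel=1e-12)
        assert mae == pytest.approx(mean_absolute_error(y, pred), rel=1e-12)
        assert medae == pytest.approx(median_absolute_error(y, pred), rel=1e-12)


@pytest.fixture(scope="module")
def linear_cohort_data():
    cohort = cc.generate_cohort(strong_signal_config(n=300, seed=5))
    mapping = cc.default_mapping(cohort.config.index_specs)
    matrix = cc.build_quantifier_matrix(cohort, mapping)
    sel = cc.select_quantifiers(matrix, cohort.ages)
    ranked = cc.ranked_quantifier_names(sel)
    return cohort, matrix, ranked


class TestCrossValidate:
    def test_strong_linear_signal_high_ev(self, linear_cohort_data):
        cohort, matrix, ranked = linear_cohort_data
        spec = cc.ClockSpec(model_families=("linear",), top_k_range=(10,), seed=1)
        (res,) = cc.cross_validate(spec, matrix, ranked, cohort.ages)
        assert res.mean_ev >= 0.9

    def test_permuted_ages_no_signal(self, linear_cohort_data):
        cohort, matrix, ranked = linear_cohort_data
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(cohort.ages)
        spec = cc.ClockSpec(model_families=("linear", "knn"),
                            grids={"knn": {"n_neighbors": [5]}},
                            top_k_range=(10,), seed=1)
        for res in cc.cross_validate(spec, matrix, ranked, shuffled):
            assert res.mean_ev <= 0.05

    def test_one_nn_memorizes_training_rows(self, linear_cohort_data):
        cohort, matrix, ranked = linear_cohort_data
        winner = cc.ClockCVResult(family="knn", params={"n_neighbors": 1},
                                  top_k=10, fold_ev=np.ones(5),
                                  fold_mae=np.zeros(5), fold_medae=np.zeros(5))
        clock = cc.fit_final(winner, matrix, ranked, cohort.ages)
        pred = clock.predict(matrix)
        _, mae, _ = cc.evaluate_metrics(cohort.ages, pred.to_numpy())
        assert mae == pytest.approx(0.0, abs=1e-9)

    def test_oversized_top_k_skipped(self, linear_cohort_data):
        cohort, matrix, ranked = linear_cohort_data
        spec = cc.ClockSpec(model_families=("linear",),
                            top_k_range=(5, 10_000), seed=1)
        results = cc.cross_validate(spec, matrix, ranked, cohort.ages)
        assert [r.top_k for r in results] == [5]

    def test_strict_mode_not_more_optimistic_on_noise(self):
        # deliberate leakage diff: per-fold ranking must not outperform
        # full-data ranking on pure-noise quantifiers, on average
        deltas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            matrix = pd.DataFrame(rng.normal(size=(80, 30)),
                                  columns=[f"q{i}" for i in range(30)])
            age = rng.uniform(19, 85, 80)
            sel = cc.select_quantifiers(matrix, age)
            ranked = cc.ranked_quantifier_names(sel, restrict_to_significant=False)
            out = {}
            for mode in ("paper", "strict"):
                spec = cc.ClockSpec(model_families=("linear",), top_k_range=(5,),
                                    ranking_mode=mode, seed=seed)
                (res,) = cc.cross_validate(spec, matrix, ranked, age)
                out[mode] = res.mean_ev
            deltas.append(out["strict"] - out["paper"])
        assert np.mean(deltas) <= 0


class TestSelectOptimal:
    def _result(self, ev, top_k, family="linear", params=None):
        return cc.ClockCVResult(family=family, params=params or {}, top_k=top_k,
                                fold_ev=np.full(5, ev), fold_mae=np.full(5, 10.0),
                                fold_medae=np.full(5, 8.0))

    def test_single_candidate(self):
        r = self._result(0.5, 10)
        assert cc.select_optimal([r]) is r

    def test_higher_ev_wins(self):
        a, b = self._result(0.50, 10), self._result(0.52, 20)
        assert cc.select_optimal([a, b]) is b

    def test_tie_breaks_to_smaller_top_k(self):
        a, b = self._result(0.5, 24), self._result(0.5, 10)
        assert cc.select_optimal([a, b]) is b

    def test_mae_objective(self):
        a = self._result(0.5, 10)
        b = cc.ClockCVResult(family="knn", params={}, top_k=10,
                             fold_ev=np.full(5, 0.4), fold_mae=np.full(5, 8.0),
                             fold_medae=np.full(5, 6.0))
        assert cc.select_optimal([a, b], objective="mean_MAE") is b

    def test_pure_function(self, linear_cohort_data):
        cohort, matrix, ranked = linear_cohort_data
        spec = cc.ClockSpec(model_families=("linear", "knn"),
                            grids={"knn": {"n_neighbors": [3, 5]}},
                            top_k_range=(5, 10), seed=2)
        results = cc.cross_validate(spec, matrix, ranked, cohort.ages)
        first = cc.select_optimal(results)
        again = cc.select_optimal(list(results))
        assert (first.family, first.params, first.top_k) == \
            (again.family, again.params, again.top_k)

    def test_empty_raises(self):
        with pytest.raises(DataError):
            cc.select_optimal([])


class TestFittedClock:
    def test_serialization_round_trip(self, linear_cohort_data, tmp_path):
        cohort, matrix, ranked = linear_cohort_data
        winner = cc.ClockCVResult(family="svr_rbf", params={"C": 10.0},
                                  top_k=8, fold_ev=np.ones(5),
                                  fold_mae=np.zeros(5), fold_medae=np.zeros(5))
        clock = cc.fit_final(winner, matrix, ranked, cohort.ages)
        path = tmp_path / "clock.pkl"
        clock.save(path)
        reloaded = cc.FittedClock.load(path)
        pd.testing.assert_series_equal(reloaded.predict(matrix), clock.predict(matrix))

    def test_batch_equals_row_by_row(self, linear_cohort_data):
        cohort, matrix, ranked = linear_cohort_data
        winner = cc.ClockCVResult(family="linear", params={}, top_k=8,
                                  fold_ev=np.ones(5), fold_mae=np.zeros(5),
                                  fold_medae=np.zeros(5))
        clock = cc.fit_final(winner, matrix, ranked, cohort.ages)
        batch = clock.predict(matrix.head(10))
        rows = pd.concat([clock.predict(matrix.iloc[[i]]) for i in range(10)])
        pd.testing.assert_series_equal(batch, rows)

    def test_na_rows_predict_na(self, linear_cohort_data):
        cohort, matrix, ranked = linear_cohort_data
        winner = cc.ClockCVResult(family="linear", params={}, top_k=5,
                                  fold_ev=np.ones(5), fold_mae=np.zeros(5),
                                  fold_medae=np.zeros(5))
        clock = cc.fit_final(winner, matrix, ranked, cohort.ages)
        broken = matrix.head(5).copy()
        broken.iloc[0, broken.columns.get_loc(clock.columns[0])] = np.nan
        pred = clock.predict(broken)
        assert np.isnan(pred.iloc[0]) and np.isfinite(pred.iloc[1:]).all()

    def test_missing_column_names_it(self, linear_cohort_data):
        cohort, matrix, ranked = linear_cohort_data
        winner = cc.ClockCVResult(family="linear", params={}, top_k=5,
                                  fold_ev=np.ones(5), fold_mae=np.zeros(5),
                                  fold_medae=np.zeros(5))
        clock = cc.fit_final(winner, matrix, ranked, cohort.ages)
        with pytest.raises(DataError, match=clock.columns[0].split()[0]):
            clock.predict(matrix.drop(columns=[clock.columns[0]]))


def test_results_frame_has_aggregates(linear_cohort_data):
    cohort, matrix, ranked = linear_cohort_data
    spec = cc.ClockSpec(model_families=("linear",), top_k_range=(5, 10), seed=0)
    frame = results_to_frame(cc.cross_validate(spec, matrix, ranked, cohort.ages))
    assert {"family", "top_k", "mean_ev", "sd_ev", "mean_mae"} <= set(frame.columns)
    assert len(frame) == 2


def test_unknown_family_rejected():
    with pytest.raises(ConfigError, match="deep_net"):
        cc.ClockSpec(model_families=("deep_net",)).validate()
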