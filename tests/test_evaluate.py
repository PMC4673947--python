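"""Metrics, stratified splits, CV component selection, window protocol."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ftirdose.errors import DataError, DegeneracyError, DesignError
from ftirdose.evaluate import (
    cv_lv_curve,
    evaluate_bis,
    evaluate_windows,
    r_squared,
    records_to_frame,
    rmse,
    stratified_split,
    summarize_windows,
)

vectors = st.lists(st.floats(min_value=-100, max_value=100, allow_nan=False),
                   min_size=2, max_size=12)


class TestMetrics:
    def test_rmse_closed_forms(self):
        assert rmse([0, 2], [1, 1]) == 1.0
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0

    @given(vectors, st.integers(0, 10 ** 6))
    def test_rmse_matches_direct_formula(self, obs, seed):
        rng = np.random.default_rng(seed)
        pred = rng.normal(size=len(obs))
        direct = np.sqrt(sum((o - p) ** 2 for o, p in zip(obs, pred)) / len(obs))
        assert rmse(obs, pred) == pytest.approx(direct, rel=1e-12)

    def test_r_squared_closed_forms(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full(3, y.mean())) == 0.0
        assert r_squared(y, [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_r_squared_negative_for_bad_predictor(self):
        assert r_squared([1.0, 2.0, 3.0], [10.0, -4.0, 7.0]) < 0

    def test_pearson_variant_available(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        p = 2.0 * y + 1.0  # affine transform: pearson^2 is 1, ss form is not
        assert r_squared(y, p, kind="pearson") == pytest.approx(1.0)
        assert r_squared(y, p) < 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            rmse([], [])
        with pytest.raises(DegeneracyError):
            r_squared([1.0, 1.0], [1.0, 2.0])


class TestSplits:
    def test_default_split_is_40_16(self, default_bis):
        split = stratified_split(default_bis, seed=0)
        assert split.train_indices.size == 40
        assert split.test_indices.size == 16

    def test_partition_is_disjoint_and_exhaustive(self, default_bis):
        split = stratified_split(default_bis, seed=5)
        combined = np.concatenate([split.train_indices, split.test_indices])
        assert np.array_equal(np.sort(combined), np.arange(56))

    def test_each_dose_in_both_halves(self, default_bis):
        split = stratified_split(default_bis, seed=2)
        train_doses = set(default_bis.y[split.train_indices])
        test_doses = set(default_bis.y[split.test_indices])
        assert train_doses == test_doses == set(np.unique(default_bis.y))

    def test_seed_determinism(self, default_bis):
        a = stratified_split(default_bis, seed=9)
        b = stratified_split(default_bis, seed=9)
        assert np.array_equal(a.train_indices, b.train_indices)

    def test_short_dose_group_rejected(self, default_bis):
        with pytest.raises(DesignError):
            stratified_split(default_bis, train_per_dose=6, test_per_dose=2)

    def test_unstratified_split_keeps_sizes(self, default_bis):
        split = stratified_split(default_bis, seed=1, stratify=False)
        assert split.train_indices.size == 40 and split.test_indices.size == 16


class TestCV:
    def test_curve_length_and_argmin_selection(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        cv = cv_lv_curve(X, y, max_lv=6, seed=0)
        assert cv.mse_by_lv.size == 6
        assert cv.selected_lv == int(np.argmin(cv.mse_by_lv)) + 1
        assert cv.mse_by_lv[cv.selected_lv - 1] <= cv.mse_by_lv.min() + 1e-15

    def test_low_rank_structure_recovered_with_few_components(self):
        # y depends on two orthogonal X directions; CV should not need more
        rng = np.random.default_rng(6)
        n = 42
        basis = np.linalg.qr(rng.normal(size=(12, 12)))[0]
        scores = rng.normal(size=(n, 2))
        X = scores @ basis[:, :2].T + 1e-6 * rng.normal(size=(n, 12))
        y = scores @ np.array([1.5, -2.0])
        cv = cv_lv_curve(X, y, max_lv=8, seed=0)
        assert cv.selected_lv <= 3

    def test_max_lv_beyond_capacity_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        y = np.arange(10.0)
        with pytest.raises(DesignError):
            cv_lv_curve(X, y, max_lv=9, k_folds=5)

    def test_fold_stratification_balances_labels(self):
        rng = np.random.default_rng(8)
        labels = np.repeat(np.arange(8.0), 5)
        X = rng.normal(size=(40, 10))
        y = labels + rng.normal(0, 0.1, size=40)
        cv = cv_lv_curve(X, y, max_lv=4, k_folds=5, seed=1, stratify_labels=labels)
        assert cv.mse_by_lv.size == 4


@pytest.fixture(scope="module")
def records(preprocessed_design):
    return evaluate_windows(preprocessed_design,
                            windows=[(1000, 3000), (2000, 2500)],
                            n_models=4, max_lv=8, seed=21)


class TestWindowProtocol:
    def test_record_count_is_models_times_windows(self, records):
        assert len(records) == 8
        frame = records_to_frame(records)
        assert frame.groupby(["window_lo", "window_hi"]).size().eq(4).all()

    def test_informative_window_beats_silent_window(self, records):
        summary = summarize_windows(records).set_index("window_lo")
        assert summary.loc[1000, "r2_test_mean"] > summary.loc[2000, "r2_test_mean"]

    def test_duplicate_seed_reproduces_records(self, preprocessed_design, records):
        again = evaluate_windows(preprocessed_design,
                                 windows=[(1000, 3000), (2000, 2500)],
                                 n_models=4, max_lv=8, seed=21)
        for a, b in zip(records, again):
            assert a == b

    def test_test_rows_never_seen_in_training(self, default_bis):
        # leakage guard: the split feeding CV + fit excludes every test row
        from ftirdose.evaluate import stratified_split

        for seed in range(5):
            split = stratified_split(default_bis, seed=seed)
            assert np.intersect1d(split.train_indices, split.test_indices).size == 0

    def test_label_permutation_destroys_generalization(self, preprocessed_design):
        real = evaluate_windows(preprocessed_design, windows=[(1000, 3000)],
                                n_models=4, max_lv=8, seed=33)
        fake = evaluate_windows(preprocessed_design, windows=[(1000, 3000)],
                                n_models=4, max_lv=8, seed=33, permute_labels=True)
        r2_real = np.mean([r.r2_test for r in real])
        r2_fake = np.mean([r.r2_test for r in fake])
        assert r2_real > 0.9
        assert r2_fake < 0.2


class TestEvaluateBis:
    def test_records_carry_window_and_model_ids(self, default_bis):
        recs = evaluate_bis(default_bis, n_models=3, max_lv=5, seed=2,
                            window=(1000, 3000))
        assert [r.model_id for r in recs] == [1, 2, 3]
        assert all(r.window == (1000, 3000) for r in recs)
        assert all(np.isfinite(r.r2_test) for r in recs)
        assert all(r.rmse_train >= 0 and r.rmse_test >= 0 for r in recs)
        assert all(r.r2_train <= 1 and r.r2_test <= 1 for r in recs)
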