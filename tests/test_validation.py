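"""The validation battery: internal/external statistics, descriptor
diagnostics, Y-randomization, and the leverage applicability domain."""
import numpy as np
import pandas as pd
import pytest

from qsarforge.dataio import DescriptorTable, QsarDataset
from qsarforge.linear_model import LinearModel, fit_ols, predict
from qsarforge.synthetic import SyntheticSpec, generate_dataset
from qsarforge.validation import (
    adjusted_r2,
    build_report,
    leverages,
    mean_effects,
    pearson_r,
    q2_loo,
    r2_pred,
    r_squared,
    vif_all,
    warning_leverage,
    williams_data,
    y_randomization,
)


class TestRSquared:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y, y.mean()) == 1.0

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, y.mean()), y.mean()) == pytest.approx(0.0)

    def test_published_training_value(self, table4):
        train = table4.subset("train")
        pred = train.table.data["pIC50_pred"].to_numpy()
        r2 = r_squared(train.y, pred, float(train.y.mean()))
        assert r2 == pytest.approx(0.9929, abs=5e-5)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(3), np.zeros(3), 1.0)


class TestAdjustedR2:
    def test_perfect_fit_stays_one(self):
        assert adjusted_r2(1.0, 16, 4) == 1.0

    def test_published_value(self):
        assert adjusted_r2(0.992869, 16, 4) == pytest.approx(0.990276, abs=5e-7)

    def test_hand_arithmetic(self):
        assert adjusted_r2(0.5, 12, 1) == pytest.approx(0.45)

    def test_never_exceeds_r2(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            r2 = rng.uniform(0, 1)
            assert adjusted_r2(r2, 20, 3) <= r2

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.9, 5, 4)


class TestQ2Loo:
    def test_noiseless_linear_is_one(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((15, 2))
        y = 1.0 + X @ np.array([2.0, -1.0])
        assert q2_loo(X, y) == pytest.approx(1.0, abs=1e-10)

    def test_hat_matrix_shortcut_equals_explicit_refits(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 3))
        y = rng.standard_normal(12)
        # explicit leave-one-out refits as the oracle
        press = 0.0
        for i in range(12):
            mask = np.arange(12) != i
            m = fit_ols(X[mask], y[mask])
            press += (y[i] - predict(m, X[i : i + 1])[0]) ** 2
        expected = 1.0 - press / ((y - y.mean()) ** 2).sum()
        assert q2_loo(X, y) == pytest.approx(expected, abs=1e-10)

    def test_pure_noise_gives_nonpositive_q2_in_expectation(self):
        rng = np.random.default_rng(3)
        values = []
        for _ in range(100):
            X = rng.standard_normal((20, 2))
            y = rng.standard_normal(20)
            values.append(q2_loo(X, y))
        assert np.mean(values) <= 0

    def test_q2_never_exceeds_r2(self):
        """PRESS >= RSS, so LOO Q2 <= training R2, on random instances."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(10, 30))
            p = int(rng.integers(1, 4))
            X = rng.standard_normal((n, p))
            y = X @ rng.standard_normal(p) + rng.normal(0, 0.5, n)
            m = fit_ols(X, y)
            assert q2_loo(X, y) <= m.r2 + 1e-12


class TestR2Pred:
    def test_published_worked_example(self, table5, table4):
        ref = float(table4.y.mean())  # 4.3699: the all-compound convention
        pred = table5.table.data["pIC50_pred"].to_numpy()
        assert r2_pred(table5.y, pred, ref) == pytest.approx(0.7560, abs=1e-4)
        num = ((pred - table5.y) ** 2).sum()
        assert num == pytest.approx(0.1368, abs=5e-5)

    def test_training_only_convention_differs(self, table5, table4):
        train_mean = float(table4.subset("train").y.mean())
        assert train_mean == pytest.approx(4.4348, abs=5e-5)
        pred = table5.table.data["pIC50_pred"].to_numpy()
        assert r2_pred(table5.y, pred, train_mean) != pytest.approx(0.7560, abs=1e-3)

    def test_perfect_prediction(self):
        y = np.array([4.0, 4.5])
        assert r2_pred(y, y, 4.2) == 1.0


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(5.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)

    def test_published_test_set_squared_correlation(self, table5):
        pred = table5.table.data["pIC50_pred"].to_numpy()
        assert pearson_r(table5.y, pred) ** 2 == pytest.approx(0.8397, abs=2e-4)

    def test_published_all_compound_correlation(self, table10):
        pred = table10.table.data["qsar_pred"].to_numpy()
        assert pearson_r(table10.y, pred) == pytest.approx(0.9831, abs=5e-5)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestVif:
    def test_orthogonal_descriptors_give_unit_vif(self):
        X = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        np.testing.assert_allclose(vif_all(X).to_numpy(), [1.0, 1.0])

    def test_duplicated_descriptor_infinite(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(10)
        X = np.column_stack([x, x])
        assert np.isinf(vif_all(X)).all()

    def test_closed_form_two_predictor_case(self):
        rng = np.random.default_rng(6)
        n = 100_000
        a = rng.standard_normal(n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        X = np.column_stack([a, b, rng.standard_normal(n)])
        vifs = vif_all(X)
        assert vifs.iloc[0] == pytest.approx(1 / (1 - 0.64), abs=2e-2)


class TestMeanEffects:
    def _model(self, coeffs, names):
        return LinearModel(names, np.asarray(coeffs, float), 0.0)

    def test_single_descriptor_is_one(self):
        me = mean_effects(self._model([2.5], ["a"]), np.ones((5, 1)))
        assert me.iloc[0] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        X = np.array([[1.0, 0.5], [2.0, 0.5]])  # column sums (3, 1)
        me = mean_effects(self._model([1.0, 1.0], ["a", "b"]), X)
        np.testing.assert_allclose(me.to_numpy(), [0.75, 0.25])

    def test_sums_to_one_on_random_models(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = int(rng.integers(1, 6))
            X = rng.standard_normal((10, p)) + 1.0
            me = mean_effects(
                self._model(rng.standard_normal(p), [f"d{j}" for j in range(p)]), X
            )
            assert me.sum() == pytest.approx(1.0, abs=1e-6)


class TestLeverages:
    def test_mean_point_has_leverage_one_over_n(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((10, 3))
        X[0] = X[1:].mean(axis=0)  # place row 0 at the mean of the rest
        X[0] = X.mean(axis=0)  # iterate once: exact mean of all rows
        h = leverages(X, X[0:1])
        assert h[0] >= 1 / 10 - 1e-9

    def test_training_leverages_sum_to_p_plus_1(self):
        rng = np.random.default_rng(9)
        for p in (1, 2, 4):
            X = rng.standard_normal((15, p))
            h = leverages(X)
            assert h.sum() == pytest.approx(p + 1, abs=1e-6)
            assert np.all(h >= 1 / 15 - 1e-12)

    def test_far_query_point_matches_matrix_oracle(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((12, 2))
        q = np.array([[50.0, -50.0]])
        h = leverages(X, q)
        A = np.column_stack([np.ones(12), X])
        aq = np.array([1.0, 50.0, -50.0])
        expected = aq @ np.linalg.inv(A.T @ A) @ aq
        assert h[0] == pytest.approx(expected, rel=1e-10)
        assert h[0] > 1.0


class TestWarningLeverage:
    def test_published_model_dimensions(self):
        assert warning_leverage(p=4, n=16) == 0.9375

    def test_intercept_only(self):
        assert warning_leverage(p=0, n=3) == 1.0

    def test_inverse_proportionality_in_n(self):
        assert warning_leverage(3, 40) == pytest.approx(warning_leverage(3, 20) / 2)


class TestWilliams:
    def _fitted_dataset(self, seed=11, noise=0.05):
        ds, truth = generate_dataset(
            SyntheticSpec(n_compounds=24, n_descriptors=4, n_informative=2, noise_sd=noise, seed=seed)
        )
        part = pd.Series(
            ["train"] * 18 + ["test"] * 6, index=ds.table.data.index
        )
        ds = ds.with_partition(part)
        train = ds.subset("train")
        model = fit_ols(train.table, train.y)
        return model, ds

    def test_noiseless_fit_has_zero_standardized_residuals(self):
        model, ds = self._fitted_dataset(noise=0.0)
        for r in williams_data(model, ds):
            assert r.standardized_residual == pytest.approx(0.0, abs=1e-6)

    def test_flags_match_compositional_recomputation(self):
        from qsarforge.linear_model import see as see_stat

        model, ds = self._fitted_dataset()
        results = williams_data(model, ds)
        train = ds.subset("train")
        X_train = train.table.select(list(model.descriptor_names)).values
        h_star = warning_leverage(X_train.shape[1], X_train.shape[0])
        see_value = see_stat(
            train.y - predict(model, X_train), *X_train.shape
        )
        X_all = ds.table.select(list(model.descriptor_names)).values
        h_all = leverages(X_train, X_all)
        resid = ds.y - predict(model, X_all)
        for r, h, e in zip(results, h_all, resid):
            assert r.leverage == pytest.approx(h)
            assert r.standardized_residual == pytest.approx(e / see_value)
            assert r.in_domain == (h <= h_star and abs(e / see_value) <= 3)

    def test_high_leverage_compound_flagged_influential(self):
        model, ds = self._fitted_dataset()
        # push one test compound far outside the training descriptor range
        ds.table.data.iloc[-1] = 100.0
        results = williams_data(model, ds)
        h_star = warning_leverage(4, 18)
        assert results[-1].leverage > h_star
        assert not results[-1].in_domain


class TestYRandomization:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((20, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(0, 0.1, 20)
        a = y_randomization(X, y, 50, seed=5)
        b = y_randomization(X, y, 50, seed=5)
        assert a == b

    def test_strong_signal_passes_threshold(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((24, 3))
        y = X @ np.array([1.5, -1.0, 2.0]) + rng.normal(0, 0.3, 24)
        _, crp2 = y_randomization(X, y, 100, seed=1)
        assert crp2 > 0.5

    def test_pure_noise_gives_small_crp2(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        mean_r2_r, crp2 = y_randomization(X, y, 100, seed=2)
        base_r2 = fit_ols(X, y).r2
        assert abs(mean_r2_r - base_r2) < 0.15  # exchangeable under the null
        assert crp2 < 0.5

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            y_randomization(np.eye(5), np.arange(5.0), 5)


class TestBuildReport:
    def _partitioned(self, noise_sd, seed=15):
        ds, truth = generate_dataset(
            SyntheticSpec(n_compounds=30, n_descriptors=6, n_informative=3, noise_sd=noise_sd, seed=seed)
        )
        part = pd.Series(["train"] * 22 + ["test"] * 8, index=ds.table.data.index)
        return ds.with_partition(part), truth

    def test_clean_synthetic_passes_all_criteria(self):
        ds, truth = self._partitioned(noise_sd=0.02)
        train = ds.subset("train")
        model = fit_ols(train.table.select(truth.support), train.y)
        report = build_report(model, ds, seed=0)
        assert report.all_pass, report.checklist

    def test_shuffled_activity_fails_r2_criterion(self):
        ds, truth = self._partitioned(noise_sd=0.02)
        rng = np.random.default_rng(0)
        ds.activity[:] = rng.permutation(ds.y)
        train = ds.subset("train")
        model = fit_ols(train.table.select(truth.support), train.y)
        report = build_report(model, ds, seed=0)
        assert not report.checklist["r2"]

    def test_report_records_reference_mean_convention(self):
        ds, truth = self._partitioned(noise_sd=0.02)
        train = ds.subset("train")
        model = fit_ols(train.table.select(truth.support), train.y)
        r_all = build_report(model, ds, "all_compounds", seed=0)
        r_train = build_report(model, ds, "training_only", seed=0)
        assert r_all.reference_mean_convention == "all_compounds"
        assert r_all.reference_mean == pytest.approx(float(ds.y.mean()))
        assert r_train.reference_mean == pytest.approx(float(train.y.mean()))

    def test_adjusted_r2_below_r2(self):
        ds, truth = self._partitioned(noise_sd=0.1)
        train = ds.subset("train")
        model = fit_ols(train.table.select(truth.support), train.y)
        report = build_report(model, ds, seed=0)
        assert report.r2_adjusted <= report.r2
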