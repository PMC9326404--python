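"""Concentration-gradient splitting, PLSR fitting, metrics, fusion harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import leafspec as ls
from leafspec._pls import pls1_coefficients
from leafspec.modeling import ModelError, fit_and_evaluate


class TestConcentrationGradientSplit:
    def test_sixty_samples_split_forty_twenty(self):
        rng = np.random.default_rng(0)
        k = rng.uniform(0.4, 2.3, 60)
        s = ls.concentration_gradient_split(k)
        assert len(s.calibration_ids) == 40
        assert len(s.validation_ids) == 20

    def test_block_rule_hand_example(self):
        s = ls.concentration_gradient_split([1, 2, 3, 4, 5, 6],
                                            ["a", "b", "c", "d", "e", "f"])
        assert set(s.validation_ids) == {"b", "e"}

    @given(st.lists(st.floats(0.3, 3.6), min_size=5, max_size=80,
                    unique=True))
    @settings(max_examples=60, deadline=None)
    def test_extremes_in_calibration_and_partition(self, k):
        k = np.asarray(k)
        s = ls.concentration_gradient_split(k)
        cal, val = set(s.calibration_ids), set(s.validation_ids)
        assert cal | val == set(range(k.size)) and not cal & val
        assert int(np.argmin(k)) in cal and int(np.argmax(k)) in cal
        if val:
            assert min(k[list(cal)]) <= min(k[list(val)])
            assert max(k[list(val)]) <= max(k[list(cal)])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            ls.concentration_gradient_split([1, 2, 3], ["a", "a", "b"])


class TestEvaluateMetrics:
    def test_perfect_and_mean_predictors(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ls.evaluate_metrics(y, y) == (1.0, 0.0)
        r2, _ = ls.evaluate_metrics(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_computed_example(self):
        r2, rmse = ls.evaluate_metrics(np.array([1.0, 2, 3]),
                                       np.array([1.0, 2, 4]))
        assert r2 == pytest.approx(0.5)
        assert rmse == pytest.approx(np.sqrt(1 / 3))

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_literal_formula_loop(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=12)
        yhat = rng.normal(size=12)
        r2, rmse = ls.evaluate_metrics(y, yhat)
        sse = sum((yi - yh) ** 2 for yi, yh in zip(y, yhat))
        sst = sum((yi - y.mean()) ** 2 for yi in y)
        assert r2 == pytest.approx(1 - sse / sst, abs=1e-12)
        assert rmse == pytest.approx(np.sqrt(sse / 12), abs=1e-12)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ModelError):
            ls.evaluate_metrics(np.ones(5), np.zeros(5))


class TestFitPlsr:
    def test_exact_recovery_of_noiseless_linear_model(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        beta = np.array([1.0, -2.0, 0.5, 3.0, 0.0])
        y = X @ beta + 1.7
        model = ls.fit_plsr(X, y, seed=0)
        r2, rmse = ls.evaluate_metrics(y, model.predict(X))
        assert r2 == pytest.approx(1.0, abs=1e-8)

    def test_single_column_equals_simple_least_squares(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        y = 2.0 * x + rng.normal(0, 0.3, 25)
        model = ls.fit_plsr(x[:, None], y, seed=0)
        slope = np.cov(x, y, bias=True)[0, 1] / x.var()
        intercept = y.mean() - slope * x.mean()
        assert np.allclose(model.predict(x[:, None]),
                           slope * x + intercept, atol=1e-8)

    def test_permuted_response_has_no_validation_skill(self):
        rng = np.random.default_rng(3)
        r2_vals = []
        for seed in range(5):
            X = rng.normal(size=(60, 20))
            y = rng.permutation(np.linspace(0.5, 2.5, 60))
            split = ls.concentration_gradient_split(y)
            cal = np.array(split.calibration_ids)
            val = np.array(split.validation_ids)
            res = fit_and_evaluate(X[cal], y[cal], X[val], y[val],
                                   "null", seed=seed)
            r2_vals.append(res.r2_val)
        assert max(r2_vals) < 0.3
        assert abs(np.mean(r2_vals)) < 0.5

    def test_agrees_with_independent_nipals_core(self):
        """sklearn-backed fit vs the in-house NIPALS core, fixed rank."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.1, 40)
        model = ls.fit_plsr(X, y, max_lv=8, seed=0)
        coef, icpt = pls1_coefficients(X, y, model.n_latent)
        assert np.allclose(model.coefficients, coef, atol=1e-8)
        assert model.intercept == pytest.approx(icpt, abs=1e-8)

    def test_empty_feature_matrix_rejected(self):
        with pytest.raises(ModelError):
            ls.fit_plsr(np.empty((10, 0)), np.arange(10.0), seed=0)


def _toy_tables(seed=0, n=30):
    rng = np.random.default_rng(seed)
    ids = [f"s{i:02d}" for i in range(n)]
    k = pd.Series(rng.uniform(0.4, 2.3, n), index=ids)
    tables = {}
    for selector in ("CARS", "RF"):
        for label in ["R"] + [f"CWT-{i}" for i in range(1, 11)]:
            X = k.to_numpy()[:, None] + rng.normal(0, 0.3, size=(n, 3))
            tables[(selector, label)] = pd.DataFrame(
                X, index=ids, columns=[f"{label}-{c}" for c in "abc"])
    color = pd.DataFrame(rng.normal(size=(n, 2)), index=ids,
                         columns=["c1", "c2"])
    texture = pd.DataFrame(
        k.to_numpy()[:, None] + rng.normal(0, 0.2, size=(n, 2)), index=ids,
        columns=["t1", "t2"])
    split = ls.concentration_gradient_split(k.to_numpy(), ids)
    return tables, color, texture, k, split


class TestFuseAndCompare:
    def test_report_row_structure(self):
        tables, color, texture, k, split = _toy_tables()
        report = ls.fuse_and_compare(tables, color, texture, k, split, seed=0)
        assert len(report.spectral) == 2 * 11  # R + 10 scales per selector
        assert len(report.fusion) == 4
        sets = list(report.fusion.feature_set)
        base = report.best_feature_set
        assert sets == [base, f"{base} + color", f"{base} + texture",
                        f"{base} + color + texture"]

    def test_misaligned_tables_rejected(self):
        tables, color, texture, k, split = _toy_tables()
        color_bad = color.iloc[::-1]
        with pytest.raises(ModelError):
            ls.fuse_and_compare(tables, color_bad, texture, k, split, seed=0)

    def test_empty_image_tables_flagged_degraded(self):
        tables, _, _, k, split = _toy_tables()
        empty = pd.DataFrame(index=next(iter(tables.values())).index)
        report = ls.fuse_and_compare(tables, empty, empty, k, split, seed=0)
        degraded = report.fusion[report.fusion.degraded]
        assert len(degraded) == 3  # the three fusion rows add nothing

    def test_noise_features_do_not_help_on_average(self):
        """Guards the harness against leaking validation information."""
        diffs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 36
            ids = [f"s{i}" for i in range(n)]
            k = pd.Series(rng.uniform(0.4, 2.3, n), index=ids)
            base = pd.DataFrame(
                k.to_numpy()[:, None] + rng.normal(0, 0.25, size=(n, 3)),
                index=ids)
            noise = pd.DataFrame(rng.normal(size=(n, 5)), index=ids,
                                 columns=[f"n{j}" for j in range(5)])
            split = ls.concentration_gradient_split(k.to_numpy(), ids)
            cal = list(split.calibration_ids)
            val = list(split.validation_ids)
            res_base = fit_and_evaluate(
                base.loc[cal].to_numpy(), k.loc[cal].to_numpy(),
                base.loc[val].to_numpy(), k.loc[val].to_numpy(), "base",
                seed=seed)
            joined = pd.concat([base, noise], axis=1)
            res_noise = fit_and_evaluate(
                joined.loc[cal].to_numpy(), k.loc[cal].to_numpy(),
                joined.loc[val].to_numpy(), k.loc[val].to_numpy(), "noise",
                seed=seed)
            diffs.append(res_base.r2_val - res_noise.r2_val)
        assert np.mean(diffs) > -0.05
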