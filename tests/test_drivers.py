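"""Tests of dataset predictors and the driver OLS regressions."""

import numpy as np
import pandas as pd
import pytest

from likertfa.drivers import (
    MODEL_SPECS,
    PREDICTORS,
    RegressionResult,
    condition_dummies,
    dataset_predictors,
    fit_driver_models,
    interpolated_median,
    item_skewness,
    predict_fit,
    regression_table,
)


class TestInterpolatedMedian:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((0, 0, 2000, 0, 0), 3.0),
            ((500, 500, 500, 500, 0), 2.5),
            ((1000, 1000, 0, 0, 0), 1.5),
            ((400, 400, 400, 400, 400), 3.0),
            ((100, 0, 0, 0, 0), 1.0),
        ],
    )
    def test_grouped_median_formula(self, counts, expected):
        assert interpolated_median(counts) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            interpolated_median([0, 0, 0, 0, 0])


class TestItemSkewness:
    def test_symmetric_distribution(self):
        x = np.repeat([1, 2, 3, 4, 5], 400)
        assert item_skewness(x) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_moment_computation(self):
        x = np.repeat([1, 2], [1900, 100])
        m2 = np.mean((x - x.mean()) ** 2)
        m3 = np.mean((x - x.mean()) ** 3)
        assert item_skewness(x) == pytest.approx(m3 / m2**1.5)
        assert item_skewness(x) > 0

    def test_reversal_flips_sign(self):
        x = np.repeat([1, 2, 3, 4, 5], [800, 500, 300, 250, 150])
        assert item_skewness(6 - x) == pytest.approx(-item_skewness(x), abs=1e-12)

    def test_zero_variance_missing(self):
        assert np.isnan(item_skewness(np.full(100, 3)))


class TestDatasetPredictors:
    def test_identical_items_have_zero_spread(self):
        col = np.tile([1, 2, 3, 4, 5], 100)
        X = np.column_stack([col, col, col])
        pred = dataset_predictors(X)
        assert pred["iqr_interpolated_medians"] == pytest.approx(0.0)
        assert pred["skew_range"] == pytest.approx(0.0)

    def test_respondent_order_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.integers(1, 6, size=(300, 5))
        shuffled = X[rng.permutation(300)]
        assert dataset_predictors(X) == dataset_predictors(shuffled)

    def test_degenerate_item_flags_missing(self):
        X = np.column_stack([np.full(100, 3), np.tile([1, 2, 3, 4, 5], 20)])
        pred = dataset_predictors(X)
        assert np.isnan(pred["iqr_interpolated_medians"])

    def test_condition_dummies_one_hot(self):
        d = condition_dummies("bimodal", 8, "large")
        assert d["dist_bimodal"] == 1 and d["dist_uniform"] == 0
        assert d["items_8"] == 1 and d["items_10"] == 0
        assert d["error_dummy"] == 1


class TestDriverRegressions:
    def _synthetic_harvest(self, n=400, seed=1):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "error_dummy": rng.integers(0, 2, n).astype(float),
                "iqr_interpolated_medians": rng.uniform(0, 3, n),
                "skew_range": rng.uniform(0, 4, n),
                "dist_bimodal": 0.0,
                "dist_uniform": 0.0,
                "dist_skew_normal": 0.0,
                "items_8": 0.0,
                "items_10": 0.0,
            }
        )
        q = n // 4
        df.loc[: q - 1, "dist_bimodal"] = 1.0
        df.loc[q : 2 * q - 1, "dist_uniform"] = 1.0
        df.loc[2 * q : 3 * q - 1, "dist_skew_normal"] = 1.0  # last quarter: normal
        n_items = rng.choice([5, 8, 10], size=n)  # independent of distribution
        df["items_8"] = (n_items == 8).astype(float)
        df["items_10"] = (n_items == 10).astype(float)
        return df

    def test_exact_linear_response_recovered(self):
        df = self._synthetic_harvest()
        y = (
            0.5
            - 0.2 * df.error_dummy
            + 0.3 * df.iqr_interpolated_medians
            + 0.1 * df.skew_range
        )
        df["pearson_efa1_rmsea"] = y
        res = fit_driver_models(df, models={"C": ("pearson_efa1_rmsea", False)})["C"]
        assert res.adj_r_squared == pytest.approx(1.0)
        assert res.params["const"] == pytest.approx(0.5, abs=1e-10)
        assert res.params["iqr_interpolated_medians"] == pytest.approx(0.3, abs=1e-10)
        assert res.params["error_dummy"] == pytest.approx(-0.2, abs=1e-10)

    def test_cube_root_models_transform_dependent(self):
        df = self._synthetic_harvest()
        # dependent exactly linear on the cube-root scale
        lin = 2.0 + 1.5 * df.iqr_interpolated_medians
        df["pearson_delta_chi2"] = lin**3
        res = fit_driver_models(df, models={"A": ("pearson_delta_chi2", True)})["A"]
        assert res.adj_r_squared == pytest.approx(1.0)
        assert res.params["iqr_interpolated_medians"] == pytest.approx(1.5, abs=1e-8)

    def test_listwise_deletion(self):
        df = self._synthetic_harvest()
        df["pearson_efa1_rmsea"] = 0.1 + 0.05 * df.iqr_interpolated_medians
        df.loc[:19, "pearson_efa1_rmsea"] = np.nan
        res = fit_driver_models(df, models={"C": ("pearson_efa1_rmsea", False)})["C"]
        assert res.n_obs == len(df) - 20

    def test_too_few_records_rejected(self):
        df = self._synthetic_harvest(n=30)
        df["pearson_efa1_rmsea"] = 0.1
        with pytest.raises(ValueError):
            fit_driver_models(df)


class TestPredictFit:
    def _result(self):
        params = pd.Series(
            {"const": 0.03, "iqr_interpolated_medians": 0.10, "skew_range": 0.03,
             "items_8": -0.03, "error_dummy": -0.03},
        )
        zeros = pd.Series(0.0, index=params.index)
        return RegressionResult("C", "pearson_efa1_rmsea", False, params, zeros, zeros, 0.8, 100)

    def test_reference_scenario_is_intercept(self):
        assert predict_fit(self._result(), {}) == pytest.approx(0.03)

    def test_linearity(self):
        res = self._result()
        base = predict_fit(res, {"iqr_interpolated_medians": 1.0}) - res.params["const"]
        double = predict_fit(res, {"iqr_interpolated_medians": 2.0}) - res.params["const"]
        assert double == pytest.approx(2 * base)

    def test_worked_scenario_matches_hand_sum(self):
        # 8 items, normal population, spread 2, skew range 2.5, low error
        res = self._result()
        pred = predict_fit(
            res, {"items_8": 1, "iqr_interpolated_medians": 2.0, "skew_range": 2.5}
        )
        assert pred == pytest.approx(0.03 - 0.03 + 0.20 + 0.075)

    def test_cube_backtransform(self):
        res = self._result()
        res.cube_root = True
        assert predict_fit(res, {}) == pytest.approx(0.03**3)

    def test_unknown_predictor_rejected(self):
        with pytest.raises(KeyError):
            predict_fit(self._result(), {"bogus": 1.0})


def test_regression_table_layout():
    params = pd.Series({"const": 1.0, **{p: 0.1 for p in PREDICTORS}})
    zeros = pd.Series(0.0, index=params.index)
    res = {"A": RegressionResult("A", "pearson_delta_chi2", True, params, zeros, zeros, 0.9, 100)}
    tab = regression_table(res)
    assert "Model A" in tab.columns
    assert tab.loc["adj_r_squared", "Model A"] == 0.9
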