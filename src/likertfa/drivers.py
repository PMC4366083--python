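"""Per-dataset predictors and the OLS regressions of the fit-statistic drivers.

The spread of item locations is measured by the inter-quartile range of the
items' interpolated medians; the disparity of item shapes by the range of
their moment skewnesses.  Ten OLS models (A-J) regress (transformed) fit
statistics of the 1-factor model on these predictors plus dummies for error
level, population distribution (reference: normal) and item-set size
(reference: 5 items).  Chi-square-distributed outcomes are cube-root
transformed against heteroskedasticity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "interpolated_median",
    "item_skewness",
    "dataset_predictors",
    "MODEL_SPECS",
    "fit_driver_models",
    "predict_fit",
]

PREDICTORS = [
    "error_dummy",
    "iqr_interpolated_medians",
    "skew_range",
    "dist_bimodal",
    "dist_uniform",
    "dist_skew_normal",
    "items_8",
    "items_10",
]

#: model id -> (harvest column of the dependent variable, cube-root flag)
MODEL_SPECS: dict[str, tuple[str, bool]] = {
    "A": ("pearson_delta_chi2", True),
    "B": ("polychoric_delta_chi2", True),
    "C": ("pearson_efa1_rmsea", False),
    "D": ("polychoric_efa1_rmsea", False),
    "E": ("pearson_cfa_chi2", True),
    "F": ("polychoric_cfa_chi2", True),
    "G": ("pearson_cfa_agfi", False),
    "H": ("polychoric_cfa_agfi", False),
    "I": ("pearson_cfa_rmsea", False),
    "J": ("polychoric_cfa_rmsea", False),
}


@dataclass
class RegressionResult:
    model_id: str
    dependent: str
    cube_root: bool
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    adj_r_squared: float
    n_obs: int


def interpolated_median(category_counts) -> float:
    """Grouped-data median of a five-category response distribution.

    Category k spans [k - 0.5, k + 0.5); with m the lowest category whose
    cumulative count reaches n/2, IM = m - 0.5 + (n/2 - F_{m-1}) / f_m.
    """
    counts = np.asarray(category_counts, dtype=float)
    total = counts.sum()
    if total < 1:
        raise ValueError("need at least one observation")
    cum = np.cumsum(counts)
    m = int(np.searchsorted(cum, total / 2.0))  # 0-based index of category m
    below = cum[m - 1] if m > 0 else 0.0
    return float((m + 1) - 0.5 + (total / 2.0 - below) / counts[m])


def item_skewness(responses) -> float:
    """Moment-based sample skewness g1 = m3 / m2^(3/2) of the codes."""
    x = np.asarray(responses, dtype=float)
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        return np.nan
    m3 = np.mean((x - x.mean()) ** 3)
    return float(m3 / m2**1.5)


def dataset_predictors(R) -> dict:
    """Spread-of-locations and skew-disparity predictors of one dataset.

    IQR of the p interpolated medians uses linear-interpolation quantiles;
    the skew range is max - min item skewness.  Degenerate items leave the
    predictors missing.
    """
    X = np.asarray(getattr(R, "responses", R))
    medians = []
    skews = []
    degenerate = False
    for j in range(X.shape[1]):
        counts = np.bincount(X[:, j], minlength=6)[1:6]
        if np.count_nonzero(counts) < 2:
            degenerate = True
            continue
        medians.append(interpolated_median(counts))
        skews.append(item_skewness(X[:, j]))
    if degenerate or not medians:
        return {"iqr_interpolated_medians": np.nan, "skew_range": np.nan}
    q1, q3 = np.percentile(medians, [25, 75])  # linear interpolation
    return {
        "iqr_interpolated_medians": float(q3 - q1),
        "skew_range": float(np.max(skews) - np.min(skews)),
    }


def condition_dummies(distribution_name: str, n_items: int, error_level: str) -> dict:
    return {
        "error_dummy": 1.0 if error_level == "large" else 0.0,
        "dist_bimodal": 1.0 if distribution_name == "bimodal" else 0.0,
        "dist_uniform": 1.0 if distribution_name == "uniform" else 0.0,
        "dist_skew_normal": 1.0 if distribution_name == "skew_normal" else 0.0,
        "items_8": 1.0 if n_items == 8 else 0.0,
        "items_10": 1.0 if n_items == 10 else 0.0,
    }


def fit_driver_models(
    harvest: pd.DataFrame, models: dict[str, tuple[str, bool]] | None = None
) -> dict[str, RegressionResult]:
    """Fit the ten OLS driver models on a harvest table (listwise per model)."""
    models = MODEL_SPECS if models is None else models
    if len(harvest) < 50:
        raise ValueError("need at least 50 harvest records for the driver regressions")
    results = {}
    for model_id, (column, cube_root) in models.items():
        cols = [column] + PREDICTORS
        data = harvest[cols].dropna()
        y = np.cbrt(data[column]) if cube_root else data[column]
        X = sm.add_constant(data[PREDICTORS])
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(f"model {model_id}: design matrix is rank deficient")
        fit = sm.OLS(y, X).fit()
        results[model_id] = RegressionResult(
            model_id=model_id,
            dependent=column,
            cube_root=cube_root,
            params=fit.params,
            bse=fit.bse,
            pvalues=fit.pvalues,
            adj_r_squared=float(fit.rsquared_adj),
            n_obs=int(fit.nobs),
        )
    return results


def predict_fit(model: RegressionResult, scenario: dict) -> float:
    """Linear prediction of a fit statistic for a hypothetical item set.

    ``scenario`` maps predictor names to values; omitted predictors sit at
    their reference/zero level.  Cube-root models are back-transformed by
    cubing the linear prediction.
    """
    pred = float(model.params.get("const", 0.0))
    for name, value in scenario.items():
        if name not in model.params.index:
            raise KeyError(f"unknown predictor {name!r}")
        pred += float(model.params[name]) * value
    return pred**3 if model.cube_root else pred


def regression_table(results: dict[str, RegressionResult]) -> pd.DataFrame:
    """Coefficient table: rows = intercept + predictors (+ fit info)."""
    cols = {}
    for mid, res in results.items():
        col = res.params.reindex(["const"] + PREDICTORS)
        col["adj_r_squared"] = res.adj_r_squared
        col["n_obs"] = res.n_obs
        cols[f"Model {mid}"] = col
    return pd.DataFrame(cols)
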