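#!/usr/bin/env python
"""What drives the (lack of) fit of 1-factor models on unidimensional items.

Fits the ten OLS models (A-J) regressing fit statistics of the 1-factor
model -- cube-rooted delta chi-square and CFA chi-square, EFA/CFA RMSEA,
CFA AGFI; Pearson and polychoric branches alternating -- on the spread of
item locations (IQR of interpolated medians), the range of item skews, the
error-level dummy, and population/item-count dummies.  Writes the
coefficient table and a tidy long format to results/.

Expected pattern: adjusted R-squared above .75 throughout; larger item
spread and skew disparity worsen fit (positive for chi-square/RMSEA,
negative for AGFI); more random error mildly improves fit; bimodal and
uniform populations fit worse than normal ones.  Ends with the worked
prediction: the RMSEA one should expect for a *truly unidimensional*
8-item set with spread 2 and skew range 2.5 under a normal population.
"""

import argparse
from pathlib import Path

import pandas as pd

from likertfa.drivers import fit_driver_models, predict_fit, regression_table

parser = argparse.ArgumentParser()
parser.add_argument("--harvest", type=Path, default=Path("results/harvest.csv"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

harvest = pd.read_csv(args.harvest)
# adjusted R-squared is composition-dependent: fit on an item-count-balanced
# design (scaled runs replicate 5-item cells more heavily than 8/10-item ones)
min_reps = harvest.groupby(["distribution", "n_items", "error"]).size().min()
harvest = harvest[harvest.replicate < min_reps]
results = fit_driver_models(harvest)

table = regression_table(results)
table.round(4).to_csv(args.outdir / "table6_regressions.csv")
long = pd.concat(
    {m: pd.DataFrame({"coef": r.params, "se": r.bse, "p": r.pvalues})
     for m, r in results.items()},
    names=["model", "term"],
)
long.to_csv(args.outdir / "table6_regressions_long.csv")

print("Adjusted R-squared by model:")
print(table.loc["adj_r_squared"].round(3))
print("\nIQR-of-medians coefficients (positive except AGFI models G/H):")
print(table.loc["iqr_interpolated_medians"].round(3))

scenario = {"items_8": 1.0, "iqr_interpolated_medians": 2.0, "skew_range": 2.5}
for model_id in ("C", "D"):
    pred = predict_fit(results[model_id], scenario)
    branch = "Pearson" if model_id == "C" else "polychoric"
    print(f"\nExpected 1-factor EFA RMSEA ({branch}) for a unidimensional "
          f"8-item set, spread 2, skew range 2.5, low error: {pred:.3f}")
print("(values near 0.3 -- far beyond the 0.10 rejection rule -- even though "
      "the items measure a single dimension)")
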