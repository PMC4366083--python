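# likertfa

How often does factor analysis report **more than one factor** for survey
items that measure exactly **one** latent dimension? `likertfa` answers this
by Monte-Carlo simulation for the most common kind of survey data:
five-category ordered (Likert) items. It is aimed at methodologists and
applied researchers in the survey-heavy sciences (health, psychology,
sociology, politics, marketing) who need to judge how trustworthy a factor
analysis of ordinal items is.

## What it does

Respondents get positions θ on a single latent continuum, drawn from one of
four populations — N(50,20), a skew-normal (ξ=15, ω=25, α=5), a ½N(25,10) +
½N(75,10) mixture, or U(0,100). An item is four ascending category
boundaries; the true response is 1 + #{boundaries ≤ θ}, and a discretised
ordinal error (z ~ N(0,1); shift 0/1/2/3 categories by which cutoff interval
|z| falls in, direction sign(z), truncated to 1..5) produces the manifest
response. A design grid crosses 4 populations × {5, 8, 10} items × 2 error
levels, items sampled per dataset from a 27-item pool, n = 2000.

Each simulated dataset is then analysed both on Pearson and on two-step ML
**polychoric** correlations, with:

* retention heuristics — K1 (eigenvalues > 1), parallel analysis (95th
  centile of random-data eigenvalues), acceleration factor (largest second
  difference of the scree);
* EFA model fit — minres extraction, Bartlett-corrected
  χ² = (n − 1 − (2p+5)/6 − 2k/3)·F with the ML discrepancy
  F = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p, the 1- vs 2-factor Δχ² test (α = 1e-5),
  and RMSEA = √(max(χ²−df, 0)/(df(n−1))) > 0.10;
* CFA model fit — 1-factor ML fit (latent variance 1),
  χ² = (n−1)·F at α = .001, AGFI < 0.90, RMSEA > 0.10.

Every verdict and statistic lands in one harvest row per dataset; risk
tables report the percentage of datasets diagnosed as multi-factor per
condition, and ten OLS models regress the fit statistics on the spread of
item locations (IQR of interpolated medians), the range of item skews, and
the design dummies. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from likertfa import (DISTRIBUTIONS, ERROR_MODELS, build_grid,
                      generate_dataset, analyze_dataset)

cond = build_grid(master_seed=1, replicates=1)[0]   # normal, 5 items, large error
R = generate_dataset(cond)
rec = analyze_dataset(R)
print(R.item_ids,
      int(rec["pearson_nfac_k1"]),
      round(rec["pearson_efa1_rmsea"], 3),
      round(rec["pearson_cfa_agfi"], 3))
```

prints

```
[9, 24, 21, 16, 17] 1 0.054 0.98
```

— for this draw K1 correctly keeps one factor and the fit indices happen to
be acceptable. Across the grid this is the exception: on the scaled
replication (1200 datasets) the 1-factor model is *rejected* by the EFA Δχ²
test in ≳96% of normal-population 5-item datasets, the mean 1-factor EFA χ²
of 5-item sets is ≈508 (dropping to ≈11 with two factors), the grid-wide
mean 1-factor RMSEA is ≈0.19 on either correlation type, and K1 on Pearson
correlations calls a skewed-normal 10-item set multidimensional in roughly
half the cases — all for data that are unidimensional by construction.

The analysis scripts narrate the study end to end and write their tables to
`results/`:

```bash
python analysis/01_test_retest.py            # item reliability (Table-2 analogue)
python analysis/02_run_grid.py               # simulate + analyse the grid -> harvest.csv
python analysis/03_risk_tables.py            # risk tables + headline averages
python analysis/04_regressions.py            # OLS drivers of (mis)fit
```

A `likertfa` console script exposes the same steps
(`likertfa analyze|tables|regress|all`).

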