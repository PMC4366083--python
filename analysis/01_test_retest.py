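#!/usr/bin/env python
"""Item reliability of the simulated pool: test-retest correlations.

For each latent population distribution and error level, one simulated
sample of 2000 respondents answers all 27 pool items twice with independent
error draws; the per-item correlation between the two response sets is the
item's test-retest stability.  Writes the per-item table and the
mean/min/max/spread summary (Pearson and polychoric) to results/.

Expected pattern: higher stability for small error; higher means for the
high-variance uniform and bimodal populations (about .88 Pearson under
large error) than for the normal (about .80) and skew-normal (about .72);
a wide spread across items despite an identical error mechanism, driven
purely by the categorisation.
"""

import argparse
from pathlib import Path

import pandas as pd

from likertfa.simulate import (
    DISTRIBUTIONS,
    ERROR_MODELS,
    summarise_test_retest,
    test_retest,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

per_item = []
summaries = []
for err_name, error in ERROR_MODELS.items():
    for dist_name, spec in DISTRIBUTIONS.items():
        tab = test_retest(spec, error, seed=args.seed)
        tab.insert(0, "distribution", dist_name)
        tab.insert(1, "error", err_name)
        per_item.append(tab)
        s = summarise_test_retest(tab)
        s.index.name = "statistic"
        s = s.reset_index().assign(distribution=dist_name, error=err_name)
        summaries.append(s)

pd.concat(per_item).to_csv(args.outdir / "table2_per_item.csv", index=False)
summary = pd.concat(summaries)
summary.to_csv(args.outdir / "table2_test_retest.csv", index=False)

wide = summary.pivot_table(
    index="statistic", columns=["error", "distribution"], values="pearson"
).round(2)
print("Pearson test-retest summary by error level and distribution:")
print(wide)
means = summary[summary.statistic == "mean"]
print("\nPolychoric means exceed Pearson means in every condition:",
      bool((means.polychoric > means.pearson).all()))
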