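"""Grid orchestration: simulate, analyse, harvest, and tabulate risks.

Every simulated dataset is pushed through both correlation branches
(Pearson, polychoric), the three retention rules, 1- and 2-factor minres
EFA with the delta-chi-square comparison and RMSEA rule, and the 1-factor
ML CFA with chi-square/AGFI/RMSEA rules.  One harvest row per dataset holds
every verdict and statistic; branch failures (non-PD or non-convergent
polychoric matrices, CFA non-convergence) become missing values for that
branch only, and risk tables report percentages over the non-missing
denominators, pooled over the two error levels.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import drivers
from .correlations import pearson_matrix, polychoric_matrix
from .factor_fit import (
    DecisionRules,
    cfa_1factor,
    delta_chi2_test,
    efa_fit_stats,
    minres_efa,
)
from .items import ItemDefinition, load_item_pool
from .retention import (
    acceleration_factor,
    eigenvalues,
    k1,
    parallel_analysis,
    reference_eigenvalue_centiles,
)
from .simulate import ResponseMatrix, SimulationCondition, generate_dataset

__all__ = [
    "analyze_dataset",
    "run_grid",
    "risk_table",
    "TABLE3_FLAGS",
    "TABLE4_FLAGS",
    "TABLE5_FLAGS",
    "DIST_ORDER",
    "write_dataset",
]

DIST_ORDER = ["normal", "skew_normal", "uniform", "bimodal"]

#: harvest flag columns feeding each published risk table
TABLE3_FLAGS = [
    "pearson_over_k1",
    "polychoric_over_k1",
    "pearson_over_pa",
    "polychoric_over_pa",
    "pearson_over_af",
    "polychoric_over_af",
]
TABLE4_FLAGS = [
    "pearson_delta_reject",
    "polychoric_delta_reject",
    "pearson_efa1_rmsea_reject",
    "polychoric_efa1_rmsea_reject",
]
TABLE5_FLAGS = [
    "pearson_cfa_reject_chi2",
    "polychoric_cfa_reject_chi2",
    "pearson_cfa_reject_agfi",
    "polychoric_cfa_reject_agfi",
    "pearson_cfa_reject_rmsea",
    "polychoric_cfa_reject_rmsea",
]

_MAX_EIG_STORED = 10


def _branch_missing(kind: str) -> dict:
    cols = {}
    for i in range(1, _MAX_EIG_STORED + 1):
        cols[f"{kind}_eig{i}"] = np.nan
    for name in (
        "nfac_k1",
        "nfac_pa",
        "nfac_af",
        "over_k1",
        "over_pa",
        "over_af",
        "efa1_chi2",
        "efa1_df",
        "efa1_rmsea",
        "efa1_rmsea_reject",
        "efa2_chi2",
        "efa2_df",
        "delta_chi2",
        "delta_reject",
        "cfa_chi2",
        "cfa_df",
        "cfa_p",
        "cfa_gfi",
        "cfa_agfi",
        "cfa_rmsea",
        "cfa_reject_chi2",
        "cfa_reject_agfi",
        "cfa_reject_rmsea",
    ):
        cols[f"{kind}_{name}"] = np.nan
    cols[f"{kind}_ok"] = 0.0
    cols[f"{kind}_cfa_ok"] = 0.0
    return cols


def _analyze_branch(
    kind: str,
    C: np.ndarray,
    n: int,
    rules: DecisionRules,
    pa_reference: np.ndarray,
    pd_ok: bool = True,
) -> dict:
    cols = _branch_missing(kind)
    cols[f"{kind}_ok"] = 1.0
    eigs = eigenvalues(C)
    for i, val in enumerate(eigs[:_MAX_EIG_STORED], start=1):
        cols[f"{kind}_eig{i}"] = val
    n_pa, _ = parallel_analysis(eigs, n, len(eigs), reference=pa_reference)
    counts = {"k1": k1(eigs), "pa": n_pa, "af": acceleration_factor(eigs)}
    for crit, cnt in counts.items():
        cols[f"{kind}_nfac_{crit}"] = float(cnt)
        cols[f"{kind}_over_{crit}"] = float(cnt >= 2)
    if not pd_ok:
        # singular/indefinite matrix: retention rules above still apply but
        # the likelihood-based fits are recorded missing
        return cols

    try:
        m1 = minres_efa(C, 1)
        m2 = minres_efa(C, 2)
        if m1.converged and m2.converged:
            f1 = efa_fit_stats(C, m1, n)
            f2 = efa_fit_stats(C, m2, n)
            reject, delta, _, _ = delta_chi2_test(f1, f2, rules.efa_delta_alpha)
            cols[f"{kind}_efa1_chi2"] = f1.chi2
            cols[f"{kind}_efa1_df"] = float(f1.df)
            cols[f"{kind}_efa1_rmsea"] = f1.rmsea
            cols[f"{kind}_efa1_rmsea_reject"] = float(f1.rmsea > rules.rmsea_cutoff)
            cols[f"{kind}_efa2_chi2"] = f2.chi2
            cols[f"{kind}_efa2_df"] = float(f2.df)
            cols[f"{kind}_delta_chi2"] = delta
            cols[f"{kind}_delta_reject"] = float(reject)
    except np.linalg.LinAlgError:
        pass

    try:
        _, cfa = cfa_1factor(C, n, rules)
        if cfa.converged:
            cols[f"{kind}_cfa_ok"] = 1.0
            cols[f"{kind}_cfa_chi2"] = cfa.chi2
            cols[f"{kind}_cfa_df"] = float(cfa.df)
            cols[f"{kind}_cfa_p"] = cfa.p_value
            cols[f"{kind}_cfa_gfi"] = cfa.gfi
            cols[f"{kind}_cfa_agfi"] = cfa.agfi
            cols[f"{kind}_cfa_rmsea"] = cfa.rmsea
            cols[f"{kind}_cfa_reject_chi2"] = float(cfa.p_value < rules.cfa_chi2_alpha)
            cols[f"{kind}_cfa_reject_agfi"] = float(cfa.agfi < rules.agfi_cutoff)
            cols[f"{kind}_cfa_reject_rmsea"] = float(cfa.rmsea > rules.rmsea_cutoff)
    except np.linalg.LinAlgError:
        pass
    return cols


def analyze_dataset(
    R: ResponseMatrix,
    rules: DecisionRules = DecisionRules(),
    pa_nrep: int = 100,
) -> dict:
    """Full two-branch analysis of one simulated dataset -> harvest record.

    The parallel-analysis reference eigenvalue centiles are simulated once
    per dataset (sub-seeded from the dataset seed) and shared by both
    correlation branches, which analyse matrices of identical size.
    """
    cond = R.condition
    n, p = R.responses.shape
    record: dict = {
        "distribution": cond.distribution_name,
        "n_items": p,
        "error": cond.error.level,
        "replicate": cond.replicate,
        "seed": cond.seed,
        "item_ids": ";".join(str(i) for i in R.item_ids),
    }
    record.update(drivers.dataset_predictors(R))
    record.update(
        drivers.condition_dummies(cond.distribution_name, p, cond.error.level)
    )
    pa_rng = np.random.default_rng([cond.seed, 1])
    pa_reference = reference_eigenvalue_centiles(n, p, nrep=pa_nrep, seed=pa_rng)

    pearson = pearson_matrix(R)
    if pearson.converged:
        record.update(
            _analyze_branch(
                "pearson", pearson.matrix, n, rules, pa_reference,
                pd_ok=pearson.positive_definite,
            )
        )
    else:
        record.update(_branch_missing("pearson"))

    poly = polychoric_matrix(R)
    if poly.usable:
        record.update(_analyze_branch("polychoric", poly.matrix, n, rules, pa_reference))
    else:
        record.update(_branch_missing("polychoric"))
    return record


def run_grid(
    conditions: Sequence[SimulationCondition],
    pool: Sequence[ItemDefinition] | None = None,
    rules: DecisionRules = DecisionRules(),
    pa_nrep: int = 100,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate and analyse every condition; one harvest row per dataset."""
    pool = list(load_item_pool() if pool is None else pool)
    rows = []
    for i, cond in enumerate(conditions):
        R = generate_dataset(cond, pool)
        rows.append(analyze_dataset(R, rules, pa_nrep))
        if progress and (i + 1) % 50 == 0:
            print(f"  analysed {i + 1}/{len(conditions)} datasets", flush=True)
    return pd.DataFrame(rows)


def risk_table(
    harvest: pd.DataFrame, flag_columns: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage tables by distribution x item count, pooled over error.

    Returns (percentages, denominators); cells with no usable datasets stay
    NaN rather than reading as 0%.
    """
    if harvest.empty:
        raise ValueError("harvest is empty")
    grouped = harvest.groupby(["distribution", "n_items"])
    pct = grouped[list(flag_columns)].mean() * 100.0
    denom = grouped[list(flag_columns)].count()
    order = [d for d in DIST_ORDER if d in pct.index.get_level_values(0)]
    pct = pct.loc[order]
    denom = denom.loc[order]
    return pct, denom


def write_dataset(R: ResponseMatrix, path: str | Path) -> None:
    """Write one simulated dataset as CSV plus a JSON condition sidecar."""
    path = Path(path)
    df = pd.DataFrame(R.responses, columns=[f"item_{i}" for i in R.item_ids])
    df.to_csv(path, index=False)
    cond = R.condition
    sidecar = {
        "distribution": cond.distribution_name,
        "n_items": cond.n_items,
        "error": cond.error.level,
        "replicate": cond.replicate,
        "seed": cond.seed,
        "n_respondents": cond.n_respondents,
        "item_ids": R.item_ids,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
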