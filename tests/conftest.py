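"""Shared fixtures: the scaled replication harvest and test-retest tables.

The replication grid mirrors the full study design (4 distributions x
{5, 8, 10} items x 2 error levels, n = 2000) at reduced replication:
100 datasets per cell for the cheap 5-item cells (the full per-cell count)
and 25 per cell for 8- and 10-item cells.  It is computed once per session
and shared by the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from likertfa.items import load_item_pool
from likertfa.pipeline import run_grid
from likertfa.simulate import (
    DISTRIBUTIONS,
    ERROR_MODELS,
    build_grid,
    summarise_test_retest,
    test_retest,
)

HARNESS_SEED = 727
REPLICATES = {5: 100, 8: 25, 10: 25}


@pytest.fixture(scope="session")
def pool():
    return load_item_pool()


@pytest.fixture(scope="session")
def harvest():
    conditions = build_grid(master_seed=HARNESS_SEED, replicates=REPLICATES)
    return run_grid(conditions)


@pytest.fixture(scope="session")
def retest_summaries():
    """Table-2 analogue: test-retest summaries per distribution, large error."""
    return {
        name: summarise_test_retest(
            test_retest(spec, ERROR_MODELS["large"], seed=HARNESS_SEED + 1)
        )
        for name, spec in DISTRIBUTIONS.items()
    }


def proportion_band(p_pct: float, n: int, floor: float = 3.0) -> float:
    """Monte-Carlo band for a cell percentage: 3 binomial SEs, 3pp floor."""
    p = p_pct / 100.0
    return max(300.0 * np.sqrt(p * (1.0 - p) / n), floor)
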