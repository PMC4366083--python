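"""Pearson and polychoric correlation estimation for ordinal item responses.

The polychoric estimator is the standard two-step one: thresholds are fixed
at normal quantiles of the marginal cumulative proportions (empty categories
collapsed), then the correlation of the underlying bivariate normal is found
by one-dimensional maximum likelihood over the rectangle probabilities of
the contingency table.  Failures (degenerate margins, non-convergence,
non-positive-definite assembled matrices) are flagged, not repaired --
downstream analyses drop flagged datasets instead of smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtri

from .bvn import bvn_cdf

__all__ = [
    "CorrelationEstimate",
    "pearson_matrix",
    "pairwise_pearson",
    "estimate_thresholds",
    "polychoric_rho",
    "polychoric_pair",
    "polychoric_matrix",
]

_PD_TOL = 1e-8
_PROB_FLOOR = 1e-12
_RHO_BOUND = 0.999


@dataclass
class CorrelationEstimate:
    """A p x p correlation matrix with convergence/definiteness diagnostics."""

    matrix: np.ndarray
    kind: str  # "pearson" | "polychoric"
    converged: bool
    positive_definite: bool
    pairwise_flags: dict = field(default_factory=dict)

    @property
    def usable(self) -> bool:
        """Usable for likelihood-based analyses (mirrors the exclusion rule)."""
        return self.converged and self.positive_definite


def _codes(R) -> np.ndarray:
    return np.asarray(getattr(R, "responses", R))


def pearson_matrix(R) -> CorrelationEstimate:
    """Product-moment correlations of the integer response codes."""
    X = _codes(R).astype(float)
    flags = {}
    var = X.var(axis=0)
    ok = True
    if np.any(var == 0):
        for j in np.flatnonzero(var == 0):
            flags[int(j)] = "zero variance"
        ok = False
        C = np.full((X.shape[1], X.shape[1]), np.nan)
    else:
        C = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(C, 1.0)
    pd_flag = ok and bool(np.linalg.eigvalsh(C).min() > _PD_TOL)
    return CorrelationEstimate(C, "pearson", ok, pd_flag, flags)


def pairwise_pearson(a, b) -> float:
    return float(np.corrcoef(np.asarray(a, float), np.asarray(b, float))[0, 1])


def estimate_thresholds(category_counts) -> np.ndarray:
    """Normal-scale thresholds from marginal category counts (step 1).

    tau_k = Phi^-1(cumulative proportion through category k) for every
    boundary with nonzero mass on both sides; boundaries of empty categories
    collapse away.  All mass in one category -> empty threshold set.
    """
    counts = np.asarray(category_counts, dtype=float)
    total = counts.sum()
    if total < 1:
        raise ValueError("need at least one observation")
    cum = np.cumsum(counts)[:-1] / total
    cum = np.unique(cum[(cum > 0) & (cum < 1)])
    return ndtri(cum)


def _cell_probabilities(rho: float, tau_a: np.ndarray, tau_b: np.ndarray) -> np.ndarray:
    edges_a = np.concatenate(([-np.inf], tau_a, [np.inf]))
    edges_b = np.concatenate(([-np.inf], tau_b, [np.inf]))
    F = bvn_cdf(edges_a[:, None], edges_b[None, :], rho)
    return np.diff(np.diff(F, axis=0), axis=1)


def polychoric_rho(
    table, thresholds_a, thresholds_b
) -> tuple[float, bool]:
    """Two-step ML estimate of the latent correlation for one item pair.

    Maximises sum n_ij log pi_ij(rho; tau_a, tau_b) by bounded scalar search
    on (-0.999, 0.999) with the thresholds held fixed; cell probabilities
    are floored at 1e-12 (no continuity correction).
    """
    n = np.asarray(table, dtype=float)
    tau_a = np.asarray(thresholds_a, dtype=float)
    tau_b = np.asarray(thresholds_b, dtype=float)
    if tau_a.size == 0 or tau_b.size == 0:
        return np.nan, False

    def negloglik(rho: float) -> float:
        pi = np.clip(_cell_probabilities(rho, tau_a, tau_b), _PROB_FLOOR, None)
        return -float(np.sum(n * np.log(pi)))

    res = minimize_scalar(
        negloglik,
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x), bool(res.success)


def polychoric_pair(a, b) -> tuple[float, bool]:
    """Polychoric correlation between two ordinal code vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    cats_a, ia = np.unique(a, return_inverse=True)
    cats_b, ib = np.unique(b, return_inverse=True)
    if cats_a.size < 2 or cats_b.size < 2:
        return np.nan, False
    table = np.zeros((cats_a.size, cats_b.size))
    np.add.at(table, (ia, ib), 1.0)
    tau_a = estimate_thresholds(table.sum(axis=1))
    tau_b = estimate_thresholds(table.sum(axis=0))
    return polychoric_rho(table, tau_a, tau_b)


def polychoric_matrix(R) -> CorrelationEstimate:
    """Pairwise polychoric correlation matrix with diagnostics.

    Any degenerate or non-convergent pair, or a non-positive-definite
    assembly, marks the matrix unusable; no smoothing is applied.
    """
    X = _codes(R)
    p = X.shape[1]
    C = np.eye(p)
    flags = {}
    ok = True
    for i in range(p):
        for j in range(i + 1, p):
            rho, conv = polychoric_pair(X[:, i], X[:, j])
            if not conv:
                flags[(i, j)] = "degenerate or non-convergent"
                ok = False
            C[i, j] = C[j, i] = rho
    pd_flag = ok and bool(np.linalg.eigvalsh(C).min() > _PD_TOL)
    return CorrelationEstimate(C, "polychoric", ok, pd_flag, flags)
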