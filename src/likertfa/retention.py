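"""Eigenvalue-based factor-retention rules: K1, parallel analysis, scree AF.

All three work on the eigenvalues of the unreduced correlation matrix.  K1
counts eigenvalues above a threshold (default 1, strictly greater).  Parallel
analysis compares leading observed eigenvalues to a centile (default 95th) of
eigenvalues of random standard-normal data of the same size, stopping at the
first failure.  The acceleration factor is a non-graphical scree rule placing
the elbow at the largest second difference of the eigenvalue sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RetentionResult",
    "eigenvalues",
    "k1",
    "parallel_analysis",
    "acceleration_factor",
    "retention_counts",
]


@dataclass(frozen=True)
class RetentionResult:
    eigenvalues: np.ndarray
    n_factors_k1: int
    n_factors_pa: int
    n_factors_af: int
    pa_centiles: np.ndarray


def eigenvalues(C: np.ndarray) -> np.ndarray:
    """Descending real eigenvalues of a symmetric correlation matrix."""
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    return np.sort(np.linalg.eigvalsh(C))[::-1]


def k1(eigs: np.ndarray, threshold: float = 1.0) -> int:
    """Count of eigenvalues strictly above the threshold (Kaiser rule).

    The conventional threshold is 1; 0.7 (Jolliffe) and 1.40 (Raiche) are
    occasionally discussed and can be passed instead.
    """
    return int(np.sum(np.asarray(eigs) > threshold))


def reference_eigenvalue_centiles(
    n: int,
    p: int,
    nrep: int = 100,
    centile: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-rank centiles of correlation eigenvalues of random normal data."""
    rng = np.random.default_rng(seed)
    sims = np.empty((nrep, p))
    for r in range(nrep):
        X = rng.standard_normal((n, p))
        sims[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    return np.percentile(sims, centile, axis=0)


def parallel_analysis(
    eigs: np.ndarray,
    n: int,
    p: int,
    nrep: int = 100,
    centile: float = 95.0,
    seed: int | np.random.Generator = 0,
    reference: np.ndarray | None = None,
) -> tuple[int, np.ndarray]:
    """Parallel analysis retained-factor count and the reference centiles.

    Retains the leading observed eigenvalues that exceed the corresponding
    rank's centile among ``nrep`` random-data eigenvalue sets, stopping at
    the first rank that fails.  A precomputed ``reference`` (e.g. shared
    between correlation kinds for the same n, p) may be passed.
    """
    eigs = np.asarray(eigs, dtype=float)
    if reference is None:
        if nrep < 20:
            import warnings

            warnings.warn("parallel analysis with nrep < 20 has unstable centiles")
        reference = reference_eigenvalue_centiles(n, p, nrep, centile, seed)
    exceeds = eigs[: len(reference)] > reference
    stop = np.argmin(exceeds) if not exceeds.all() else len(exceeds)
    return int(stop), np.asarray(reference)


def acceleration_factor(eigs: np.ndarray) -> int:
    """Non-graphical scree: elbow at the largest second difference.

    af_i = e_{i+1} - 2 e_i + e_{i-1} for interior ranks i = 2..p-1 (1-based);
    the retained count is the elbow rank minus one, floored at one factor.
    """
    e = np.asarray(eigs, dtype=float)
    if e.size < 3:
        raise ValueError("acceleration factor needs at least 3 eigenvalues")
    af = e[2:] - 2.0 * e[1:-1] + e[:-2]  # af[j] is rank j+2 in 1-based terms
    elbow = int(np.argmax(af)) + 2
    return max(elbow - 1, 1)


def retention_counts(
    C: np.ndarray,
    n: int,
    nrep: int = 100,
    centile: float = 95.0,
    seed: int | np.random.Generator = 0,
    pa_reference: np.ndarray | None = None,
) -> RetentionResult:
    """All three retention rules on one correlation matrix."""
    eigs = eigenvalues(C)
    n_pa, ref = parallel_analysis(
        eigs, n, len(eigs), nrep=nrep, centile=centile, seed=seed, reference=pa_reference
    )
    return RetentionResult(
        eigenvalues=eigs,
        n_factors_k1=k1(eigs),
        n_factors_pa=n_pa,
        n_factors_af=acceleration_factor(eigs),
        pa_centiles=ref,
    )
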