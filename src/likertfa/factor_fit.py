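"""Exploratory (minres) and confirmatory (ML) factor models with fit indices.

The EFA extraction is minimum-residual: uniquenesses are chosen to minimise
the squared off-diagonal residuals of C - Lambda Lambda', with the loadings
the best rank-k approximation of the reduced matrix.  Fit statistics for EFA
use the ML discrepancy evaluated at the minres solution with the Bartlett
correction chi2 = (n - 1 - (2p+5)/6 - 2k/3) F.  The 1-factor CFA is a direct
ML fit (latent variance fixed at 1, free loadings and uniquenesses) with
chi2 = (n-1) F, plus GFI/AGFI and RMSEA.  Rejection rules follow the study's
conventions: delta-chi-square at alpha 1e-5, CFA chi-square at alpha 1e-3,
RMSEA > 0.10, AGFI < 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FactorModel",
    "FitStats",
    "DecisionRules",
    "minres_efa",
    "ml_discrepancy",
    "efa_chi2",
    "efa_df",
    "delta_chi2_test",
    "rmsea",
    "gfi_agfi",
    "cfa_1factor",
    "efa_fit_stats",
]

_UNIQUENESS_FLOOR = 1e-4
_COMMUNALITY_CAP = 1.0 - 1e-6


@dataclass
class FactorModel:
    loadings: np.ndarray  # p x k
    uniquenesses: np.ndarray  # p
    k: int
    method: str  # "minres" | "ml"
    converged: bool
    heywood: bool

    @property
    def implied_matrix(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.uniquenesses)

    @property
    def communalities(self) -> np.ndarray:
        return np.sum(self.loadings**2, axis=1)


@dataclass
class FitStats:
    discrepancy: float
    chi2: float
    df: int
    p_value: float
    rmsea: float
    gfi: float
    agfi: float
    converged: bool
    heywood: bool


@dataclass(frozen=True)
class DecisionRules:
    """Accept/reject conventions for the 1-factor model."""

    efa_delta_alpha: float = 1e-5
    cfa_chi2_alpha: float = 1e-3
    rmsea_cutoff: float = 0.10
    agfi_cutoff: float = 0.90


def efa_df(p: int, k: int) -> int:
    """Degrees of freedom of a k-factor EFA model on p items."""
    df = ((p - k) ** 2 - (p + k)) / 2
    if df < 0:
        raise ValueError(f"k={k} factors not identified for p={p} items")
    return int(df)


def _reduced_loadings(C: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    """Best rank-k loadings of the reduced matrix C - diag(psi)."""
    S = C.copy()
    np.fill_diagonal(S, 1.0 - psi)
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1][:k]
    lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    # sign convention only; fit statistics are invariant
    signs = np.where(lam.sum(axis=0) < 0, -1.0, 1.0)
    return lam * signs


def minres_efa(C: np.ndarray, k: int) -> FactorModel:
    """Minimum-residual EFA: k factors on a p x p correlation matrix."""
    C = np.asarray(C, dtype=float)
    p = C.shape[0]
    efa_df(p, k)  # raises if not identified

    def objective(psi: np.ndarray) -> float:
        lam = _reduced_loadings(C, psi, k)
        resid = C - lam @ lam.T
        np.fill_diagonal(resid, 0.0)
        return float(np.sum(resid**2))

    # start from 1 - squared multiple correlation when C is invertible
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(C))
        psi0 = np.clip(1.0 - smc, 0.05, 1.0)
    except np.linalg.LinAlgError:
        psi0 = np.full(p, 0.5)
    res = optimize.minimize(
        objective,
        psi0,
        method="L-BFGS-B",
        bounds=[(_UNIQUENESS_FLOOR, 1.0)] * p,
        options={"maxfun": 10_000, "ftol": 1e-12, "gtol": 1e-8},
    )
    lam = _reduced_loadings(C, res.x, k)
    comm = np.sum(lam**2, axis=1)
    heywood = bool(np.any(comm >= 1.0))
    if heywood:
        scale = np.sqrt(np.minimum(comm, _COMMUNALITY_CAP) / np.where(comm > 0, comm, 1.0))
        lam = lam * scale[:, None]
        comm = np.sum(lam**2, axis=1)
    return FactorModel(
        loadings=lam,
        uniquenesses=1.0 - comm,
        k=k,
        method="minres",
        converged=bool(res.success),
        heywood=heywood,
    )


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """ML lack-of-fit F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p (>= 0)."""
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_m <= 0:
        raise np.linalg.LinAlgError("implied matrix is not positive definite")
    if sign_s <= 0:
        raise np.linalg.LinAlgError("observed matrix is not positive definite")
    F = logdet_m - logdet_s + float(np.trace(np.linalg.solve(Sigma, S))) - p
    return max(F, 0.0)


def efa_chi2(F: float, n: int, p: int, k: int) -> tuple[float, int, float]:
    """Bartlett-corrected chi-square of a k-factor EFA model."""
    df = efa_df(p, k)
    chi2 = max(n - 1 - (2 * p + 5) / 6 - 2 * k / 3, 0.0) * F
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
    return float(chi2), df, p_value


def delta_chi2_test(
    fit1: FitStats, fit2: FitStats, alpha: float = 1e-5
) -> tuple[bool, float, int, float]:
    """Nested-model chi-square difference test (1- vs 2-factor EFA).

    Returns (reject_1factor, delta_chi2, delta_df, p_value); a 2-factor
    chi-square above the 1-factor one clamps the difference at zero.
    """
    ddf = fit1.df - fit2.df
    if ddf <= 0:
        raise ValueError("models are not nested in the expected order")
    delta = max(fit1.chi2 - fit2.chi2, 0.0)
    p_value = float(stats.chi2.sf(delta, ddf))
    return p_value < alpha, delta, ddf, p_value


def rmsea(chi2: float, df: int, n: int) -> float:
    """Root mean square error of approximation."""
    if df < 1:
        raise ValueError("RMSEA undefined for df < 1")
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))


def gfi_agfi(S: np.ndarray, Sigma: np.ndarray, df: int, p: int) -> tuple[float, float]:
    """ML goodness-of-fit index and its degrees-of-freedom adjustment."""
    W = np.linalg.solve(Sigma, S)
    resid = W - np.eye(p)
    gfi = 1.0 - float(np.trace(resid @ resid)) / float(np.trace(W @ W))
    if df <= 0:
        return gfi, np.nan
    agfi = 1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi)
    return gfi, agfi


def efa_fit_stats(C: np.ndarray, model: FactorModel, n: int) -> FitStats:
    """ML fit statistics of an EFA model evaluated at its solution."""
    p = C.shape[0]
    F = ml_discrepancy(C, model.implied_matrix)
    chi2, df, p_value = efa_chi2(F, n, p, model.k)
    rm = rmsea(chi2, df, n) if df >= 1 else np.nan
    gfi, agfi = gfi_agfi(C, model.implied_matrix, df, p)
    return FitStats(
        discrepancy=F,
        chi2=chi2,
        df=df,
        p_value=p_value,
        rmsea=rm,
        gfi=gfi,
        agfi=agfi,
        converged=model.converged,
        heywood=model.heywood,
    )


def _cfa_objective_grad(x: np.ndarray, S: np.ndarray, p: int):
    lam = x[:p]
    psi = x[p:]
    Sigma = np.outer(lam, lam) + np.diag(psi)
    sign, logdet_m = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf, np.zeros_like(x)
    Sigma_inv = np.linalg.inv(Sigma)
    _, logdet_s = np.linalg.slogdet(S)
    F = logdet_m - logdet_s + float(np.trace(Sigma_inv @ S)) - p
    # dF/dSigma = Sigma^-1 (Sigma - S) Sigma^-1
    G = Sigma_inv @ (Sigma - S) @ Sigma_inv
    grad = np.concatenate((2.0 * G @ lam, np.diag(G)))
    return F, grad


def cfa_1factor(
    C: np.ndarray, n: int, rules: DecisionRules = DecisionRules()
) -> tuple[FactorModel, FitStats]:
    """One-factor confirmatory ML fit to a correlation matrix.

    Latent variance is fixed at 1; the p loadings and p uniquenesses are
    free.  chi2 = (n-1) F on df = p(p+1)/2 - 2p.  Non-PD input raises, as
    the paper-style pipeline records such datasets missing.
    """
    C = np.asarray(C, dtype=float)
    p = C.shape[0]
    if np.linalg.eigvalsh(C).min() <= 0:
        raise np.linalg.LinAlgError("correlation matrix is not positive definite")
    start = minres_efa(C, 1)
    lam0 = start.loadings[:, 0]
    psi0 = np.clip(1.0 - lam0**2, _UNIQUENESS_FLOOR, 1.0)
    res = optimize.minimize(
        _cfa_objective_grad,
        np.concatenate((lam0, psi0)),
        args=(C, p),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [(_UNIQUENESS_FLOOR, None)] * p,
        options={"maxfun": 10_000, "ftol": 1e-12, "gtol": 1e-8},
    )
    lam = res.x[:p]
    if lam.sum() < 0:
        lam = -lam
    psi = res.x[p:]
    heywood = bool(np.any(psi <= _UNIQUENESS_FLOOR * (1 + 1e-9)))
    model = FactorModel(
        loadings=lam[:, None],
        uniquenesses=psi,
        k=1,
        method="ml",
        converged=bool(res.success),
        heywood=heywood,
    )
    Sigma = model.implied_matrix
    F = ml_discrepancy(C, Sigma)
    df = p * (p + 1) // 2 - 2 * p
    chi2 = (n - 1) * F
    p_value = float(stats.chi2.sf(chi2, df))
    gfi, agfi = gfi_agfi(C, Sigma, df, p)
    fit = FitStats(
        discrepancy=F,
        chi2=chi2,
        df=df,
        p_value=p_value,
        rmsea=rmsea(chi2, df, n),
        gfi=gfi,
        agfi=agfi,
        converged=model.converged,
        heywood=heywood,
    )
    return model, fit
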