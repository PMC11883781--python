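"""Exploratory factor analysis: ML extraction with oblique oblimin rotation.

Maximum-likelihood extraction profiles the loadings out of the normal-
theory discrepancy: for fixed uniquenesses Psi the optimal loadings come
from the leading eigenvectors of Psi^-1/2 R Psi^-1/2, leaving a smooth
objective in Psi alone (Lawley-Maxwell).  Rotation uses the gradient-
projection algorithm for oblique rotation with the oblimin (quartimin)
criterion.  Factors are ordered by explained variance and sign-aligned so
each column's loading sum is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "EfaResult",
    "ExploratoryFactorModel",
    "fit_efa",
    "oblimin_rotate",
    "parallel_analysis",
    "tucker_congruence",
]

_PSI_FLOOR = 5e-3


@dataclass
class EfaResult:
    loadings: pd.DataFrame  # rotated pattern matrix
    factor_corr: np.ndarray
    proportions: np.ndarray  # proportion of total variance per factor
    uniquenesses: np.ndarray
    heywood: bool
    converged: bool
    n_used: int


def _ml_extract(R: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, bool]:
    """Unrotated ML loadings and uniquenesses from a correlation matrix."""
    p = R.shape[0]
    if ((p - k) ** 2 - (p + k)) < 0:
        raise ValueError(
            f"{k} factors cannot be extracted from {p} variables "
            "(negative degrees of freedom)"
        )
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    psi0 = np.clip(1.0 - smc, _PSI_FLOOR, 1.0)

    def objective(logpsi):
        psi = np.exp(logpsi)
        d = 1.0 / np.sqrt(psi)
        Rs = R * np.outer(d, d)
        vals = np.linalg.eigvalsh(Rs)[::-1]
        tail = vals[k:]
        return float(np.sum(tail - np.log(np.maximum(tail, 1e-12)) - 1.0))

    res = optimize.minimize(
        objective,
        np.log(psi0),
        method="L-BFGS-B",
        bounds=[(np.log(_PSI_FLOOR), 0.0)] * p,
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    psi = np.exp(res.x)
    d = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(d, d)
    vals, vecs = np.linalg.eigh(Rs)
    order = np.argsort(vals)[::-1][:k]
    gam = np.maximum(vals[order] - 1.0, 0.0)
    lam = np.sqrt(psi)[:, None] * vecs[:, order] * np.sqrt(gam)[None, :]
    return lam, psi, bool(res.success)


def oblimin_rotate(
    A: np.ndarray, gamma: float = 0.0, max_iter: int = 1000, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique gradient-projection rotation with the oblimin criterion.

    ``gamma = 0`` is quartimin (the usual "direct oblimin" default).
    Returns the rotated pattern matrix and the factor correlation matrix.
    """
    p, k = A.shape
    if k == 1:
        return A.copy(), np.eye(1)
    N = np.ones((k, k)) - np.eye(k)
    C = np.eye(p) - gamma * np.ones((p, p)) / p

    def criterion(L):
        L2 = L**2
        M = C @ L2 @ N
        return float(np.sum(L2 * M)) / 4.0, L * M

    T = np.eye(k)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = criterion(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T * np.sum(T * G, axis=0)[None, :]
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            Tt = X / np.sqrt(np.sum(X**2, axis=0))[None, :]
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = criterion(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi


def parallel_analysis(
    X: np.ndarray | pd.DataFrame, n_iter: int = 50, quantile: float = 0.95, seed: int = 0
) -> int:
    """Horn's parallel analysis: factors whose observed correlation-matrix
    eigenvalues exceed the chosen quantile of eigenvalues from random
    normal data of the same shape.  A seeded helper for choosing k; the
    pipeline never auto-selects with it."""
    X = np.asarray(pd.DataFrame(X).dropna(), dtype=np.float64)
    n, p = X.shape
    obs = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((n_iter, p))
    for i in range(n_iter):
        Z = rng.standard_normal((n, p))
        sims[i] = np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False))[::-1]
    thresh = np.quantile(sims, quantile, axis=0)
    return int(np.sum(obs > thresh))


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Tucker congruence coefficients between columns of A and B, after
    matching columns greedily by absolute congruence (sign-invariant)."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    k = A.shape[1]
    raw = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            raw[i, j] = A[:, i] @ B[:, j] / np.sqrt(
                (A[:, i] @ A[:, i]) * (B[:, j] @ B[:, j])
            )
    out = np.empty(k)
    used: set[int] = set()
    for i in range(k):
        j = int(np.argmax([abs(raw[i, j]) if j not in used else -1 for j in range(k)]))
        used.add(j)
        out[i] = abs(raw[i, j])
    return out


class ExploratoryFactorModel:
    """ML exploratory factor analysis on the complete-case correlation matrix.

    Parameters: ``n_factors`` (user-chosen; see :func:`parallel_analysis`
    for a seeded helper), ``rotation`` in {"oblimin", "none"}.  Fitted
    attributes: ``loadings_`` (rotated pattern, DataFrame), ``factor_corr_``,
    ``proportions_``, ``uniquenesses_``, ``heywood_`` (flag, never a crash),
    ``n_used_``, ``result_``.
    """

    def __init__(self, n_factors: int = 2, rotation: str = "oblimin", seed: int = 0):
        self.n_factors = n_factors
        self.rotation = rotation
        self.seed = seed

    def get_params(self, deep: bool = True):
        return {"n_factors": self.n_factors, "rotation": self.rotation, "seed": self.seed}

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X) -> "ExploratoryFactorModel":
        df = X.df if hasattr(X, "df") else pd.DataFrame(X)
        df = df.select_dtypes(include=[np.number]) if not isinstance(X, pd.DataFrame) else df
        data = df.dropna()
        names = list(data.columns)
        if self.n_factors >= len(names):
            raise ValueError("n_factors must be smaller than the number of variables")
        R = np.corrcoef(data.to_numpy(dtype=np.float64), rowvar=False)
        lam, psi, ok = _ml_extract(R, self.n_factors)
        heywood = bool((psi <= _PSI_FLOOR * (1 + 1e-6)).any())

        if self.rotation == "oblimin":
            L, Phi = oblimin_rotate(lam)
        elif self.rotation == "none":
            L, Phi = lam, np.eye(self.n_factors)
        else:
            raise ValueError(f"unknown rotation {self.rotation!r}")

        # deterministic column order (explained variance) and sign
        ssq = (L**2).sum(axis=0)
        order = np.argsort(ssq)[::-1]
        L = L[:, order]
        Phi = Phi[np.ix_(order, order)]
        signs = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
        L = L * signs
        Phi = Phi * np.outer(signs, signs)
        ssq = (L**2).sum(axis=0)

        cols = [f"F{i + 1}" for i in range(self.n_factors)]
        self.loadings_ = pd.DataFrame(L, index=names, columns=cols)
        self.factor_corr_ = Phi
        self.proportions_ = ssq / len(names)
        self.uniquenesses_ = psi
        self.heywood_ = heywood
        self.n_used_ = len(data)
        self.result_ = EfaResult(
            loadings=self.loadings_,
            factor_corr=Phi,
            proportions=self.proportions_,
            uniquenesses=psi,
            heywood=heywood,
            converged=ok,
            n_used=len(data),
        )
        return self


def fit_efa(table, n_factors: int, rotation: str = "oblimin", seed: int = 0, columns=None):
    """Functional wrapper: returns (loadings, factor_correlation, proportions)."""
    df = table.df if hasattr(table, "df") else table
    if columns is None and hasattr(table, "analysis_cols"):
        columns = table.analysis_cols
    if columns is not None:
        df = df[list(columns)]
    model = ExploratoryFactorModel(n_factors=n_factors, rotation=rotation, seed=seed).fit(df)
    return model.loadings_, model.factor_corr_, model.proportions_
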