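import numpy as np
import pandas as pd
import pytest

import latentgen as lg
from latentgen.genotype_io import GRM


def dense_reml_loglik(A: np.ndarray, y: np.ndarray, sg: float, se: float) -> float:
    """Independent dense evaluation of the restricted log-likelihood
    -0.5 [log|V| + log|X'V^-1 X| + y'Py] with V = sg A + se I, X = 1."""
    n = len(y)
    V = sg * A + se * np.eye(n)
    sign, ld = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    X = np.ones((n, 1))
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return float(-0.5 * (ld + np.log(XtViX[0, 0]) + y @ P @ y))


def make_synthetic_grm(n: int, var_offdiag: float, seed: int) -> GRM:
    """Near-identity GRM with off-diagonal variance var_offdiag (PD for
    n * var_offdiag well below ~0.25)."""
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n, n)) * np.sqrt(var_offdiag)
    W = (W + W.T) / np.sqrt(2.0)
    np.fill_diagonal(W, 0.0)
    A = np.eye(n) + W
    ids = pd.DataFrame({"fid": [f"f{i}" for i in range(n)], "iid": [f"i{i}" for i in range(n)]})
    return GRM(matrix=A, pair_counts=np.full((n, n), 1000.0), ids=ids, m_used=1000)


def draw_bivariate_from_grm(grm: GRM, h2: float, rg: float, rp: float, rng):
    """Exact draw of two standardized traits from the bivariate GREML model."""
    lam, U = grm.eigen()
    e = 1.0 - h2
    re = (rp - rg * h2) / e
    G = np.array([[h2, rg * h2], [rg * h2, h2]])
    E = np.array([[e, re * e], [re * e, e]])
    C = lam[:, None, None] * G[None] + E[None]
    L = np.linalg.cholesky(C)
    z = rng.standard_normal((grm.n, 2, 1))
    Yt = (L @ z)[:, :, 0]
    return U @ Yt[:, 0], U @ Yt[:, 1]


@pytest.fixture(scope="session")
def two_factor_table():
    """Complete continuous six-indicator dataset from the two-factor model
    (loadings .75/.65/.60 and .70/.65/.60, factor correlation 0.5)."""
    params = lg.GenerativeParams(
        n=20000, m=10, h2_per_latent=0.0, latent_structure="two_factor",
        taf_binary=False, missing_rate=0.0, seed=42,
    )
    sim = lg.simulate_dataset(params)
    return lg.residualize(sim.table), sim


@pytest.fixture(scope="session")
def residual_table():
    """Complete dataset generated from the bifactor (residual) structure."""
    params = lg.GenerativeParams(
        n=20000, m=10, h2_per_latent=0.0, latent_structure="residual",
        taf_binary=False, missing_rate=0.0, seed=7,
    )
    sim = lg.simulate_dataset(params)
    return lg.residualize(sim.table), sim


@pytest.fixture(scope="session")
def small_geno():
    return lg.simulate_genotypes(600, 1500, seed=11)
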