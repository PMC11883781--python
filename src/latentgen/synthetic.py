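"""Generator for genotypes and item-level phenotypes with known ground truth.

The generator emulates a mental-health questionnaire + genotyping study:
biallelic SNP genotypes in Hardy-Weinberg proportions, correlated latent
factors (eating-disorder and suicidal-ideation susceptibility, or a general
factor plus domain-specific factors) with configurable SNP heritability and
genetic correlations, continuous symptom indicators that sum into AN/BN/BED
scores, binary suicidality (TAF) items produced by liability thresholding,
optional depression/anxiety sum scores, covariates (age, sex, batch, 10
ancestry PCs computed from the simulated genotypes) and MCAR missingness.

SNPs are simulated without linkage disequilibrium: the quantities under
test downstream (variance components, factor recoveries) are unbiased under
this design and it keeps the generator desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .phenotypes import PhenotypeTable

__all__ = [
    "GenerativeParams",
    "LatentTruth",
    "SimulatedData",
    "simulate_genotypes",
    "simulate_latent_structure",
    "generate_observed_items",
    "inject_missingness",
    "simulate_dataset",
    "standardize_dosages",
    "structure_defaults",
]

ED_SCORES = ["AN_score", "BN_score", "BED_score"]
TAF_ITEMS = ["TAF1", "TAF2", "TAF3"]
PSYCH_SCORES = ["PHQ8", "GAD7"]

_ITEMS_PER_SCORE = {"AN_score": 5, "BN_score": 5, "BED_score": 5, "PHQ8": 8, "GAD7": 7}


def _corr_matrix(value, k: int, name: str) -> np.ndarray:
    """Expand a scalar off-diagonal correlation to k x k, or validate a matrix."""
    if np.isscalar(value):
        mat = np.full((k, k), float(value))
        np.fill_diagonal(mat, 1.0)
    else:
        mat = np.asarray(value, dtype=np.float64)
    if mat.shape != (k, k):
        raise ValueError(f"{name} must be {k}x{k}")
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(mat), 1.0):
        raise ValueError(f"{name} must have a unit diagonal")
    if np.linalg.eigvalsh(mat).min() < -1e-8:
        raise ValueError(f"{name} must be positive semidefinite")
    return mat


def structure_defaults(structure: str, with_psychopathology: bool = False):
    """Default loadings and correlation targets per latent structure.

    Returns ``(indicator_names, latent_names, loadings, factor_corr,
    genetic_corr)``.  The bifactor ("residual") loadings are deliberately
    heterogeneous so that two-factor approximations of bifactor-generated
    data are distinguishable from the generating model; specific and general
    factors are phenotypically orthogonal, with a negative genetic
    correlation between the two specific factors.
    """
    indicators = ED_SCORES + TAF_ITEMS
    if structure in ("two_factor", "hierarchical"):
        latents = ["ED", "SI"]
        lam = np.zeros((6, 2))
        lam[0:3, 0] = [0.75, 0.65, 0.60]
        lam[3:6, 1] = [0.70, 0.65, 0.60]
        phi = _corr_matrix(0.5, 2, "factor_corr")
        gcorr = _corr_matrix(0.71, 2, "genetic_corr")
    elif structure == "residual":
        latents = ["general", "ED_specific", "SI_specific"]
        lam = np.zeros((6, 3))
        lam[:, 0] = [0.65, 0.55, 0.45, 0.70, 0.60, 0.50]
        lam[0:3, 1] = [0.45, 0.55, 0.50]
        lam[3:6, 2] = [0.50, 0.45, 0.55]
        phi = np.eye(3)
        gcorr = np.eye(3)
        gcorr[1, 2] = gcorr[2, 1] = -0.40
    elif structure == "four_factor":
        latents = ["restricting", "purging", "bingeing", "SI"]
        lam = np.zeros((6, 4))
        lam[0, 0] = lam[1, 1] = lam[2, 2] = 0.80
        lam[3:6, 3] = [0.70, 0.65, 0.60]
        phi = np.eye(4)
        for i in range(3):
            for j in range(i + 1, 3):
                phi[i, j] = phi[j, i] = 0.65
            phi[i, 3] = phi[3, i] = 0.50
        gcorr = np.eye(4)
        for i in range(3):
            for j in range(i + 1, 3):
                gcorr[i, j] = gcorr[j, i] = 0.875
            gcorr[i, 3] = gcorr[3, i] = 0.71
    else:
        raise ValueError(f"unknown latent structure {structure!r}")

    if with_psychopathology:
        indicators = indicators + PSYCH_SCORES
        latents = latents + ["distress"]
        k = lam.shape[1]
        lam = np.pad(lam, ((0, 2), (0, 1)))
        lam[-2, -1] = 0.75
        lam[-1, -1] = 0.70
        phi = np.pad(phi, ((0, 1), (0, 1)))
        phi[-1, -1] = 1.0
        gcorr = np.pad(gcorr, ((0, 1), (0, 1)))
        gcorr[-1, -1] = 1.0
        # the distress factor is only modestly related to the ED/SI factors
        for j in range(k):
            phi[j, -1] = phi[-1, j] = 0.30 if structure != "residual" or j == 0 else 0.0
            gcorr[j, -1] = gcorr[-1, j] = 0.30 if structure != "residual" or j == 0 else 0.0
    return indicators, latents, lam, phi, gcorr


@dataclass
class GenerativeParams:
    """Conditions of a simulated study.

    Defaults mirror the study being emulated where it states them (sample
    size 20,810; mean SNP heritability 0.09; genetic correlation 0.71
    between susceptibility factors; phenotypic factor correlation 0.5;
    female fraction 0.71; age 49.3 +/- 17.56) and otherwise use desk-scale
    values documented in the methods note.
    """

    n: int = 20810
    m: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_fraction: float = 1.0
    latent_structure: str = "two_factor"
    with_psychopathology: bool = False
    true_loadings: np.ndarray | None = None
    factor_corr: np.ndarray | float | None = None
    h2_per_latent: np.ndarray | float = 0.09
    genetic_corr: np.ndarray | float | None = None
    taf_prevalence: tuple[float, float, float] = (0.45, 0.30, 0.25)
    taf_binary: bool = True
    covariate_betas: dict[str, float] = field(
        default_factory=lambda: {"age": 0.10, "sex": 0.15, "batch": 0.05}
    )
    missing_rate: float = 0.2
    seed: int = 0

    def resolved(self):
        """Indicator/latent names, loadings and correlation matrices in use."""
        inds, lats, lam, phi, gcorr = structure_defaults(
            self.latent_structure, self.with_psychopathology
        )
        if self.true_loadings is not None:
            lam = np.asarray(self.true_loadings, dtype=np.float64)
            if lam.shape != (len(inds), len(lats)):
                raise ValueError(
                    f"true_loadings must be {len(inds)}x{len(lats)} for "
                    f"structure {self.latent_structure!r}"
                )
        k = len(lats)
        if self.factor_corr is not None:
            phi = _corr_matrix(self.factor_corr, k, "factor_corr")
        if self.genetic_corr is not None:
            gcorr = _corr_matrix(self.genetic_corr, k, "genetic_corr")
        h2 = np.asarray(
            np.broadcast_to(np.asarray(self.h2_per_latent, dtype=np.float64), k)
        ).copy()
        if (h2 < 0).any() or (h2 > 1).any():
            raise ValueError("h2_per_latent must lie in [0, 1]")
        return inds, lats, lam, phi, gcorr, h2


@dataclass
class LatentTruth:
    """Ground truth behind a simulated dataset (for recovery tests)."""

    latent_names: list[str]
    genetic_values: np.ndarray  # n x k, empirical variance == h2 per latent
    env_values: np.ndarray  # n x k
    factor_values: np.ndarray  # n x k, total latent scores
    causal_effects: np.ndarray  # m x k, zero rows for non-causal SNPs
    h2_per_latent: np.ndarray


@dataclass
class SimulatedData:
    geno: GenotypeMatrix | None
    table: PhenotypeTable
    truth: LatentTruth
    params: GenerativeParams


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n: int, m: int, maf_range: tuple[float, float] = (0.05, 0.5), seed: int = 0
) -> GenotypeMatrix:
    """Independent biallelic SNPs: p ~ U(maf_range), dosage ~ Binomial(2, p).

    Monomorphic columns are redrawn so every SNP is polymorphic in-sample.
    """
    low, high = maf_range
    if not (0.0 < low <= high <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 individuals and m >= 1 SNPs")
    rng = np.random.default_rng(seed)
    p = rng.uniform(low, high, size=m)

    def draw(prob, cols):
        # Binomial(2, p) as the sum of two Bernoulli draws (fast at scale)
        pf = prob.astype(np.float32)
        u1 = rng.random((n, cols), dtype=np.float32)
        u2 = rng.random((n, cols), dtype=np.float32)
        return (u1 < pf).astype(np.int8) + (u2 < pf).astype(np.int8)

    dosages = draw(p[None, :], m)
    for _ in range(1000):
        mono = (dosages == dosages[0]).all(axis=0)
        if not mono.any():
            break
        k = int(mono.sum())
        p[mono] = rng.uniform(low, high, size=k)
        dosages[:, mono] = draw(p[None, mono], k)
    else:  # pragma: no cover - astronomically unlikely with valid maf_range
        raise RuntimeError("failed to draw polymorphic SNPs")

    snp_meta = pd.DataFrame(
        {
            "chrom": np.repeat("1", m),
            "snp_id": [f"snp{i + 1}" for i in range(m)],
            "pos": np.arange(1, m + 1, dtype=np.int64),
            "a1": np.repeat("A", m),
            "a2": np.repeat("C", m),
        }
    )
    sample_ids = pd.DataFrame(
        {"fid": [f"F{i + 1}" for i in range(n)], "iid": [f"I{i + 1}" for i in range(n)]}
    )
    return GenotypeMatrix(dosages=dosages, snp_meta=snp_meta, sample_ids=sample_ids)


def standardize_dosages(geno: GenotypeMatrix, dtype=np.float32) -> np.ndarray:
    """Center/scale dosages to (x - 2p)/sqrt(2p(1-p)) with sample frequencies.

    Missing calls are set to 0 (the per-SNP mean) after centering.
    """
    X = geno.dosages.astype(dtype)
    miss = geno.missing_mask()
    if miss.any():
        X[miss] = np.nan
        p = np.nanmean(X, axis=0) / 2.0
    else:
        p = X.mean(axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    Z = (X - 2.0 * p) / denom
    if miss.any():
        Z[miss] = 0.0
    return Z.astype(dtype, copy=False)


# ---------------------------------------------------------------------------
# latent structure
# ---------------------------------------------------------------------------

def simulate_latent_structure(
    geno: GenotypeMatrix | None, params: GenerativeParams, seed: int | None = None
) -> LatentTruth:
    """Draw correlated genetic and environmental latent components.

    Per-SNP causal effects are drawn from a multivariate normal across
    latents with correlation ``genetic_corr``; each latent's genetic value
    is the standardized-genotype score rescaled to have empirical variance
    exactly ``h2_per_latent``.  Environmental values are multivariate
    normal with the covariance needed to reach the target total factor
    correlation, rescaled so each latent's total variance is 1.
    """
    _, lats, _, phi, gcorr, h2 = params.resolved()
    k = len(lats)
    rng = np.random.default_rng(params.seed if seed is None else seed)

    if geno is None:
        if (h2 > 0).any():
            raise ValueError("genotypes are required when any h2_per_latent > 0")
        n, m = params.n, 0
    else:
        n, m = geno.n_samples, geno.n_snps

    genetic = np.zeros((n, k))
    effects = np.zeros((m, k))
    if (h2 > 0).any():
        m_causal = max(1, int(round(params.causal_fraction * m)))
        causal_idx = rng.choice(m, size=m_causal, replace=False)
        L = np.linalg.cholesky(gcorr + 1e-10 * np.eye(k))
        beta = rng.standard_normal((m_causal, k)) @ L.T / np.sqrt(m_causal)
        Z = standardize_dosages(geno)[:, causal_idx].astype(np.float64)
        g_raw = Z @ beta
        for j in range(k):
            if h2[j] <= 0:
                continue
            scale = np.sqrt(h2[j] / g_raw[:, j].var())
            genetic[:, j] = g_raw[:, j] * scale
            effects[causal_idx, j] = beta[:, j] * scale

    # environmental covariance required to hit the target factor correlation:
    # phi_lm = rG_lm sqrt(h2_l h2_m) + cov_e(l, m)
    e_var = 1.0 - h2
    cov_e = np.outer(np.sqrt(e_var), np.sqrt(e_var)).copy()
    sq = np.sqrt(h2)
    for l in range(k):
        for mm in range(l + 1, k):
            c = phi[l, mm] - gcorr[l, mm] * sq[l] * sq[mm]
            cov_e[l, mm] = cov_e[mm, l] = c
    np.fill_diagonal(cov_e, e_var)
    evals = np.linalg.eigvalsh(cov_e)
    if evals.min() < -1e-8:
        raise ValueError(
            "target factor_corr is unreachable: implied environmental "
            "covariance is not positive semidefinite"
        )
    Le = np.linalg.cholesky(cov_e + 1e-10 * np.eye(k))
    env = rng.standard_normal((n, k)) @ Le.T
    for j in range(k):
        if e_var[j] > 0:
            env[:, j] *= np.sqrt(e_var[j] / env[:, j].var())
        else:
            env[:, j] = 0.0

    return LatentTruth(
        latent_names=list(lats),
        genetic_values=genetic,
        env_values=env,
        factor_values=genetic + env,
        causal_effects=effects,
        h2_per_latent=h2,
    )


# ---------------------------------------------------------------------------
# observed items
# ---------------------------------------------------------------------------

def _genotype_pcs(geno: GenotypeMatrix, n_pcs: int = 10, seed: int = 0) -> np.ndarray:
    from sklearn.utils.extmath import randomized_svd

    Z = standardize_dosages(geno).astype(np.float64)
    U, S, _ = randomized_svd(Z, n_components=n_pcs, random_state=seed)
    pcs = U * S
    sd = pcs.std(axis=0)
    sd[sd == 0] = 1.0
    return pcs / sd


def generate_observed_items(
    truth: LatentTruth,
    params: GenerativeParams,
    geno: GenotypeMatrix | None = None,
    seed: int | None = None,
) -> PhenotypeTable:
    """Produce the observed phenotype table from the latent ground truth.

    Continuous indicators follow y = Lambda f + e with residual variance
    1 - (row communality); each AN/BN/BED (and PHQ8/GAD7) indicator is also
    decomposed into item columns that sum exactly to the score.  TAF items
    are dichotomized at the quantile implied by ``taf_prevalence`` when
    ``taf_binary`` is set.  Covariate effects (age, sex, batch) are injected
    additively on the standardized-covariate scale; ancestry PCs are the
    top 10 PCs of the standardized genotype matrix.
    """
    inds, lats, lam, phi, _, _ = params.resolved()
    if lam.shape[1] != truth.factor_values.shape[1]:
        raise ValueError("loadings pattern not conformable with latent count")
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    n = truth.factor_values.shape[0]

    communality = np.einsum("pk,kl,pl->p", lam, phi, lam)
    if (communality > 1.0 + 1e-12).any():
        bad = [inds[i] for i in np.where(communality > 1.0 + 1e-12)[0]]
        raise ValueError(f"communality exceeds 1 for indicators: {bad}")
    resid_sd = np.sqrt(np.maximum(1.0 - communality, 0.0))
    Y = truth.factor_values @ lam.T + rng.standard_normal((n, len(inds))) * resid_sd

    # covariates
    age = rng.normal(49.3, 17.56, size=n)
    sex = (rng.uniform(size=n) < 0.71).astype(float)  # 1 = female
    batch = (rng.uniform(size=n) < 0.5).astype(float)
    if geno is not None:
        pcs = _genotype_pcs(geno, 10, seed=int(rng.integers(2**31 - 1)))
    else:
        pcs = rng.standard_normal((n, 10))
    cov_std = {
        "age": (age - age.mean()) / age.std(),
        "sex": (sex - sex.mean()) / max(sex.std(), 1e-12),
        "batch": (batch - batch.mean()) / max(batch.std(), 1e-12),
    }
    for name, beta in (params.covariate_betas or {}).items():
        Y += beta * cov_std[name][:, None]

    df = pd.DataFrame(
        {
            "FID": [f"F{i + 1}" for i in range(n)],
            "IID": [f"I{i + 1}" for i in range(n)],
        }
    )
    item_cols: list[str] = []
    score_cols: list[str] = []
    for j, name in enumerate(inds):
        col = Y[:, j]
        if name in TAF_ITEMS:
            continue
        if name in _ITEMS_PER_SCORE:
            k_items = _ITEMS_PER_SCORE[name]
            stem = name.replace("_score", "")
            u = rng.normal(0.0, 0.3 * col.std(), size=(n, k_items))
            u -= u.mean(axis=1, keepdims=True)
            items = col[:, None] / k_items + u
            for t in range(k_items):
                iname = f"{stem}_item{t + 1}"
                df[iname] = items[:, t]
                item_cols.append(iname)
        df[name] = col
        score_cols.append(name)

    taf_cols = []
    for t, name in enumerate(TAF_ITEMS):
        j = inds.index(name)
        liab = Y[:, j]
        if params.taf_binary:
            thresh = np.quantile(liab, 1.0 - params.taf_prevalence[t])
            df[name] = (liab > thresh).astype(float)
        else:
            df[name] = liab
        taf_cols.append(name)

    df["age"] = age
    df["sex"] = sex
    df["batch"] = batch
    for c in range(10):
        df[f"PC{c + 1}"] = pcs[:, c]
    covariate_cols = ["age", "sex", "batch"] + [f"PC{c + 1}" for c in range(10)]

    return PhenotypeTable(
        df=df,
        item_cols=item_cols,
        score_cols=score_cols,
        taf_cols=taf_cols,
        covariate_cols=covariate_cols,
    )


def inject_missingness(
    table: PhenotypeTable,
    rate: float,
    seed: int = 0,
    columns: list[str] | None = None,
) -> PhenotypeTable:
    """Apply an MCAR mask to item/analysis columns (never IDs or covariates)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    if columns is None:
        columns = table.analysis_cols
    forbidden = set(["FID", "IID"] + list(table.covariate_cols))
    bad = [c for c in columns if c in forbidden]
    if bad:
        raise ValueError(f"refusing to mask ID/covariate columns: {bad}")
    out = table.copy()
    if rate == 0.0 or not columns:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.uniform(size=(table.n, len(columns))) < rate
    block = out.df[columns].to_numpy(dtype=np.float64)
    block[mask] = np.nan
    out.df[columns] = block
    return out


def simulate_dataset(params: GenerativeParams) -> SimulatedData:
    """End-to-end simulation: genotypes, latent truth, items, missingness.

    All randomness flows from ``params.seed`` through per-stage substreams.
    Missingness is applied at the questionnaire-score level (a missing score
    also blanks its item columns, so score == item row-sum holds wherever
    both are observed).
    """
    ss = np.random.SeedSequence(params.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]
    _, _, _, _, _, h2 = params.resolved()
    geno = None
    if (h2 > 0).any():
        geno = simulate_genotypes(params.n, params.m, params.maf_range, seed=seeds[0])
    truth = simulate_latent_structure(geno, params, seed=seeds[1])
    table = generate_observed_items(truth, params, geno=geno, seed=seeds[2])
    table = inject_missingness(table, params.missing_rate, seed=seeds[3])
    if params.missing_rate > 0:
        # propagate score-level missingness to the underlying items
        df = table.df
        for score in table.score_cols:
            stem = score.replace("_score", "")
            items = [c for c in table.item_cols if c.startswith(f"{stem}_item")]
            if items:
                df.loc[df[score].isna(), items] = np.nan
    return SimulatedData(geno=geno, table=table, truth=truth, params=params)
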