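"""Per-SNP additive association of (factor-score) phenotypes.

Each SNP is tested by OLS of the phenotype on the A1 dosage with an
intercept and a two-sided t test; no covariates enter the per-SNP model
because phenotypes arrive residualized (a covariate matrix can be supplied
for standalone use).  Missing dosages are mean-imputed per SNP by default
(matching the GRM convention) or dropped per SNP with ``impute="drop"``.
The output table mirrors the PLINK 2 ``--glm`` additive layout
(CHROM, POS, ID, A1, A1_FREQ, BETA, SE, T_STAT, P, N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix

__all__ = ["GwasResult", "run_gwas", "genomic_inflation"]

# median of the chi-square(1) distribution
_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class GwasResult:
    """Summary statistics table plus genome-wide diagnostics."""

    table: pd.DataFrame
    skipped: pd.DataFrame
    n_used: int

    @property
    def lambda_gc(self) -> float:
        return genomic_inflation(self)

    def qq_data(self) -> pd.DataFrame:
        """Expected vs observed -log10 p for a QQ plot."""
        p = np.sort(self.table["P"].to_numpy())
        k = p.size
        exp = (np.arange(1, k + 1) - 0.5) / k
        return pd.DataFrame(
            {"expected_neglog10": -np.log10(exp), "observed_neglog10": -np.log10(p)}
        )


def _align_phenotype(scores, geno: GenotypeMatrix, latent: str | None):
    """Intersect phenotype rows with genotype samples, preserving geno order."""
    if hasattr(scores, "scores"):  # FactorScores
        df = scores.scores
    elif isinstance(scores, pd.DataFrame):
        df = scores
    else:
        y = np.asarray(scores, dtype=np.float64).ravel()
        if y.size != geno.n_samples:
            raise ValueError("bare phenotype array must align with genotype samples")
        return y
    if latent is None:
        value_cols = [c for c in df.columns if c not in ("FID", "IID")]
        if len(value_cols) != 1:
            raise ValueError(
                f"specify `latent`; candidates are {value_cols}"
            )
        latent = value_cols[0]
    if "FID" not in df.columns:
        raise ValueError("phenotype table must carry FID/IID columns")
    key = geno.sample_ids.rename(columns={"fid": "FID", "iid": "IID"})
    merged = key.merge(df[["FID", "IID", latent]], on=["FID", "IID"], how="left")
    y = merged[latent].to_numpy(dtype=np.float64)
    if np.isnan(y).all():
        raise ValueError("zero overlapping ids between phenotype and genotypes")
    return y


def run_gwas(
    scores,
    geno: GenotypeMatrix,
    latent: str | None = None,
    impute: str = "mean",
) -> GwasResult:
    """Additive per-SNP scan of a phenotype over a genotype matrix.

    ``scores`` may be a FactorScores object, a FID/IID-keyed DataFrame or a
    bare array aligned with the genotype samples.
    """
    if impute not in ("mean", "drop"):
        raise ValueError("impute must be 'mean' or 'drop'")
    y = _align_phenotype(scores, geno, latent)
    keep = ~np.isnan(y)
    y = y[keep]
    n = y.size
    if n < 3:
        raise ValueError("fewer than 3 individuals with phenotype and genotypes")

    X = geno.dosages[keep].astype(np.float64)
    X[geno.missing_mask()[keep]] = np.nan
    obs = ~np.isnan(X)
    n_j = obs.sum(axis=0).astype(np.float64)
    freq = np.nansum(X, axis=0) / (2.0 * np.maximum(n_j, 1.0))

    if impute == "mean":
        col_mean = 2.0 * freq
        Xf = np.where(obs, X, col_mean)
        W = np.ones_like(Xf, dtype=bool)
        n_eff = np.full(X.shape[1], float(n))
    else:
        Xf = np.where(obs, X, 0.0)
        W = obs
        n_eff = n_j

    yw = y[:, None] * W
    Sx = (Xf * W).sum(axis=0)
    Sy = yw.sum(axis=0)
    Sxx = (Xf * Xf * W).sum(axis=0)
    Syy = (y[:, None] ** 2 * W).sum(axis=0)
    Sxy = (Xf * yw).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        vx = Sxx - Sx * Sx / n_eff
        vy = Syy - Sy * Sy / n_eff
        cxy = Sxy - Sx * Sy / n_eff
        beta = cxy / vx
        sse = np.maximum(vy - beta * cxy, 0.0)
        dof = n_eff - 2.0
        se = np.sqrt(sse / np.maximum(dof, 1.0) / vx)
        t = beta / se

    poly = (vx > 1e-12) & (n_eff >= 3)
    reasons = np.where(vx <= 1e-12, "monomorphic", "insufficient_n")
    skipped = pd.DataFrame(
        {"ID": geno.snp_meta["snp_id"][~poly], "reason": reasons[~poly]}
    )

    meta = geno.snp_meta[poly]
    tt = t[poly]
    dd = dof[poly]
    pvals = 2.0 * stats.t.sf(np.abs(tt), df=dd)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "CHROM": meta["chrom"].to_numpy(),
            "POS": meta["pos"].to_numpy(),
            "ID": meta["snp_id"].to_numpy(),
            "A1": meta["a1"].to_numpy(),
            "A1_FREQ": freq[poly],
            "BETA": beta[poly],
            "SE": se[poly],
            "T_STAT": tt,
            "P": pvals,
            "N": n_eff[poly].astype(int),
        }
    )
    return GwasResult(table=table, skipped=skipped, n_used=n)


def genomic_inflation(result) -> float:
    """Genomic inflation factor: median association chi2 over 0.4549.

    Accepts a :class:`GwasResult` or an array of chi-square(1) statistics;
    refuses to compute from fewer than 100 tests.
    """
    if isinstance(result, GwasResult):
        chi2 = result.table["T_STAT"].to_numpy() ** 2
    else:
        chi2 = np.asarray(result, dtype=np.float64)
    chi2 = chi2[np.isfinite(chi2)]
    if chi2.size < 100:
        raise ValueError(
            f"need at least 100 tests for a stable inflation estimate; got {chi2.size}"
        )
    return float(np.median(chi2) / _CHI2_MEDIAN)
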