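"""Symptom-score construction, covariate residualization and sample splitting.

The analysis variables are disorder-specific symptom sum scores (AN, BN,
BED), three suicidal-ideation items (TAF1-TAF3) and, optionally, depression
(PHQ8) and anxiety (GAD7) sum scores.  Before any latent modelling or
genetic analysis, every analysis variable is residualized on age, sex,
genotyping batch and 10 ancestry principal components; downstream stages
therefore fit intercept-only fixed-effect structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeTable",
    "SymptomScoreSpec",
    "build_symptom_scores",
    "residualize",
    "split_sample",
]


class CollinearCovariatesError(np.linalg.LinAlgError):
    """Raised when the covariate design matrix is rank deficient."""

    def __init__(self, offending: list[str]):
        self.offending = offending
        super().__init__(
            "covariate design is rank-deficient; offending columns: "
            + ", ".join(offending)
        )


@dataclass
class PhenotypeTable:
    """Per-individual items, scores and covariates keyed by (FID, IID).

    ``df`` holds one row per individual with ``FID``/``IID`` string columns;
    the remaining attributes name the columns playing each role.  Scores and
    TAF items together form the analysis variables fed to the latent models.
    """

    df: pd.DataFrame
    item_cols: list[str] = field(default_factory=list)
    score_cols: list[str] = field(default_factory=list)
    taf_cols: list[str] = field(default_factory=list)
    covariate_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in ("FID", "IID"):
            if col not in self.df.columns:
                raise ValueError(f"PhenotypeTable requires a {col!r} column")
        if self.df.duplicated(subset=["FID", "IID"]).any():
            raise ValueError("duplicate (FID, IID) pairs in phenotype table")

    @property
    def analysis_cols(self) -> list[str]:
        return list(self.score_cols) + list(self.taf_cols)

    @property
    def n(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "PhenotypeTable":
        """Pure row filtering (e.g. sensitivity subsets); roles unchanged."""
        return replace(self, df=self.df.loc[mask].reset_index(drop=True))

    def copy(self) -> "PhenotypeTable":
        return replace(self, df=self.df.copy())


@dataclass
class SymptomScoreSpec:
    """Mapping from score name to the ordered item columns summed into it."""

    items: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, cols in self.items.items():
            if not cols:
                raise ValueError(f"score {name!r} has an empty item list")


def build_symptom_scores(
    table: PhenotypeTable, spec: SymptomScoreSpec, prorate: bool = False
) -> PhenotypeTable:
    """Sum item responses into symptom scores (higher = more severe).

    By default a row with any missing item in the set receives a missing
    score.  With ``prorate=True`` the score for partially observed rows is
    the mean of the observed items times the item count.
    """
    df = table.df.copy()
    for score_name, item_names in spec.items.items():
        missing_cols = [c for c in item_names if c not in df.columns]
        if missing_cols:
            raise KeyError(
                f"score {score_name!r} references unknown item columns: {missing_cols}"
            )
        block = df[item_names]
        if prorate:
            scores = block.mean(axis=1, skipna=True) * len(item_names)
            scores[block.isna().all(axis=1)] = np.nan
        else:
            scores = block.sum(axis=1, skipna=False)
        df[score_name] = scores
    new_scores = [s for s in spec.items if s not in table.score_cols]
    return replace(table, df=df, score_cols=list(table.score_cols) + new_scores)


def residualize(
    table: PhenotypeTable,
    covariate_names: list[str] | None = None,
    columns: list[str] | None = None,
) -> PhenotypeTable:
    """Replace each analysis variable with its OLS residual on the covariates.

    A single design matrix (intercept plus the named covariates) is built
    from rows with complete covariates; rows with any missing covariate are
    dropped from fitting and their residuals set missing (they are flagged
    in the returned table's ``_covariates_missing`` column).  Residuals have
    zero mean and zero sample correlation with every covariate by
    construction.  The operation is idempotent up to numerical tolerance.
    """
    covariate_names = list(
        table.covariate_cols if covariate_names is None else covariate_names
    )
    columns = list(table.analysis_cols if columns is None else columns)
    df = table.df.copy()

    C = df[covariate_names].to_numpy(dtype=np.float64)
    ok = ~np.isnan(C).any(axis=1)
    X = np.column_stack([np.ones(ok.sum()), C[ok]])

    # condition check with named offenders
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if (diag < tol).any():
        bad = [covariate_names[i - 1] for i in np.where(diag < tol)[0] if i > 0]
        raise CollinearCovariatesError(bad or covariate_names)

    for col in columns:
        y = df[col].to_numpy(dtype=np.float64)
        res = np.full_like(y, np.nan)
        rows = ok & ~np.isnan(y)
        if rows.sum() == 0:
            df[col] = res
            continue
        # project onto the complement of the covariate span, using the QR of
        # the complete-covariate design restricted to this column's rows
        Xr = np.column_stack([np.ones(rows.sum()), C[rows]])
        beta, *_ = np.linalg.lstsq(Xr, y[rows], rcond=None)
        res[rows] = y[rows] - Xr @ beta
        df[col] = res
    df["_covariates_missing"] = ~ok
    return replace(table, df=df)


def split_sample(
    table: PhenotypeTable, train_fraction: float = 0.7, seed: int = 0
) -> tuple[PhenotypeTable, PhenotypeTable]:
    """Random disjoint, exhaustive split (e.g. 70% for EFA, 30% for CFA)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = table.n
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    mk = lambda idx: replace(table, df=table.df.iloc[idx].reset_index(drop=True))
    return mk(train_idx), mk(test_idx)
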