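"""Readers/writers for the standard file formats the pipeline touches.

PLINK 1 binary genotypes (.bed/.bim/.fam) are read and written bit-exactly
following the published PLINK 1 specification (SNP-major .bed, 2-bit codes).
The GCTA binary GRM triad (.grm.bin/.grm.N.bin/.grm.id) stores the lower
triangle, including the diagonal, as little-endian float32.

The counted allele is always A1 (.bim column 5), matching the PLINK
convention: a dosage of 2 means two copies of A1.  Heritability and GRM
values are invariant to the allele choice, but per-SNP regression betas
flip sign if A1/A2 are swapped.

Missing hard calls are kept as an explicit sentinel (:data:`MISSING`) and
are never imputed at the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "GRM",
    "read_plink",
    "write_plink",
    "read_grm_gcta",
    "write_grm_gcta",
    "read_phenotype_file",
    "write_phenotype_file",
]

#: Sentinel for a missing hard-call dosage (distinct from the valid 0/1/2).
MISSING: int = -9

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# PLINK 1 2-bit codes (within a byte, individuals are packed from the low
# bits up): 00 = hom A1 (dosage 2), 01 = missing, 10 = het, 11 = hom A2.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam fileset violates the PLINK 1 format."""


@dataclass
class GenotypeMatrix:
    """Hard-call genotypes for ``n`` individuals at ``m`` biallelic SNPs.

    Attributes
    ----------
    dosages : (n, m) int8 array
        Count of the A1 allele in {0, 1, 2}, with :data:`MISSING` for
        missing calls.
    snp_meta : DataFrame
        Columns ``chrom, snp_id, pos, a1, a2`` (positions are 1-based).
    sample_ids : DataFrame
        Columns ``fid, iid``.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (individuals x SNPs) array")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"sample_ids has {len(self.sample_ids)} rows for {n} dosage rows"
            )
        if len(self.snp_meta) != m:
            raise ValueError(
                f"snp_meta has {len(self.snp_meta)} rows for {m} dosage columns"
            )
        d = self.dosages
        valid = ((d >= 0) & (d <= 2)) | (d == MISSING)
        if not valid.all():
            bad = np.unique(d[~valid])
            raise ValueError(f"invalid dosage values: {bad}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """In-sample frequency of the counted (A1) allele per SNP.

        Computed as mean(dosage)/2 over non-missing calls; NaN for SNPs
        with no observed calls.
        """
        d = self.dosages.astype(np.float64)
        d[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING


@dataclass
class GRM:
    """Genomic relationship matrix with per-pair SNP counts.

    ``matrix`` is symmetric n x n; ``pair_counts`` holds the number of SNPs
    with non-missing genotypes in both members of each pair; ``m_used`` is
    the number of SNPs surviving the filters.
    """

    matrix: np.ndarray
    pair_counts: np.ndarray
    ids: pd.DataFrame
    m_used: int
    _eigen: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM matrix must be symmetric")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("ids length does not match GRM dimension")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (values, vectors), ascending order."""
        if self._eigen is None:
            from scipy.linalg import eigh

            vals, vecs = eigh(self.matrix)
            self._eigen = (vals, vecs)
        return self._eigen


# ---------------------------------------------------------------------------
# PLINK 1 .bed/.bim/.fam
# ---------------------------------------------------------------------------

def read_plink(path_prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 fileset ``<prefix>.bed/.bim/.fam``.

    The .bed file must be in SNP-major mode.  Dosages count copies of A1
    (.bim column 5).
    """
    prefix = Path(path_prefix)
    fam = _read_fam(prefix.with_suffix(".fam"))
    bim = _read_bim(prefix.with_suffix(".bim"))
    n, m = len(fam), len(bim)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if len(raw) < 3 or raw[0:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(f"{prefix}.bed: not in SNP-major mode")
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{prefix}.bed payload has {payload.size} bytes; expected "
            f"{bytes_per_snp * m} for {n} samples x {m} SNPs"
        )
    blocks = payload.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, low bits first within each byte
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift_idx in range(4):
        codes[:, shift_idx::4] = (blocks >> (2 * shift_idx)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    return GenotypeMatrix(dosages=dosages, snp_meta=bim, sample_ids=fam)


def write_plink(geno: GenotypeMatrix, path_prefix: str | Path) -> None:
    """Write ``geno`` as a PLINK 1 fileset readable by :func:`read_plink`."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.n_samples, geno.n_snps

    fam = geno.sample_ids
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for fid, iid in zip(fam["fid"], fam["iid"]):
            fh.write(f"{fid}\t{iid}\t0\t0\t0\t-9\n")
    bim = geno.snp_meta
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in bim.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\t{row.a1}\t{row.a2}\n")

    bytes_per_snp = (n + 3) // 4
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    codes[:] = 0
    dosage_codes = np.empty_like(geno.dosages, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        dosage_codes[geno.dosages == dosage] = code
    codes[:, :n] = dosage_codes.T
    blocks = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for shift_idx in range(4):
        blocks |= codes[:, shift_idx::4] << (2 * shift_idx)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(blocks.tobytes())


def _read_fam(path: Path) -> pd.DataFrame:
    fam = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise PlinkFormatError(f"{path}: expected at least 2 columns")
    return pd.DataFrame({"fid": fam[0], "iid": fam[1]})


def _read_bim(path: Path) -> pd.DataFrame:
    try:
        bim = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "snp_id", "pos", "a1", "a2"])
    if bim.shape[1] != 6:
        raise PlinkFormatError(f"{path}: expected 6 columns, got {bim.shape[1]}")
    return pd.DataFrame(
        {
            "chrom": bim[0],
            "snp_id": bim[1],
            "pos": bim[3].astype(np.int64),
            "a1": bim[4],
            "a2": bim[5],
        }
    )


# ---------------------------------------------------------------------------
# GCTA binary GRM triad
# ---------------------------------------------------------------------------

def write_grm_gcta(grm: GRM, path_prefix: str | Path) -> None:
    """Write ``grm`` in the GCTA binary triad format.

    ``<prefix>.grm.bin`` holds the lower triangle (rows j, columns k <= j,
    diagonal included) in row-major order as little-endian float32;
    ``<prefix>.grm.N.bin`` the matching per-pair SNP counts;
    ``<prefix>.grm.id`` two tab-separated columns FID IID.
    """
    prefix = str(path_prefix)
    n = grm.n
    rows, cols = np.tril_indices(n)
    tri = grm.matrix[rows, cols].astype("<f4")
    Path(prefix + ".grm.bin").write_bytes(tri.tobytes())
    counts = np.broadcast_to(np.asarray(grm.pair_counts, dtype=np.float64), grm.matrix.shape)
    Path(prefix + ".grm.N.bin").write_bytes(counts[rows, cols].astype("<f4").tobytes())
    with open(prefix + ".grm.id", "w") as fh:
        for fid, iid in zip(grm.ids["fid"], grm.ids["iid"]):
            fh.write(f"{fid}\t{iid}\n")


def read_grm_gcta(path_prefix: str | Path) -> GRM:
    """Read a GCTA binary GRM triad written by :func:`write_grm_gcta`."""
    prefix = str(path_prefix)
    ids = pd.read_csv(
        prefix + ".grm.id", sep=r"\s+", header=None, names=["fid", "iid"], dtype=str
    )
    n = len(ids)
    tri = np.frombuffer(Path(prefix + ".grm.bin").read_bytes(), dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise ValueError(
            f"{prefix}.grm.bin holds {tri.size} values; expected {n * (n + 1) // 2}"
        )
    counts_tri = np.frombuffer(Path(prefix + ".grm.N.bin").read_bytes(), dtype="<f4")
    mat = np.zeros((n, n))
    cnt = np.zeros((n, n))
    rows, cols = np.tril_indices(n)
    mat[rows, cols] = tri
    mat[cols, rows] = tri
    cnt[rows, cols] = counts_tri
    cnt[cols, rows] = counts_tri
    return GRM(matrix=mat, pair_counts=cnt, ids=ids, m_used=int(round(cnt.max())) if n else 0)


# ---------------------------------------------------------------------------
# Phenotype / covariate tables
# ---------------------------------------------------------------------------

def read_phenotype_file(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited table whose first two columns are FID, IID."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = list(df.columns)
    if len(cols) < 2 or cols[0].upper() != "FID" or cols[1].upper() != "IID":
        raise ValueError(f"{path}: first two columns must be FID, IID (got {cols[:2]})")
    return df.rename(columns={cols[0]: "FID", cols[1]: "IID"})


def write_phenotype_file(df: pd.DataFrame, path: str | Path) -> None:
    """Write a FID/IID-keyed table as tab-delimited text with a header."""
    cols = list(df.columns)
    if cols[:2] != ["FID", "IID"]:
        raise ValueError("first two columns must be FID, IID")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
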