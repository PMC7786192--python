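"""SNP quality control, genotype standardization, GRM construction and PCs.

Genotypes are additive-coded 0/1/2 counts of the minor (or either) allele
with NaN for missing calls.  The genomic relationship matrix follows the
usual SNP-BLUP construction A = W W' / m where W is the column-standardized
genotype matrix; with population-sd (divide-by-n) standardization the mean
of diag(A) is exactly 1, which downstream code relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "QCReport",
    "qc_genotypes",
    "standardize",
    "compute_grm",
    "grm_pcs",
    "read_plink_additive",
    "write_plink_additive",
    "read_gcta_grm",
    "write_gcta_grm",
]


@dataclass
class GenotypeMatrix:
    """Additive-coded calls (n animals x m SNPs), NaN = missing."""

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    calls: np.ndarray  # float array with values in {0,1,2,nan}

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.calls = np.asarray(self.calls, dtype=float)
        n, m = self.calls.shape
        if len(self.animal_ids) != n or len(self.snp_ids) != m:
            raise ValueError("id lengths inconsistent with call matrix shape")
        if len(set(self.animal_ids)) != n or len(set(self.snp_ids)) != m:
            raise ValueError("animal and SNP ids must be unique")

    @property
    def n(self) -> int:
        return self.calls.shape[0]

    @property
    def m(self) -> int:
        return self.calls.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele, ignoring missing calls."""
        return np.nanmean(self.calls, axis=0) / 2.0


@dataclass
class GRM:
    animal_ids: np.ndarray
    A: np.ndarray
    n_snps: int = 0

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids)
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.animal_ids),) * 2:
            raise ValueError("GRM shape inconsistent with animal ids")


@dataclass
class QCReport:
    """Per-filter removal counts; removed + retained = input."""

    n_animals_in: int
    n_snps_in: int
    animals_removed_missingness: int = 0
    snps_removed_maf: int = 0
    snps_removed_missingness: int = 0
    snps_removed_hwe: int = 0
    snps_removed_sex_chrom: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_animals_out(self) -> int:
        return self.n_animals_in - self.animals_removed_missingness

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - (
            self.snps_removed_maf
            + self.snps_removed_missingness
            + self.snps_removed_hwe
            + self.snps_removed_sex_chrom
        )


def hwe_chi2_p(calls_col: np.ndarray) -> float:
    """Hardy-Weinberg chi-square (1 df) p-value for one SNP column."""
    c = calls_col[~np.isnan(calls_col)]
    n = len(c)
    if n == 0:
        return 1.0
    obs = np.array([(c == 0).sum(), (c == 1).sum(), (c == 2).sum()], dtype=float)
    p = obs @ np.array([0.0, 0.5, 1.0]) / n
    q = 1.0 - p
    if p in (0.0, 1.0):
        return 1.0  # monomorphic; MAF filter handles it
    exp = n * np.array([q * q, 2 * p * q, p * p])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_genotypes(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    snp_missing_max: float = 0.10,
    hwe_p_min: float = 1e-4,
    indiv_missing_max: float = 0.10,
    sex_chrom_snps=None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter animals then SNPs, each in a single pass.

    Animals with missingness above ``indiv_missing_max`` are removed first;
    SNP filters (sex-chromosome annotation, MAF, missingness, HWE) are then
    evaluated on the retained animals.  A SNP failing several filters is
    counted against the first in that order.
    """
    for name, v in [
        ("maf_min", maf_min), ("snp_missing_max", snp_missing_max),
        ("hwe_p_min", hwe_p_min), ("indiv_missing_max", indiv_missing_max),
    ]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")

    report = QCReport(
        n_animals_in=g.n,
        n_snps_in=g.m,
        thresholds=dict(
            maf_min=maf_min, snp_missing_max=snp_missing_max,
            hwe_p_min=hwe_p_min, indiv_missing_max=indiv_missing_max,
        ),
    )

    miss_animal = np.isnan(g.calls).mean(axis=1)
    keep_animal = miss_animal <= indiv_missing_max
    report.animals_removed_missingness = int((~keep_animal).sum())
    calls = g.calls[keep_animal]

    sexchrom = np.zeros(g.m, dtype=bool)
    if sex_chrom_snps is not None:
        sexset = set(sex_chrom_snps)
        sexchrom = np.array([s in sexset for s in g.snp_ids])

    freq = np.nanmean(calls, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    miss_snp = np.isnan(calls).mean(axis=0)
    hwe_p = np.array([hwe_chi2_p(calls[:, j]) for j in range(calls.shape[1])])

    fail_maf = (maf < maf_min) & ~sexchrom
    fail_miss = (miss_snp > snp_missing_max) & ~sexchrom & ~fail_maf
    fail_hwe = (hwe_p < hwe_p_min) & ~sexchrom & ~fail_maf & ~fail_miss
    report.snps_removed_sex_chrom = int(sexchrom.sum())
    report.snps_removed_maf = int(fail_maf.sum())
    report.snps_removed_missingness = int(fail_miss.sum())
    report.snps_removed_hwe = int(fail_hwe.sum())

    keep_snp = ~(sexchrom | fail_maf | fail_miss | fail_hwe)
    if not keep_snp.any():
        raise ValueError("quality control removed every SNP (empty panel)")

    out = GenotypeMatrix(
        animal_ids=g.animal_ids[keep_animal],
        snp_ids=g.snp_ids[keep_snp],
        calls=calls[:, keep_snp],
    )
    return out, report


def standardize(g: GenotypeMatrix) -> np.ndarray:
    """Column-standardized genotype matrix W.

    Missing calls are imputed with the SNP mean; each column is centered and
    divided by its population (divide-by-n) standard deviation.
    """
    calls = g.calls.copy()
    mean = np.nanmean(calls, axis=0)
    idx = np.where(np.isnan(calls))
    calls[idx] = mean[idx[1]]
    sd = calls.std(axis=0)  # ddof=0
    if np.any(sd == 0.0):
        bad = g.snp_ids[sd == 0.0]
        raise RuntimeError(
            f"zero-variance SNP column(s) {bad[:5]!r} reached standardize(); "
            "QC should have removed them"
        )
    return (calls - mean) / sd


def compute_grm(W: np.ndarray, animal_ids=None) -> GRM:
    """A = W W' / m from a standardized genotype matrix."""
    W = np.asarray(W, dtype=float)
    n, m = W.shape
    A = W @ W.T / m
    A = (A + A.T) / 2.0  # enforce bit-exact symmetry
    if animal_ids is None:
        animal_ids = np.arange(n)
    return GRM(animal_ids=animal_ids, A=A, n_snps=m)


def grm_pcs(grm: GRM, k: int = 10) -> np.ndarray:
    """Top-k principal component scores of the GRM.

    Columns are eigenvectors of A for the k largest eigenvalues, scaled by
    the square root of the eigenvalue.  Sign convention: the largest-
    magnitude loading in each column is positive.  Zero (or numerically
    negative) eigenvalue PCs are dropped, so fewer than k columns may be
    returned on a rank-deficient GRM.
    """
    n = grm.A.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds matrix dimension {n}")
    vals, vecs = np.linalg.eigh(grm.A)
    order = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > 1e-8 * max(vals[0], 1.0)
    vals, vecs = vals[keep], vecs[:, keep]
    signs = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs * np.sqrt(vals)


# ---------------------------------------------------------------------------
# text-format IO
# ---------------------------------------------------------------------------

def write_plink_additive(g: GenotypeMatrix, path) -> None:
    """Write additive-coded genotypes: header of SNP ids, rows of id + 0/1/2/NA."""
    df = pd.DataFrame(g.calls, columns=g.snp_ids)
    df.insert(0, "animal_id", g.animal_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.0f")


def read_plink_additive(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return GenotypeMatrix(
        animal_ids=df.iloc[:, 0].to_numpy(),
        snp_ids=np.array(df.columns[1:]),
        calls=df.iloc[:, 1:].to_numpy(dtype=float),
    )


def write_gcta_grm(grm: GRM, prefix) -> None:
    """Write a GRM in the GCTA text dialect.

    ``<prefix>.grm.txt`` holds rows (i, j <= i, n_snps, A_ij) with 1-based
    indices; ``<prefix>.grm.id`` holds two id columns (family id repeated).
    """
    n = len(grm.animal_ids)
    with open(f"{prefix}.grm.txt", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.n_snps}\t{grm.A[i, j]:.6f}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for aid in grm.animal_ids:
            fh.write(f"{aid}\t{aid}\n")


def read_gcta_grm(prefix) -> GRM:
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)
    animal_ids = ids.iloc[:, 1].to_numpy()
    n = len(animal_ids)
    tab = pd.read_csv(f"{prefix}.grm.txt", sep="\t", header=None,
                      names=["i", "j", "nsnp", "a"])
    A = np.zeros((n, n))
    ii = tab["i"].to_numpy() - 1
    jj = tab["j"].to_numpy() - 1
    A[ii, jj] = tab["a"].to_numpy()
    A[jj, ii] = tab["a"].to_numpy()
    return GRM(animal_ids=animal_ids, A=A, n_snps=int(tab["nsnp"].iloc[0]))
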