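"""Genotype QC, frequency-based imputation, GRM construction and PCA.

The dosage matrix is individuals x SNPs with entries in {0, 1, 2} counting
copies of the alternative allele; missing entries are NaN. The SNP map is
kept sorted by (chromosome, bp) with 1-based positions, mirroring the PLINK
text convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan


@dataclass
class GenotypeSet:
    """Dosage matrix plus SNP map and sample sheet.

    Attributes
    ----------
    dosages : ndarray of shape (n_individuals, n_snps)
        Alt-allele dosages in {0, 1, 2}; NaN marks a missing call.
    snp_map : DataFrame with columns snp_id, chrom, bp
        Sorted by (chrom, bp); bp is 1-based.
    samples : DataFrame with columns doe_id, population
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError("sample sheet does not match dosage rows")
        if len(self.snp_map) != m:
            raise ValueError("SNP map does not match dosage columns")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0/1/2 or missing")
        self.snp_map = self.snp_map.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per individual."""
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def snp_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Observed alternative-allele frequency per SNP (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def subset(self, individuals=None, snps=None) -> "GenotypeSet":
        """Row/column subset by boolean mask or integer index."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if ind.dtype == bool:
            ind = np.flatnonzero(ind)
        if snp.dtype == bool:
            snp = np.flatnonzero(snp)
        return GenotypeSet(
            dosages=self.dosages[np.ix_(ind, snp)].copy(),
            snp_map=self.snp_map.iloc[snp].reset_index(drop=True),
            samples=self.samples.iloc[ind].reset_index(drop=True),
        )

    def snps_on(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.snp_map["chrom"].astype(str) == str(chrom))


@dataclass
class GRM:
    """VanRaden-style genomic relationship matrix.

    matrix = W W' / m with W the column-standardised dosage matrix; the
    diagonal averages ~1 and the matrix is positive semidefinite up to
    numerical tolerance.
    """

    matrix: np.ndarray
    snps_used: list = field(default_factory=list)
    excluded_chrom: str | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def qc_filter(
    gs: GenotypeSet,
    min_call_rate: float = 0.97,
    min_maf: float = 0.05,
    max_snp_missing: float = 0.05,
) -> GenotypeSet:
    """Remove low-call-rate individuals, then low-MAF / high-missing SNPs.

    Thresholds are strict in the removal direction: an individual is removed
    when call rate < min_call_rate, a SNP when MAF < min_maf or missing rate
    > max_snp_missing or its map position is unknown. Values exactly at the
    threshold are retained. Individuals are filtered before SNP statistics
    are computed.
    """
    if gs.n_individuals == 0 or gs.n_snps == 0:
        raise ValueError("empty genotype set")
    keep_ind = gs.call_rate() >= min_call_rate
    n_ind_removed = int((~keep_ind).sum())
    if not keep_ind.any():
        raise ValueError("all individuals removed by call-rate filter")
    gs = gs.subset(individuals=keep_ind)

    maf = gs.maf()
    miss = gs.snp_missing_rate()
    has_pos = gs.snp_map["bp"].notna().to_numpy() & (gs.snp_map["bp"].to_numpy() > 0)
    low_maf = maf < min_maf
    high_miss = miss > max_snp_missing
    keep_snp = ~low_maf & ~high_miss & has_pos
    if not keep_snp.any():
        raise ValueError("all SNPs removed by QC")
    logger.info(
        "QC removed %d individuals (call rate), %d SNPs (MAF), %d SNPs (missing), "
        "%d SNPs (no position)",
        n_ind_removed,
        int(low_maf.sum()),
        int((high_miss & ~low_maf).sum()),
        int((~has_pos & ~low_maf & ~high_miss).sum()),
    )
    return gs.subset(snps=keep_snp)


def impute_missing(gs: GenotypeSet, seed: int) -> GenotypeSet:
    """Fill missing dosages with Binomial(2, p_hat) draws at the observed
    alt frequency of each SNP. Observed entries are never altered."""
    rng = np.random.default_rng(seed)
    dos = gs.dosages.copy()
    p = gs.alt_freq()
    for j in range(gs.n_snps):
        miss = np.isnan(dos[:, j])
        if not miss.any():
            continue
        if np.isnan(p[j]):
            raise ValueError(f"SNP {gs.snp_map['snp_id'].iloc[j]} has no observed calls")
        dos[miss, j] = rng.binomial(2, p[j], size=int(miss.sum()))
    return GenotypeSet(dosages=dos, snp_map=gs.snp_map.copy(), samples=gs.samples.copy())


def standardized_dosages(gs: GenotypeSet, snp_idx: np.ndarray | None = None) -> np.ndarray:
    """Center each column at 2p and scale by sqrt(2p(1-p)); monomorphic
    columns become all-zero."""
    idx = np.arange(gs.n_snps) if snp_idx is None else np.asarray(snp_idx)
    dos = gs.dosages[:, idx]
    if np.isnan(dos).any():
        raise ValueError("impute missing genotypes before standardising")
    p = dos.mean(axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    W = dos - 2.0 * p
    poly = denom > 0
    W[:, poly] /= denom[poly]
    W[:, ~poly] = 0.0
    return W


def compute_grm(gs: GenotypeSet, exclude_chrom: str | None = None) -> GRM:
    """GRM = W W' / m over the included SNPs; ``exclude_chrom`` drops all
    SNPs on that chromosome (LOCO construction)."""
    chroms = gs.snp_map["chrom"].astype(str)
    if exclude_chrom is not None:
        include = np.flatnonzero(chroms != str(exclude_chrom))
        if include.size == 0:
            raise ValueError(f"excluding chromosome {exclude_chrom} leaves no SNPs")
    else:
        include = np.arange(gs.n_snps)
    W = standardized_dosages(gs, include)
    m = include.size
    return GRM(
        matrix=W @ W.T / m,
        snps_used=gs.snp_map["snp_id"].iloc[include].tolist(),
        excluded_chrom=None if exclude_chrom is None else str(exclude_chrom),
    )


def compute_pcs(grm: GRM, k: int = 5) -> np.ndarray:
    """Top-k eigenvectors of the GRM (descending eigenvalue), sign-fixed so
    each vector's largest-magnitude entry is positive."""
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    rank = int((vals > max(vals[0], 0) * 1e-10).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds GRM rank {rank}")
    pcs = vecs[:, :k].copy()
    for j in range(k):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


# ---------------------------------------------------------------------------
# PLINK text I/O


def write_plink(gs: GenotypeSet, prefix: str | Path) -> None:
    """Write .ped/.map text files; alleles coded A (ref) / B (alt), missing 0."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in gs.snp_map.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{int(row['bp'])}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(gs.n_individuals):
            doe = gs.samples["doe_id"].iloc[i]
            pop = gs.samples["population"].iloc[i]
            cells = [str(pop), str(doe), "0", "0", "2", "-9"]
            for d in gs.dosages[i]:
                if np.isnan(d):
                    cells += ["0", "0"]
                else:
                    nalt = int(d)
                    cells += ["B"] * nalt + ["A"] * (2 - nalt)
            fh.write(" ".join(cells) + "\n")


def read_plink(prefix: str | Path) -> GenotypeSet:
    """Read .ped/.map text files written by :func:`write_plink` (alt allele =
    'B'); dosage counts B alleles, '0 0' is missing."""
    prefix = Path(prefix)
    snp_map = pd.read_csv(
        prefix.with_suffix(".map"),
        sep="\t",
        header=None,
        names=["chrom", "snp_id", "cm", "bp"],
        dtype={"chrom": str},
    )[["snp_id", "chrom", "bp"]]
    rows, ids, pops = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            cells = line.split()
            pops.append(cells[0])
            ids.append(cells[1])
            alleles = cells[6:]
            a1 = np.array(alleles[0::2])
            a2 = np.array(alleles[1::2])
            dos = (a1 == "B").astype(float) + (a2 == "B").astype(float)
            dos[(a1 == "0") | (a2 == "0")] = np.nan
            rows.append(dos)
    return GenotypeSet(
        dosages=np.vstack(rows),
        snp_map=snp_map,
        samples=pd.DataFrame({"doe_id": ids, "population": pops}),
    )
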