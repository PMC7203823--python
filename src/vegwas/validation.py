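"""Additional evidence for candidate SNPs.

Two checks: an empirical p-value (EMP1) from phenotype-label permutations
with variance components frozen at the observed-data fit, and a
within-population comparison of allele substitution effects whose +/- 2 SE
confidence intervals must overlap across populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from vegwas.genotype_qc import GRM, GenotypeSet
from vegwas.gwas_smr import VarianceComponents


def _whitener(n: int, grm: GRM | None, vc: VarianceComponents | None) -> np.ndarray | None:
    """Inverse square root of sigma2_g*G + sigma2_e*I, or None for identity
    covariance (plain OLS statistics)."""
    if grm is None or vc is None or vc.sigma2_g <= 0:
        return None
    lam, U = np.linalg.eigh(grm.matrix)
    d = np.maximum(vc.sigma2_g * lam + vc.sigma2_e, 1e-12)
    return (U / np.sqrt(d)) @ U.T


def _wald_p_matrix(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Wald p-values for the slope of each column of Y regressed on
    (intercept, x); vectorised over columns."""
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx < 1e-12:
        return np.ones(Y.shape[1])
    Yc = Y - Y.mean(axis=0)
    sxy = xc @ Yc
    beta = sxy / sxx
    rss = np.einsum("ij,ij->j", Yc, Yc) - beta * sxy
    sigma2 = np.maximum(rss, 0.0) / max(n - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(sigma2 > 0, beta**2 * sxx / sigma2, np.inf)
    return stats.chi2.sf(chi2, df=1)


def permutation_test(
    pheno: pd.DataFrame,
    gs: GenotypeSet,
    candidate_snps: list,
    n_perm: int = 100_000,
    seed: int = 0,
    grm: GRM | None = None,
    vc: VarianceComponents | None = None,
    block_size: int = 2_000,
) -> pd.DataFrame:
    """EMP1 per candidate SNP over ``n_perm`` uniform phenotype permutations.

    The same permutation is applied to all candidates within a replicate and
    variance components are held fixed from the observed-data fit (the
    association statistic is computed on whitened data). b counts permuted
    p-values <= the observed p-value; EMP1 = (b + 1) / N capped at 1, so the
    minimum registrable value is 1/N.
    """
    if not candidate_snps:
        raise ValueError("candidate list is empty")
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    aligned = gs.samples[["doe_id"]].merge(pheno, on="doe_id", how="left")
    if aligned["ve"].isna().any():
        raise ValueError("phenotype missing for some genotyped does")
    y = aligned["ve"].to_numpy(dtype=float)
    idx = [gs.snp_map.index[gs.snp_map["snp_id"] == s][0] for s in candidate_snps]
    X = gs.dosages[:, idx]
    if np.isnan(X).any():
        raise ValueError("impute missing genotypes before the permutation test")

    L = _whitener(y.size, grm, vc)
    Xw = X if L is None else L @ X
    yw = y if L is None else L @ y
    p_obs = np.array([_wald_p_matrix(Xw[:, k], yw[:, None])[0] for k in range(len(idx))])

    rng = np.random.default_rng(seed)
    b = np.zeros(len(idx), dtype=np.int64)
    done = 0
    while done < n_perm:
        nb = min(block_size, n_perm - done)
        perms = np.empty((y.size, nb), dtype=float)
        for c in range(nb):
            perms[:, c] = y[rng.permutation(y.size)]
        Pw = perms if L is None else L @ perms
        for k in range(len(idx)):
            p_perm = _wald_p_matrix(Xw[:, k], Pw)
            b[k] += int((p_perm <= p_obs[k]).sum())
        done += nb

    emp1 = np.minimum((b + 1) / n_perm, 1.0)
    return pd.DataFrame(
        {"snp": candidate_snps, "emp1": emp1, "b": b, "n_perm": n_perm, "p_obs": p_obs}
    )


@dataclass
class PopulationEffect:
    snp: str
    population: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    monomorphic: bool
    low_power: bool


def within_population_gwas(
    pheno: pd.DataFrame, gs: GenotypeSet, candidate_snps: list
) -> pd.DataFrame:
    """Per-population simple regression of ve on dosage with a shared
    alt-allele orientation; CI = beta +/- 2 SE. Populations with fewer than
    10 does are flagged low-power but still reported; monomorphic SNPs are
    flagged and contribute no evidence of a difference."""
    aligned = gs.samples[["doe_id", "population"]].merge(
        pheno.drop(columns=["population"], errors="ignore"), on="doe_id", how="left"
    )
    y_all = aligned["ve"].to_numpy(dtype=float)
    idx = {s: gs.snp_map.index[gs.snp_map["snp_id"] == s][0] for s in candidate_snps}

    rows = []
    for pop in pd.unique(aligned["population"]):
        mask = (aligned["population"] == pop).to_numpy()
        y = y_all[mask]
        for snp, j in idx.items():
            x = gs.dosages[mask, j]
            ok = ~np.isnan(x) & ~np.isnan(y)
            xk, yk = x[ok], y[ok]
            mono = xk.size < 3 or np.std(xk) < 1e-12
            if mono:
                beta = se = np.nan
            else:
                xc = xk - xk.mean()
                sxx = float(xc @ xc)
                beta = float(xc @ yk / sxx)
                resid = yk - yk.mean() - beta * xc
                sigma2 = float(resid @ resid) / max(xk.size - 2, 1)
                se = float(np.sqrt(sigma2 / sxx))
            rows.append(
                PopulationEffect(
                    snp=snp,
                    population=str(pop),
                    beta=beta,
                    se=se,
                    ci_low=beta - 2 * se if not mono else np.nan,
                    ci_high=beta + 2 * se if not mono else np.nan,
                    monomorphic=mono,
                    low_power=bool(mask.sum() < 10),
                ).__dict__
            )
    return pd.DataFrame(rows)


def ci_overlap_filter(
    effects: pd.DataFrame, perm: pd.DataFrame, emp1_max: float = 0.0005
) -> pd.DataFrame:
    """A SNP passes iff all pairwise population CIs overlap (monomorphic
    populations count as overlapping) and its EMP1 <= emp1_max."""
    perm_map = dict(zip(perm["snp"], perm["emp1"]))
    rows = []
    for snp, grp in effects.groupby("snp", sort=False):
        reasons = []
        usable = grp[~grp["monomorphic"]]
        cis = list(zip(usable["ci_low"], usable["ci_high"]))
        overlap = all(
            max(a_lo, b_lo) <= min(a_hi, b_hi)
            for i, (a_lo, a_hi) in enumerate(cis)
            for b_lo, b_hi in cis[i + 1 :]
        )
        if not overlap:
            reasons.append("line effect difference")
        emp1 = perm_map.get(snp, np.nan)
        if not np.isnan(emp1) and emp1 > emp1_max:
            reasons.append("permutation")
        rows.append(
            {"snp": snp, "pass": not reasons, "emp1": emp1, "reasons": ";".join(reasons)}
        )
    return pd.DataFrame(rows)
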