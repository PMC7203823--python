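"""Single-marker regression on the environmental-variance phenotype.

Two variants are provided: a mixed linear model with a leave-one-chromosome-
out (LOCO) genomic relationship matrix, and a weighted least-squares model
with the first five principal components as covariates and per-doe precision
weights. Variance components come from a one-dimensional REML profile over
the heritability ratio, computed once per LOCO chromosome and then fixed for
all SNP tests on that chromosome (the usual MLMA shortcut).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from vegwas.genotype_qc import GRM, GenotypeSet

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    identifiable: bool = True
    converged: bool = True
    reml_loglik: float = np.nan

    @property
    def total(self) -> float:
        return self.sigma2_g + self.sigma2_e

    @property
    def h2(self) -> float:
        return self.sigma2_g / self.total if self.total > 0 else 0.0


def _reml_profile(h: float, lam: np.ndarray, ystar: np.ndarray, xstar: np.ndarray) -> float:
    """Negative profiled REML log-likelihood at heritability ratio h, in the
    eigenbasis of the GRM (lam = eigenvalues)."""
    n, p = xstar.shape[0], xstar.shape[1]
    d = h * lam + (1.0 - h)
    d = np.maximum(d, 1e-10)
    xtd = xstar / d[:, None]
    xtx = xstar.T @ xtd
    beta = np.linalg.solve(xtx, xtd.T @ ystar)
    resid = ystar - xstar @ beta
    rss = float(resid @ (resid / d))
    sigma2 = rss / (n - p)
    _, logdet_xtx = np.linalg.slogdet(xtx)
    ll = -0.5 * ((n - p) * np.log(sigma2) + np.log(d).sum() + logdet_xtx)
    return -ll


def estimate_variance_components(y: np.ndarray, grm: GRM) -> VarianceComponents:
    """REML under y = 1*mu + g + e, g ~ N(0, G*sigma2_g), via the GRM
    eigendecomposition and 1-D optimisation of the profiled likelihood in
    h = sigma2_g / (sigma2_g + sigma2_e).

    A flat profile (e.g. G = identity) is flagged ``identifiable=False`` and
    the total variance is split evenly. Non-convergence returns the boundary
    estimate sigma2_g = 0 with ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    if y.size != grm.n:
        raise ValueError("phenotype length does not match GRM")
    lam, U = np.linalg.eigh(grm.matrix)
    ystar = U.T @ y
    xstar = U.T @ np.ones((y.size, 1))

    hs = np.linspace(0.0, 0.99, 25)
    vals = np.array([_reml_profile(h, lam, ystar, xstar) for h in hs])
    if np.ptp(vals) < 1e-8:
        total = float(np.var(y, ddof=1))
        return VarianceComponents(
            total / 2.0, total / 2.0, identifiable=False, reml_loglik=-vals[0]
        )
    res = optimize.minimize_scalar(
        _reml_profile, bounds=(0.0, 0.999), args=(lam, ystar, xstar), method="bounded"
    )
    if not res.success:
        logger.warning("REML did not converge; returning boundary sigma2_g = 0")
        total = float(np.var(y, ddof=1))
        return VarianceComponents(0.0, total, converged=False, reml_loglik=np.nan)
    h = float(res.x)
    d = h * lam + (1.0 - h)
    d = np.maximum(d, 1e-10)
    xtd = xstar / d[:, None]
    beta = np.linalg.solve(xstar.T @ xtd, xtd.T @ ystar)
    resid = ystar - xstar @ beta
    sigma2 = float(resid @ (resid / d)) / (y.size - 1)
    return VarianceComponents(
        sigma2_g=max(h * sigma2, 0.0),
        sigma2_e=max((1.0 - h) * sigma2, 0.0),
        reml_loglik=-float(res.fun),
    )


def _gls_scan(
    y: np.ndarray, X_snps: np.ndarray, lam: np.ndarray, U: np.ndarray, vc: VarianceComponents
) -> pd.DataFrame:
    """GLS of y on (intercept, snp) for each SNP column, with covariance
    sigma2_g * G + sigma2_e * I held fixed; returns beta, se, Wald p."""
    d = vc.sigma2_g * lam + vc.sigma2_e
    d = np.maximum(d, 1e-12)
    sqrt_d = np.sqrt(d)
    yt = (U.T @ y) / sqrt_d
    onet = (U.T @ np.ones_like(y)) / sqrt_d
    Xt = (U.T @ X_snps) / sqrt_d[:, None]

    # project out the (whitened) intercept, then 1-D GLS per SNP
    denom_1 = float(onet @ onet)
    y_r = yt - onet * (float(onet @ yt) / denom_1)
    X_r = Xt - np.outer(onet, onet @ Xt / denom_1)
    sxx = np.einsum("ij,ij->j", X_r, X_r)
    sxy = X_r.T @ y_r

    beta = np.zeros(X_snps.shape[1])
    se = np.full(X_snps.shape[1], np.inf)
    poly = sxx > 1e-12
    beta[poly] = sxy[poly] / sxx[poly]
    # residual scale re-estimated per SNP so the sigma2_g -> 0 limit is
    # exactly OLS; near 1 when the variance components fit well
    syy = float(y_r @ y_r)
    dof = max(y.size - 2, 1)
    scale = np.maximum(syy - beta[poly] * sxy[poly], 0.0) / dof
    se[poly] = np.sqrt(scale / sxx[poly])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(poly, (beta / se) ** 2, 0.0)
        chi2 = np.nan_to_num(chi2, nan=0.0, posinf=np.inf)
    p = stats.chi2.sf(chi2, df=1)
    p[~poly] = 1.0
    return pd.DataFrame({"beta": beta, "se": se, "p": p, "monomorphic": ~poly})


def mlma_loco(pheno: pd.DataFrame, gs: GenotypeSet) -> pd.DataFrame:
    """Mixed-model association with leave-one-chromosome-out GRM.

    For each chromosome the GRM excludes that chromosome's SNPs, variance
    components are estimated once under the no-SNP null, and every SNP on
    the chromosome is tested by GLS with that covariance.

    ``pheno`` must carry doe_id and ve; rows are aligned to ``gs.samples``.
    Monomorphic SNPs are reported with beta = 0, p = 1 and flagged.
    """
    from vegwas.genotype_qc import compute_grm

    aligned = gs.samples[["doe_id"]].merge(pheno, on="doe_id", how="left")
    if aligned["ve"].isna().any():
        raise ValueError("phenotype missing for some genotyped does")
    y = aligned["ve"].to_numpy(dtype=float)

    out = []
    for chrom in pd.unique(gs.snp_map["chrom"].astype(str)):
        idx = gs.snps_on(chrom)
        try:
            grm = compute_grm(gs, exclude_chrom=chrom)
        except ValueError:  # single-chromosome panel: fall back to full GRM
            grm = compute_grm(gs)
        vc = estimate_variance_components(y, grm)
        lam, U = np.linalg.eigh(grm.matrix)
        res = _gls_scan(y, gs.dosages[:, idx], lam, U, vc)
        res.insert(0, "snp", gs.snp_map["snp_id"].iloc[idx].to_numpy())
        res.insert(1, "chrom", chrom)
        res.insert(2, "bp", gs.snp_map["bp"].iloc[idx].to_numpy())
        res["sigma2_g"] = vc.sigma2_g
        res["sigma2_e"] = vc.sigma2_e
        out.append(res)
    df = pd.concat(out, ignore_index=True)
    df["method"] = "mlma_loco"
    return df


def weighted_smr(
    pheno: pd.DataFrame, gs: GenotypeSet, pcs: np.ndarray, weights: np.ndarray | None = None
) -> pd.DataFrame:
    """Weighted least squares of ve on (intercept, dosage, PC1..PCk) with
    per-doe precision weights (residual variance proportional to 1/w_i)."""
    import statsmodels.api as sm

    aligned = gs.samples[["doe_id"]].merge(pheno, on="doe_id", how="left")
    if aligned["ve"].isna().any():
        raise ValueError("phenotype missing for some genotyped does")
    y = aligned["ve"].to_numpy(dtype=float)
    w = aligned["weight"].to_numpy(dtype=float) if weights is None else np.asarray(weights, float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    pcs = np.asarray(pcs, dtype=float)
    if pcs.shape[0] != gs.n_individuals:
        raise ValueError("PC matrix does not match individuals")

    rows = []
    base = np.column_stack([np.ones_like(y), pcs])
    for j in range(gs.n_snps):
        x = gs.dosages[:, j]
        if np.nanstd(x) < 1e-12:
            rows.append({"beta": 0.0, "se": np.inf, "p": 1.0, "monomorphic": True})
            continue
        X = np.column_stack([base[:, :1], x, base[:, 1:]])
        fit = sm.WLS(y, X, weights=w).fit()
        t = fit.params[1] / fit.bse[1]
        rows.append(
            {
                "beta": float(fit.params[1]),
                "se": float(fit.bse[1]),
                "p": float(stats.chi2.sf(t * t, df=1)),
                "monomorphic": False,
            }
        )
    df = pd.DataFrame(rows)
    df.insert(0, "snp", gs.snp_map["snp_id"].to_numpy())
    df.insert(1, "chrom", gs.snp_map["chrom"].to_numpy())
    df.insert(2, "bp", gs.snp_map["bp"].to_numpy())
    df["method"] = "weighted_pc"
    return df


def smr_significant(
    results: pd.DataFrame, threshold: float = 1e-4, relaxed: float = 2e-4
) -> pd.DataFrame:
    """Label SNPs 'strict' (p < threshold) or 'near' (threshold <= p <
    relaxed); near-tier SNPs only stand if the multiple-marker Bayes factor
    later confirms them."""
    df = results.copy()
    tier = np.full(len(df), "", dtype=object)
    tier[df["p"].to_numpy() < threshold] = "strict"
    near = (df["p"].to_numpy() >= threshold) & (df["p"].to_numpy() < relaxed)
    tier[near] = "near"
    df["tier"] = tier
    return df[df["tier"] != ""].reset_index(drop=True)
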