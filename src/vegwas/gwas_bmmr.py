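"""Bayesian multiple-marker regression (BayesB) with Bayes factors and
1-Mb window variance partitioning.

The sampler fits y = 1*mu + sum_j z_j delta_j beta_j + e where each locus
carries a point mass at zero with prior exclusion probability pi and, when
included, a locus-specific variance with a scaled-inverse-chi-square prior.
Locus variances of excluded loci are refreshed from the prior so the
(delta_j, beta_j) update is a plain Gibbs step on the marginalised locus
likelihood. Genotypes are centred but not variance-standardised; window
variance uses realised genetic values of the saved samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from vegwas.genotype_qc import GenotypeSet


@dataclass
class BayesBConfig:
    pi: float = 0.999
    chain_length: int = 550_000
    burn_in: int = 150_000
    thin: int = 100
    prior_mean_genomic_var: float = 5.1
    prior_mean_resid_var: float = 4.3
    prior_df: float = 4.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must be in (0, 1)")
        if self.burn_in >= self.chain_length:
            raise ValueError("burn-in must be shorter than the chain")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_df <= 2:
            raise ValueError("prior_df must exceed 2 for a finite prior mean")


@dataclass
class BmmrResult:
    snp_ids: list
    p_hat: np.ndarray
    bf: np.ndarray
    post_mean_effect: np.ndarray
    saved_betas: np.ndarray  # (n_saved, m)
    saved_resvar: np.ndarray
    saved_mu: np.ndarray
    pi: float
    scaled_down: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "p_hat": self.p_hat,
                "bf": self.bf,
                "post_mean_effect": self.post_mean_effect,
            }
        )


@njit(cache=False)
def _gibbs(Zt, y, pi, nu, s2_beta, nu_e, s2_e, n_iter, burn_in, thin, seed):
    # Zt is loci x individuals (row-contiguous per locus)
    m, n = Zt.shape
    np.random.seed(seed)
    zz = np.empty(m)
    for j in range(m):
        zz[j] = np.dot(Zt[j], Zt[j])

    beta = np.zeros(m)
    delta = np.zeros(m, dtype=np.int8)
    mu = np.mean(y)
    e = y - mu
    var_e = s2_e * nu_e / (nu_e - 2.0)

    n_saved = (n_iter - burn_in + thin - 1) // thin
    saved_beta = np.zeros((n_saved, m))
    saved_resvar = np.zeros(n_saved)
    saved_mu = np.zeros(n_saved)
    incl_count = np.zeros(m, dtype=np.int64)
    log_prior_odds = np.log(1.0 - pi) - np.log(pi)

    s = 0
    for it in range(n_iter):
        # intercept
        e += mu
        mu = np.sum(e) / n + np.random.normal() * np.sqrt(var_e / n)
        e -= mu

        for j in range(m):
            if zz[j] <= 1e-12:
                continue
            # locus variance: posterior draw if included, prior draw if not
            if delta[j] == 1:
                var_j = (nu * s2_beta + beta[j] * beta[j]) / np.random.chisquare(nu + 1.0)
            else:
                var_j = nu * s2_beta / np.random.chisquare(nu)

            # marginalised inclusion odds given var_j
            r = np.dot(Zt[j], e) + zz[j] * beta[j] * delta[j]
            v0 = zz[j] * var_e
            v1 = v0 + zz[j] * zz[j] * var_j
            log_like_ratio = 0.5 * (np.log(v0) - np.log(v1)) + 0.5 * r * r * (1.0 / v0 - 1.0 / v1)
            log_odds = log_prior_odds + log_like_ratio
            p_incl = 1.0 / (1.0 + np.exp(-log_odds)) if log_odds < 35.0 else 1.0

            old = beta[j] * delta[j]
            if np.random.random() < p_incl:
                prec = zz[j] / var_e + 1.0 / var_j
                mean = (r / var_e) / prec
                beta[j] = mean + np.random.normal() / np.sqrt(prec)
                delta[j] = 1
            else:
                beta[j] = 0.0
                delta[j] = 0
            if beta[j] != old:
                diff = old - beta[j]
                for i in range(n):
                    e[i] += Zt[j, i] * diff

        sse = np.dot(e, e)
        var_e = (nu_e * s2_e + sse) / np.random.chisquare(nu_e + n)
        if not np.isfinite(var_e) or var_e <= 0.0:
            return saved_beta, saved_resvar, saved_mu, incl_count, -1

        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(m):
                saved_beta[s, j] = beta[j] * delta[j]
                incl_count[j] += delta[j]
            saved_resvar[s] = var_e
            saved_mu[s] = mu
            s += 1
    return saved_beta, saved_resvar, saved_mu, incl_count, s


def run_bayesb(pheno: pd.DataFrame | np.ndarray, gs: GenotypeSet, cfg: BayesBConfig) -> BmmrResult:
    """Run the BayesB Gibbs sampler and summarise posterior inclusion
    probabilities, Bayes factors and posterior mean effects.

    The locus-variance prior scale is solved from the prior mean genomic
    variance: E[var_j] * sum_j 2 p_j (1 - p_j) = prior_mean_genomic_var.
    """
    if isinstance(pheno, pd.DataFrame):
        aligned = gs.samples[["doe_id"]].merge(pheno, on="doe_id", how="left")
        if aligned["ve"].isna().any():
            raise ValueError("phenotype missing for some genotyped does")
        y = aligned["ve"].to_numpy(dtype=float)
    else:
        y = np.asarray(pheno, dtype=float)
    if y.size != gs.n_individuals:
        raise ValueError("phenotype length mismatch")
    if np.isnan(gs.dosages).any():
        raise ValueError("impute missing genotypes before BayesB")

    p = gs.alt_freq()
    sum2pq = float(np.sum(2.0 * p * (1.0 - p)))
    if sum2pq <= 0:
        raise ValueError("all SNPs monomorphic")
    mean_var_j = cfg.prior_mean_genomic_var / sum2pq
    s2_beta = mean_var_j * (cfg.prior_df - 2.0) / cfg.prior_df
    if s2_beta <= 0:
        raise ValueError("nonpositive prior scale")
    nu_e = 4.0
    s2_e = cfg.prior_mean_resid_var * (nu_e - 2.0) / nu_e

    Zt = np.ascontiguousarray((gs.dosages - gs.dosages.mean(axis=0)).T)
    saved_beta, saved_resvar, saved_mu, incl_count, n_saved = _gibbs(
        Zt,
        y.astype(float),
        cfg.pi,
        cfg.prior_df,
        s2_beta,
        nu_e,
        s2_e,
        cfg.chain_length,
        cfg.burn_in,
        cfg.thin,
        cfg.seed % (2**32),
    )
    if n_saved < 0:
        raise RuntimeError(
            "BayesB chain diverged (non-finite residual variance); "
            "check phenotype scaling and priors"
        )
    p_hat = incl_count / n_saved
    return BmmrResult(
        snp_ids=gs.snp_map["snp_id"].tolist(),
        p_hat=p_hat,
        bf=np.array([bayes_factor(ph, cfg.pi) for ph in p_hat]),
        post_mean_effect=saved_beta[:n_saved].mean(axis=0),
        saved_betas=saved_beta[:n_saved],
        saved_resvar=saved_resvar[:n_saved],
        saved_mu=saved_mu[:n_saved],
        pi=cfg.pi,
        scaled_down=cfg.chain_length < 550_000,
    )


def bayes_factor(p_hat: float, pi: float) -> float:
    """Posterior-to-prior odds of a locus having an effect:
    (p_hat / (1 - p_hat)) / ((1 - pi) / pi). p_hat = 1 maps to +inf."""
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must be in [0, 1]")
    if p_hat == 1.0:
        return float("inf")
    prior_odds = (1.0 - pi) / pi
    return (p_hat / (1.0 - p_hat)) / prior_odds


def window_variance(
    result: BmmrResult, gs: GenotypeSet, window_bp: int = 1_000_000
) -> pd.DataFrame:
    """Posterior mean percentage of total genomic variance per non-overlapping
    window (grid anchored at bp 1; stored half-open, 0-based internally).

    Per saved sample the window genomic value is Z_w beta_w across
    individuals and the percentage is Var(window) / Var(genome) * 100. The
    raw ratios need not sum to 100 when windows covary; a normalised column
    rescaled to sum exactly 100 is reported alongside.
    """
    Z = gs.dosages - gs.dosages.mean(axis=0)
    bp = gs.snp_map["bp"].to_numpy()
    chrom = gs.snp_map["chrom"].astype(str).to_numpy()
    win_idx = (bp - 1) // window_bp
    keys = pd.DataFrame({"chrom": chrom, "win": win_idx})
    windows = keys.drop_duplicates().sort_values(["chrom", "win"]).reset_index(drop=True)

    B = result.saved_betas
    g_total = Z @ B.T  # (n, n_saved)
    var_total = g_total.var(axis=0)
    ok = var_total > 0

    rows = []
    for _, w in windows.iterrows():
        cols = np.flatnonzero((chrom == w["chrom"]) & (win_idx == w["win"]))
        g_w = Z[:, cols] @ B[:, cols].T
        var_w = g_w.var(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(ok, var_w / np.where(ok, var_total, 1.0) * 100.0, 0.0)
        rows.append(
            {
                "chrom": w["chrom"],
                "window_start": int(w["win"] * window_bp + 1),
                "window_end": int((w["win"] + 1) * window_bp),
                "pct_genomic_var": float(pct[ok].mean()) if ok.any() else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    total = df["pct_genomic_var"].sum()
    if total > 0:
        df["pct_normalized"] = df["pct_genomic_var"] / total * 100.0
    else:
        df["pct_normalized"] = 0.0
    return df


def bmmr_significant(result: BmmrResult, bf_threshold: float = 10.0) -> list:
    """SNPs whose Bayes factor strictly exceeds the threshold."""
    return [s for s, bf in zip(result.snp_ids, result.bf) if bf > bf_threshold]
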