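"""Per-doe environmental-variance phenotype from repeated litter records.

Litter size (total number born, TNB) is first corrected for the two
systematic factors (year-season and parity-lactation status) by ordinary
least squares. The per-doe environmental variance is then the within-doe
variance of the corrected records computed with divisor n + 1, and each doe
receives the precision weight (n + 1)^2 / (2 (n - 1)).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

LITTER_COLUMNS = ["doe_id", "parity", "tnb", "yearseason", "paritylact", "population"]


def validate_litters(litters: pd.DataFrame) -> None:
    if len(litters) == 0:
        raise ValueError("empty litter table")
    missing = [c for c in LITTER_COLUMNS if c not in litters.columns]
    if missing:
        raise ValueError(f"litter table missing columns: {missing}")
    if (litters["tnb"] < 0).any():
        raise ValueError("TNB must be non-negative")
    if litters.duplicated(["doe_id", "parity"]).any():
        raise ValueError("duplicate (doe_id, parity) rows")


def precorrect_tnb(litters: pd.DataFrame) -> pd.DataFrame:
    """Return the table with a ``residual`` column: TNB minus the fitted value
    of an OLS model with intercept + year-season + parity-lactation factors
    (treatment coding, first level reference), fitted pooled over all
    populations. With a single level per factor this reduces to grand-mean
    centering.
    """
    validate_litters(litters)
    df = litters.copy()
    df["yearseason"] = df["yearseason"].astype(str)
    df["paritylact"] = df["paritylact"].astype(str)
    fit = smf.ols("tnb ~ C(yearseason) + C(paritylact)", data=df).fit()
    df["residual"] = fit.resid.to_numpy()
    return df


def compute_ve(residuals: np.ndarray) -> float:
    """Within-doe variance with divisor n + 1 (minimum-quadratic-risk form):
    sum((x_i - xbar)^2) / (n + 1), xbar the doe's own mean."""
    x = np.asarray(residuals, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("at least two parities required")
    return float(np.sum((x - x.mean()) ** 2) / (n + 1))


def compute_weight(n: int) -> float:
    """Precision weight (n + 1)^2 / (2 (n - 1)) for a doe with n parities."""
    if n < 2:
        raise ValueError("weight undefined for n < 2")
    return (n + 1) ** 2 / (2.0 * (n - 1))


def build_phenotypes(litters: pd.DataFrame) -> pd.DataFrame:
    """Pre-correct TNB and collapse to one row per doe.

    Does with fewer than two parities carry no variance information and are
    dropped with a logged count.

    Returns columns: doe_id, n, ve, weight, population, xbar.
    """
    corrected = precorrect_tnb(litters)
    rows = []
    n_dropped = 0
    for doe, grp in corrected.groupby("doe_id", sort=False):
        if len(grp) < 2:
            n_dropped += 1
            continue
        res = grp["residual"].to_numpy()
        rows.append(
            {
                "doe_id": doe,
                "n": len(grp),
                "ve": compute_ve(res),
                "weight": compute_weight(len(grp)),
                "population": grp["population"].iloc[0],
                "xbar": float(res.mean()),
            }
        )
    if n_dropped:
        logger.warning("dropped %d does with a single parity", n_dropped)
    if not rows:
        raise ValueError("no doe has two or more parities")
    return pd.DataFrame(rows)
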