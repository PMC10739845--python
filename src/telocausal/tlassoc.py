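"""Correlation of telomere phenotypes (RTL / STP) with curated
telomere-regulatory gene sets, with BH correction and covariate-adjusted
multivariable regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["correlate_trait", "adjusted_association"]


def correlate_trait(
    expr: pd.DataFrame,
    trait: pd.Series,
    gene_set: list[str],
    fdr_flag: float = 0.2,
) -> pd.DataFrame:
    """Pearson r of each curated gene's expression with the trait.

    Two-sided t-test p per gene, BH within the tested set, and a flag at
    ``q < fdr_flag``. Genes absent from the matrix or with zero variance
    (undetectable) are excluded and listed in ``attrs['excluded']``.
    """
    t = trait.reindex(expr.columns)
    if t.isna().any():
        raise ValueError("trait missing for some samples")
    excluded, rows = [], []
    for g in gene_set:
        if g not in expr.index:
            excluded.append(g)
            continue
        x = expr.loc[g].to_numpy(dtype=float)
        if x.std() == 0:
            excluded.append(g)
            continue
        r, p = stats.pearsonr(x, t.to_numpy())
        rows.append({"gene_id": g, "r": r, "p": p, "n": len(x)})
    df = pd.DataFrame(rows)
    if not df.empty:
        _, q, _, _ = multipletests(df["p"], method="fdr_bh")
        df["q"] = q
        df["significant"] = df["q"] < fdr_flag
    df.attrs["excluded"] = excluded
    return df


def adjusted_association(
    expr: pd.DataFrame,
    trait: pd.Series,
    covariates: pd.DataFrame,
    gene_set: list[str] | None = None,
) -> pd.DataFrame:
    """Gene coefficient from ``trait ~ gene + covariates`` OLS per gene."""
    genes = gene_set if gene_set is not None else list(expr.index)
    y = trait.reindex(expr.columns).to_numpy(dtype=float)
    C = covariates.reindex(expr.columns).to_numpy(dtype=float)
    if np.isnan(C).any():
        raise ValueError("covariates must be complete")
    base = np.column_stack([np.ones(len(y)), C])
    if np.linalg.matrix_rank(base) < base.shape[1]:
        raise ValueError("covariates are collinear")
    rows = []
    for g in genes:
        if g not in expr.index:
            continue
        x = expr.loc[g].to_numpy(dtype=float)
        if x.std() == 0:
            raise ValueError(f"gene {g} has zero variance")
        X = np.column_stack([base, x])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = len(y) - X.shape[1]
        sigma2 = resid @ resid / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * xtx_inv[-1, -1])
        tstat = coef[-1] / se
        rows.append(
            {
                "gene_id": g,
                "beta": float(coef[-1]),
                "se": float(se),
                "p": float(2.0 * stats.t.sf(abs(tstat), dof)),
            }
        )
    return pd.DataFrame(rows)
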