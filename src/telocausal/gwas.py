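"""Per-cohort association, fixed-effect meta-analysis, LD clumping, and
novelty classification of sentinel variants.

Summary statistics travel as DataFrames with METAL-like columns
``id, chrom, pos, a1 (effect allele), a2, eaf, beta, se, z, p, n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AMBIGUOUS_PAIRS, GenotypeMatrix

__all__ = [
    "run_gwas",
    "harmonize",
    "meta_fixed",
    "ld_clump",
    "classify_novel",
    "nearest_gene",
    "SentinelSet",
]


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of y on [1 | covariates] via least squares."""
    X = np.column_stack([np.ones(len(y)), covariates]) if covariates is not None \
        else np.ones((len(y), 1))
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def run_gwas(
    geno: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    cohort: str = "cohort0",
) -> pd.DataFrame:
    """Per-variant OLS of phenotype on dosage plus covariates.

    Implemented by residualizing both sides on the covariates (with
    intercept) and adjusting the degrees of freedom, which matches the full
    multiple regression t-statistic exactly. Constant-dosage variants get an
    NA row.
    """
    y = np.asarray(phenotype, dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype must be complete")
    C = None
    q = 0
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        q = C.shape[1]
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), C])) < q + 1:
            raise ValueError("covariates are rank deficient")
    n = len(y)
    dof = n - q - 2
    yr = _residualize(y, C)

    dos = geno.dosages.copy()
    col_mean = np.nanmean(dos, axis=0)
    nan_mask = np.isnan(dos)
    dos[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    Xr = np.column_stack([_residualize(dos[:, j], C) for j in range(dos.shape[1])])

    sxx = np.sum(Xr**2, axis=0)
    sxy = Xr.T @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = np.sum(yr**2) - beta * sxy
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    bad = sxx <= 1e-12
    beta[bad] = se[bad] = t[bad] = np.nan
    p[bad] = np.nan

    af = geno.allele_freq()
    return pd.DataFrame(
        {
            "id": geno.variants["id"],
            "chrom": geno.variants["chrom"],
            "pos": geno.variants["pos"],
            "a1": geno.variants["alt"],
            "a2": geno.variants["ref"],
            "eaf": af,
            "beta": beta,
            "se": se,
            "z": t,
            "p": p,
            "n": n,
            "cohort": cohort,
        }
    )


def harmonize(
    stats_list: list[pd.DataFrame], maf_min: float = 0.01
) -> list[pd.DataFrame]:
    """Align cohorts to shared variants with a common effect allele.

    Variants are matched on ``chrom:pos`` with identical or swapped allele
    pairs (swapped pairs get their effect sign flipped and EAF mirrored);
    strand-ambiguous A/T and C/G variants and variants below ``maf_min`` in
    any cohort are dropped; only variants present in every cohort survive
    (complete-case meta).
    """
    if not stats_list:
        raise ValueError("no cohorts supplied")
    ref = stats_list[0]
    keyed = []
    for df in stats_list:
        df = df.copy()
        df["key"] = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
        keyed.append(df.set_index("key"))
    shared = keyed[0].index
    for df in keyed[1:]:
        shared = shared.intersection(df.index)

    ref = keyed[0]
    aligned = [ref.loc[shared].copy()]
    keep = np.ones(len(shared), dtype=bool)
    for df in keyed[1:]:
        sub = df.loc[shared].copy()
        same = (sub["a1"].values == ref.loc[shared, "a1"].values) & (
            sub["a2"].values == ref.loc[shared, "a2"].values
        )
        swapped = (sub["a1"].values == ref.loc[shared, "a2"].values) & (
            sub["a2"].values == ref.loc[shared, "a1"].values
        )
        keep &= same | swapped
        flip = swapped
        sub.loc[flip, "beta"] *= -1.0
        sub.loc[flip, "z"] *= -1.0
        sub.loc[flip, "eaf"] = 1.0 - sub.loc[flip, "eaf"]
        sub.loc[flip, ["a1", "a2"]] = ref.loc[shared, ["a1", "a2"]].values[flip]
        aligned.append(sub)

    ambiguous = np.array(
        [(a, b) in AMBIGUOUS_PAIRS for a, b in zip(ref.loc[shared, "a1"],
                                                   ref.loc[shared, "a2"])]
    )
    keep &= ~ambiguous
    for sub in aligned:
        maf = np.minimum(sub["eaf"].values, 1.0 - sub["eaf"].values)
        keep &= maf >= maf_min
    return [sub.loc[keep].reset_index(drop=True) for sub in aligned]


def meta_fixed(
    stats_list: list[pd.DataFrame], scheme: str = "inverse_variance"
) -> pd.DataFrame:
    """Fixed-effect meta-analysis across harmonized cohorts.

    ``inverse_variance``: pooled beta = sum(b_i/se_i^2)/sum(1/se_i^2) with
    se = sqrt(1/sum(1/se_i^2)). ``sample_size``: pooled Z =
    sum(sqrt(N_i) Z_i)/sqrt(sum N_i). Either way Cochran's Q, its p-value and
    I^2 = max(0, (Q - df)/Q) are computed from the per-cohort betas.
    """
    if scheme not in {"inverse_variance", "sample_size"}:
        raise ValueError(f"unknown scheme {scheme!r}")
    k = len(stats_list)
    base = stats_list[0]
    betas = np.vstack([df["beta"].values for df in stats_list])
    ses = np.vstack([df["se"].values for df in stats_list])
    ns = np.vstack([df["n"].values.astype(float) for df in stats_list])
    zs = np.vstack([df["z"].values for df in stats_list])
    if scheme == "sample_size" and np.isnan(ns).any():
        raise ValueError("sample_size scheme requires N for every cohort")

    w = 1.0 / ses**2
    beta_pool = (betas * w).sum(axis=0) / w.sum(axis=0)
    se_pool = np.sqrt(1.0 / w.sum(axis=0))
    if scheme == "inverse_variance":
        z_pool = beta_pool / se_pool
    else:
        z_pool = (np.sqrt(ns) * zs).sum(axis=0) / np.sqrt(ns.sum(axis=0))
    p_pool = 2.0 * stats.norm.sf(np.abs(z_pool))

    if k > 1:
        Q = (w * (betas - beta_pool) ** 2).sum(axis=0)
        p_het = stats.chi2.sf(Q, k - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            i2 = np.where(Q > 0, np.maximum(0.0, (Q - (k - 1)) / Q), 0.0)
    else:
        Q = np.zeros(len(base))
        p_het = np.ones(len(base))
        i2 = np.zeros(len(base))

    return pd.DataFrame(
        {
            "id": base["id"],
            "chrom": base["chrom"],
            "pos": base["pos"],
            "a1": base["a1"],
            "a2": base["a2"],
            "eaf": np.vstack([df["eaf"].values for df in stats_list]).mean(axis=0),
            "beta": beta_pool,
            "se": se_pool,
            "z": z_pool,
            "p": np.clip(p_pool, np.finfo(float).tiny, 1.0),
            "n": ns.sum(axis=0).astype(int),
            "Q": Q,
            "p_het": p_het,
            "I2": i2,
            "n_studies": k,
        }
    )


@dataclass
class SentinelSet:
    sentinels: pd.DataFrame  # id, chrom, pos, p, novel
    membership: dict[str, str] = field(default_factory=dict)  # variant -> sentinel


def _ld_r2(ref: GenotypeMatrix) -> tuple[dict[str, int], np.ndarray]:
    idx = {v: j for j, v in enumerate(ref.variants["id"])}
    dos = ref.dosages
    dos = np.where(np.isnan(dos), np.nanmean(dos, axis=0, keepdims=True), dos)
    std = dos.std(axis=0)
    std[std == 0] = np.nan
    zs = (dos - dos.mean(axis=0)) / std
    return idx, zs


def ld_clump(
    meta: pd.DataFrame,
    ref: GenotypeMatrix,
    p_max: float = 5e-8,
    window_kb: float = 10_000.0,
    r2_max: float = 0.001,
) -> SentinelSet:
    """Greedy LD clumping of significant variants into sentinel loci.

    Repeatedly takes the smallest-p unassigned significant variant as a
    sentinel (ties broken by position, then id) and assigns to it every
    unassigned significant variant on the same chromosome within
    ``window_kb`` whose dosage r^2 with the sentinel exceeds ``r2_max``.
    Variants missing from the reference panel are skipped with a note.
    """
    idx, zs = _ld_r2(ref)
    sig = meta.loc[meta["p"] <= p_max].copy()
    sig = sig.sort_values(["p", "pos", "id"], kind="mergesort").reset_index(drop=True)
    sig = sig.loc[sig["id"].isin(idx)].reset_index(drop=True)

    assigned: dict[str, str] = {}
    rows = []
    n = len(zs)
    for _, row in sig.iterrows():
        if row["id"] in assigned:
            continue
        assigned[row["id"]] = row["id"]
        rows.append(row)
        zi = zs[:, idx[row["id"]]]
        near = sig.loc[
            (~sig["id"].isin(assigned))
            & (sig["chrom"] == row["chrom"])
            & (np.abs(sig["pos"] - row["pos"]) <= window_kb * 1_000)
        ]
        for _, other in near.iterrows():
            zj = zs[:, idx[other["id"]]]
            r2 = np.nan_to_num(np.dot(zi, zj) / n) ** 2
            if r2 > r2_max:
                assigned[other["id"]] = row["id"]
    sentinels = (
        pd.DataFrame(rows).reset_index(drop=True)
        if rows
        else pd.DataFrame(columns=meta.columns)
    )
    return SentinelSet(sentinels=sentinels, membership=assigned)


def classify_novel(
    sentinels: SentinelSet,
    known: list[str],
    ref: GenotypeMatrix,
    r2_known: float = 0.01,
) -> SentinelSet:
    """Flag each sentinel novel iff its r^2 with every known hit is < r2_known.

    With an empty known list, everything is novel. Sentinels absent from the
    reference panel get ``novel = NaN`` (undetermined).
    """
    idx, zs = _ld_r2(ref)
    n = len(zs)
    known_idx = [idx[v] for v in known if v in idx]
    flags = []
    for _, row in sentinels.sentinels.iterrows():
        if row["id"] not in idx:
            flags.append(np.nan)
            continue
        if not known_idx:
            flags.append(True)
            continue
        zi = zs[:, idx[row["id"]]]
        r2 = np.array(
            [np.nan_to_num(np.dot(zi, zs[:, k]) / n) ** 2 for k in known_idx]
        )
        flags.append(bool(r2.max() < r2_known))
    out = sentinels.sentinels.copy()
    out["novel"] = flags
    return SentinelSet(sentinels=out, membership=dict(sentinels.membership))


def nearest_gene(sentinels: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Nearest gene body per sentinel (distance 0 inside; ties -> smaller id)."""
    if annotation.empty:
        raise ValueError("empty gene annotation")
    out = []
    for _, row in sentinels.iterrows():
        ann = annotation.loc[annotation["chrom"].astype(str) == str(row["chrom"])]
        if ann.empty:
            ann = annotation
        d = np.maximum(ann["start"] - row["pos"], 0) + np.maximum(
            row["pos"] - ann["end"], 0
        )
        best = ann.assign(distance=d).sort_values(["distance", "gene_id"]).iloc[0]
        out.append(
            {"id": row["id"], "gene_id": best["gene_id"],
             "distance": int(best["distance"])}
        )
    return pd.DataFrame(out)
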