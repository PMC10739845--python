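"""Genotype quality control: variant filters, sample filters, relatedness,
and a BAF/LRR DNA-contamination heuristic.

The filters mirror standard array-QC practice: variants are dropped for low
call rate, low minor-allele frequency, or departure from Hardy-Weinberg
equilibrium (exact test); samples are dropped for low call rate, outlying
heterozygosity, or relatedness (method-of-moments IBD, removing one member
of each related pair). Strand-ambiguous A/T and C/G variants are flagged so
cross-cohort harmonization can drop them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import gaussian_kde

from .containers import GenotypeMatrix

__all__ = [
    "QcReport",
    "hwe_exact_test",
    "filter_variants",
    "ibd_estimate",
    "filter_samples",
    "detect_contamination",
    "filter_imputed",
]


@dataclass
class QcReport:
    variant_table: pd.DataFrame | None = None
    sample_table: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided).

    Conditions on the minor-allele count and sums the probabilities of every
    heterozygote configuration at most as probable as the observed one
    (sum-of-<=-probability convention, no mid-p). Monomorphic variants return
    p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or (n_AA + n_Aa + n_aa) < 1:
        raise ValueError("genotype counts must be nonnegative with total >= 1")
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # one allele's count
    minor = min(n_a, 2 * n - n_a)
    if minor == 0:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    hets = np.arange(minor % 2, minor + 1, 2)
    homs_minor = (minor - hets) // 2
    homs_major = n - hets - homs_minor
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(homs_minor + 1)
        - gammaln(hets + 1)
        - gammaln(homs_major + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == min(n_Aa, minor)][0]
    return float(min(probs[probs <= obs * (1 + 1e-12)].sum(), 1.0))


def _hwe_from_dosages(dosages: np.ndarray) -> np.ndarray:
    out = np.ones(dosages.shape[1])
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        out[j] = hwe_exact_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return out


def filter_variants(
    geno: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.0001,
    hwe_p_min: float = 1e-5,
) -> tuple[QcReport, GenotypeMatrix]:
    """Drop variants failing call rate, MAF, or HWE; flag strand-ambiguous ones.

    A variant is removed iff it violates at least one threshold; the report
    lists every violated reason. A/T and C/G variants are flagged
    ``ambiguous`` but not removed here (harmonization handles them).
    """
    call_rate = geno.call_rate_variants()
    maf = geno.maf()
    hwe_p = _hwe_from_dosages(geno.dosages)
    ambiguous = geno.is_ambiguous()

    reasons = []
    for j in range(geno.n_variants):
        r = []
        if call_rate[j] < call_rate_min:
            r.append("call_rate")
        if maf[j] < maf_min or np.isnan(maf[j]):
            r.append("maf")
        if hwe_p[j] < hwe_p_min:
            r.append("hwe")
        reasons.append(",".join(r))
    keep = np.array([r == "" for r in reasons])
    table = pd.DataFrame(
        {
            "id": geno.variants["id"],
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "ambiguous": ambiguous,
            "pass": keep,
            "reasons": reasons,
        }
    )
    return QcReport(variant_table=table), geno.subset(variant_idx=np.where(keep)[0])


def _ibs_expectations(p: np.ndarray):
    """Per-variant P(IBS = i | IBD = j) for a biallelic variant at freq p."""
    q = 1.0 - p
    e0_ibd0 = 2 * p**2 * q**2
    e1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e2_ibd0 = 1.0 - e0_ibd0 - e1_ibd0
    e1_ibd1 = 2 * p**2 * q + 2 * p * q**2
    e2_ibd1 = 1.0 - e1_ibd1
    return e0_ibd0, e1_ibd0, e2_ibd0, e1_ibd1, e2_ibd1


def ibd_estimate(
    geno: GenotypeMatrix, pair: tuple[int, int], min_overlap: int = 100
) -> float:
    """Method-of-moments PI_HAT for one sample pair.

    Counts observed IBS-0/1/2 over the pair's shared non-missing variants,
    compares with the frequencies expected under IBD states 0/1/2 given the
    cohort allele frequencies, and solves for the IBD-state probabilities;
    ``PI_HAT = P(IBD=1)/2 + P(IBD=2)``, truncated to [0, 1].
    """
    i, j = pair
    a, b = geno.dosages[i], geno.dosages[j]
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < min_overlap:
        import warnings

        warnings.warn(
            f"only {int(ok.sum())} overlapping variants for pair {pair}; "
            "PI_HAT undefined"
        )
        return float("nan")
    a, b = a[ok], b[ok]
    p = np.clip(geno.allele_freq()[ok], 0.01, 0.99)
    ibs = 2 - np.abs(a - b)
    n0, n1, n2 = [(ibs == k).sum() for k in (0, 1, 2)]

    e0_0, e1_0, e2_0, e1_1, e2_1 = _ibs_expectations(p)
    P0 = n0 / max(e0_0.sum(), 1e-12)
    P1 = (n1 - P0 * e1_0.sum()) / max(e1_1.sum(), 1e-12)
    P2 = (n2 - P0 * e2_0.sum() - P1 * e2_1.sum()) / ok.sum()
    # truncate only the final quantity: clipping the individual state
    # probabilities first would bias PI_HAT upward for unrelated pairs
    return float(np.clip(P1 / 2.0 + P2, 0.0, 1.0))


def filter_samples(
    geno: GenotypeMatrix,
    call_rate_min: float = 0.95,
    het_sd: float = 3.0,
    pi_hat_max: float = 0.1875,
) -> tuple[QcReport, GenotypeMatrix]:
    """Drop samples failing call rate, heterozygosity, or relatedness.

    For each related pair (PI_HAT above threshold) the lower-call-rate member
    is removed (ties broken by lexicographic sample id, removing the larger).
    Needs >= 3 samples for the heterozygosity SD.
    """
    n = geno.n_samples
    if n < 3:
        raise ValueError("need >= 3 samples to compute the heterozygosity SD")
    call_rate = geno.call_rate_samples()
    het = np.nanmean(geno.dosages == 1, axis=1)
    het_z = (het - het.mean()) / het.std() if het.std() > 0 else np.zeros(n)

    reasons: list[list[str]] = [[] for _ in range(n)]
    for i in range(n):
        if call_rate[i] < call_rate_min:
            reasons[i].append("call_rate")
        if abs(het_z[i]) > het_sd:
            reasons[i].append("het")

    pi_hat_max_obs = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            ph = ibd_estimate(geno, (i, j), min_overlap=1)
            pi_hat_max_obs[i] = max(pi_hat_max_obs[i], ph)
            pi_hat_max_obs[j] = max(pi_hat_max_obs[j], ph)
            if ph > pi_hat_max:
                if call_rate[i] < call_rate[j]:
                    drop = i
                elif call_rate[j] < call_rate[i]:
                    drop = j
                else:
                    drop = i if geno.samples[i] > geno.samples[j] else j
                if "related" not in reasons[drop]:
                    reasons[drop].append("related")

    keep = np.array([not r for r in reasons])
    table = pd.DataFrame(
        {
            "sample": geno.samples,
            "call_rate": call_rate,
            "het_z": het_z,
            "max_pi_hat": pi_hat_max_obs,
            "pass": keep,
            "reasons": [",".join(r) for r in reasons],
        }
    )
    return QcReport(sample_table=table), geno.subset(sample_idx=np.where(keep)[0])


def detect_contamination(
    het_baf: np.ndarray,
    lrr: np.ndarray | None = None,
    baf_dev_max: float = 0.07,
    dip_max: float = 0.2,
    min_het: int = 200,
) -> tuple[bool | None, float]:
    """Heuristic DNA-mixture check from heterozygous B-allele fractions.

    Pure diploid samples have het BAF tightly clustered at 0.5; a mixture of
    two genomes splits the cluster into symmetric modes (e.g. ~0.25/0.75 for
    a 50:50 mix). The score is the median absolute deviation of het BAF from
    0.5 plus the LRR variance; the flag is raised when that deviation exceeds
    ``baf_dev_max`` or when a kernel-density dip at 0.5 reveals bimodality.
    Returns ``(flag, score)``; flag is ``None`` when there are too few het
    calls to decide.
    """
    het_baf = np.asarray(het_baf, dtype=float)
    het_baf = het_baf[~np.isnan(het_baf)]
    score_lrr = float(np.nanvar(lrr)) if lrr is not None else 0.0
    if het_baf.size < min_het:
        return None, float("nan")
    dev = float(np.median(np.abs(het_baf - 0.5)))
    score = dev + score_lrr

    kde = gaussian_kde(het_baf)
    grid = np.linspace(0.2, 0.8, 121)
    dens = kde(grid)
    center = float(kde(np.array([0.5]))[0])
    off = dens[np.abs(grid - 0.5) > 0.08]
    dip = float((off.max() - center) / off.max()) if off.size and off.max() > 0 else 0.0

    flagged = bool(dev > baf_dev_max or dip > dip_max)
    return flagged, score


def filter_imputed(
    stats: pd.DataFrame, info_min: float = 0.3, maf_min: float = 0.01
) -> pd.DataFrame:
    """Post-imputation column filter on provided info scores and MAF."""
    maf = np.minimum(stats["eaf"], 1.0 - stats["eaf"])
    keep = (stats["info"] >= info_min) & (maf >= maf_min)
    return stats.loc[keep].reset_index(drop=True)
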