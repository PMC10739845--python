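"""Integration of eQTL and GWAS summary evidence into causal-gene calls.

Four lines of evidence are computed per gene and then intersected:

* **Colocalization** — approximate-Bayes-factor enumeration over the five
  standard hypotheses (no signal / eQTL only / GWAS only / two distinct
  causal variants / one shared causal variant), with a two-tier call:
  strong (PP4 >= 0.8 and PP4/PP3 >= 5) or suggestive (PP4 >= 0.5 and
  PP4/PP3 >= 3).
* **TWAS** — cis expression weights (top1 / elastic net / BLUP, gated by a
  Haseman-Elston cis-heritability test) combined with GWAS z-scores through
  the LD-aware weighted burden statistic ``Z = w'z / sqrt(w'Rw)``.
* **SMR + HEIDI** — single-instrument Mendelian randomization with the
  heterogeneity-in-dependent-instruments test to reject linkage.
* **TRS** — a per-sample transcriptional risk score summing genetically
  predicted expression weighted by TWAS Z over significant genes.

The prioritization rule is: coloc evidence (strong or suggestive) AND
(TWAS FDR < 0.1 OR SMR FDR < 0.1 with HEIDI pass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.linear_model import ElasticNetCV
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegionPair",
    "ColocResult",
    "wakefield_log_abf",
    "coloc_abf",
    "fit_twas_weights",
    "twas_assoc",
    "smr_test",
    "heidi_test",
    "compute_trs",
    "prioritize",
]


@dataclass
class RegionPair:
    """Aligned per-variant summary statistics for one gene's cis region.

    ``ld`` is the variant x variant dosage correlation matrix from a
    reference panel, in the same variant order as the statistics.
    """

    gene_id: str
    variant_ids: list[str]
    beta_eqtl: np.ndarray
    se_eqtl: np.ndarray
    beta_gwas: np.ndarray
    se_gwas: np.ndarray
    ld: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.variant_ids)
        for name in ("beta_eqtl", "se_eqtl", "beta_gwas", "se_gwas"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (m,):
                raise ValueError(f"{name} length does not match variant_ids")
            setattr(self, name, arr)
        self.ld = np.asarray(self.ld, dtype=float)
        if self.ld.shape != (m, m):
            raise ValueError("LD matrix shape mismatch")

    def z_eqtl(self) -> np.ndarray:
        return self.beta_eqtl / self.se_eqtl

    def z_gwas(self) -> np.ndarray:
        return self.beta_gwas / self.se_gwas


def regularize_ld(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Symmetrize and floor the eigenvalues so R is usable as a covariance."""
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    w = np.clip(w, eps, None)
    return V @ np.diag(w) @ V.T


def wakefield_log_abf(
    beta: np.ndarray, se: np.ndarray, prior_sd: float = 0.15
) -> np.ndarray:
    """Log approximate Bayes factor for a normal effect prior.

    With ``V = se^2``, ``W = prior_sd^2`` and ``r = W/(V + W)``:
    ``log ABF = 0.5 log(1 - r) + 0.5 z^2 r``. The ABF tends to 1 as the
    standard error grows (no information) and increases monotonically in
    ``|z|`` at fixed se.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    V = se**2
    W = prior_sd**2
    r = W / (V + W)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * z**2 * r


@dataclass
class ColocResult:
    gene_id: str
    pp: np.ndarray  # PP0..PP4
    n_variants: int
    coloc_class: str  # strong | suggestive | none
    low_resolution: bool = False

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def pp3(self) -> float:
        return float(self.pp[3])


def _classify(pp3: float, pp4: float) -> str:
    ratio = pp4 / pp3 if pp3 > 0 else np.inf
    if pp4 >= 0.8 and ratio >= 5:
        return "strong"
    if pp4 >= 0.5 and ratio >= 3:
        return "suggestive"
    return "none"


def coloc_abf(
    pair: RegionPair,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd: float = 0.15,
) -> ColocResult:
    """Enumeration colocalization over per-variant approximate Bayes factors.

    Sums variant-configuration ABFs for each hypothesis in log space:
    H1/H2 sum single-trait ABFs, H4 sums the product at the same variant,
    and H3 sums products over distinct variant pairs. Priors are per-variant
    probabilities of being causal for trait 1, trait 2, or both.
    """
    m = len(pair.variant_ids)
    if m < 1:
        raise ValueError("region must contain at least one variant")
    l1 = wakefield_log_abf(pair.beta_eqtl, pair.se_eqtl, prior_sd)
    l2 = wakefield_log_abf(pair.beta_gwas, pair.se_gwas, prior_sd)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    lh0 = 0.0
    lh1 = np.log(p1) + lsum1
    lh2 = np.log(p2) + lsum2
    lh4 = np.log(p12) + lsum12
    # H3: sum over i != j of ABF1_i * ABF2_j = (sum1)(sum2) - sum(diag)
    if m > 1:
        mx = max(lsum1 + lsum2, lsum12)
        cross = np.exp(lsum1 + lsum2 - mx) - np.exp(lsum12 - mx)
        if cross <= 0:
            lh3 = -np.inf
        else:
            lh3 = np.log(p1) + np.log(p2) + mx + np.log(cross)
    else:
        lh3 = -np.inf

    logs = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(logs - logsumexp(logs))
    pp /= pp.sum()
    return ColocResult(
        gene_id=pair.gene_id,
        pp=pp,
        n_variants=m,
        coloc_class=_classify(float(pp[3]), float(pp[4])),
        low_resolution=m < 2,
    )


# ---------------------------------------------------------------------------
# TWAS


@dataclass
class TwasWeights:
    gene_id: str
    variant_ids: list[str]
    weights: np.ndarray
    cis_h2: float
    h2_p: float
    method: str


def _haseman_elston_h2(
    y: np.ndarray, Z: np.ndarray, n_perm: int = 200, seed: int = 0
) -> tuple[float, float]:
    """cis heritability by Haseman-Elston regression with a permutation p.

    Regresses off-diagonal products of the standardized phenotype on the
    off-diagonal cis GRM entries; the slope estimates h2. The p-value is the
    fraction of label permutations with at least as large a slope.
    """
    ys = (y - y.mean()) / y.std()
    A = Z @ Z.T / Z.shape[1]
    iu = np.triu_indices(len(y), k=1)
    a = A[iu]
    denom = float(a @ a)
    if denom <= 0:
        return 0.0, 1.0
    diag = np.diag(A)

    def slope(yv: np.ndarray) -> float:
        # sum over i<j of A_ij y_i y_j, via the quadratic form
        return float(0.5 * (yv @ A @ yv - diag @ yv**2) / denom)

    obs = slope(ys)
    rng = np.random.default_rng(seed)
    count = sum(slope(rng.permutation(ys)) >= obs for _ in range(n_perm))
    return obs, (1 + count) / (n_perm + 1)


def fit_twas_weights(
    expr_row: np.ndarray,
    cis_geno: np.ndarray,
    variant_ids: list[str],
    covariates: np.ndarray | None = None,
    method: str = "top1",
    gene_id: str = "",
    h2_p_max: float = 0.01,
    seed: int = 0,
) -> TwasWeights | None:
    """Fit cis expression weights for one gene, gated by a heritability test.

    Returns ``None`` when the gene fails the cis-h2 gate (permutation
    p > ``h2_p_max``). Methods: ``top1`` (single best marginal variant),
    ``elastic_net`` (cross-validated), ``blup`` (ridge with lambda set by
    the h2 estimate).
    """
    y = np.asarray(expr_row, dtype=float)
    X = np.asarray(cis_geno, dtype=float)
    if X.shape[1] == 0:
        return None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        M = np.column_stack([np.ones(len(y)), C])
        H = M @ np.linalg.pinv(M)
        y = y - H @ y
        X = X - H @ X
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    if y.std() == 0:
        return None

    h2, h2_p = _haseman_elston_h2(y, Z, seed=seed)
    if h2_p > h2_p_max:
        return None

    ys = (y - y.mean()) / y.std()
    if method == "top1":
        r = Z.T @ ys / len(ys)
        w = np.zeros(Z.shape[1])
        k = int(np.argmax(np.abs(r)))
        w[k] = r[k]
    elif method == "elastic_net":
        model = ElasticNetCV(l1_ratio=0.5, cv=5, random_state=seed, n_alphas=30)
        model.fit(Z, ys)
        w = model.coef_
        if not np.any(w):
            r = Z.T @ ys / len(ys)
            k = int(np.argmax(np.abs(r)))
            w = np.zeros(Z.shape[1])
            w[k] = r[k]
    elif method == "blup":
        m = Z.shape[1]
        h2c = float(np.clip(h2, 0.01, 0.99))
        lam = m * (1.0 - h2c) / h2c
        w = np.linalg.solve(Z.T @ Z + lam * np.eye(m), Z.T @ ys)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TwasWeights(gene_id, list(variant_ids), w, float(h2), float(h2_p), method)


def twas_assoc(
    weights: np.ndarray, gwas_z: np.ndarray, ld: np.ndarray
) -> tuple[float, float]:
    """LD-aware weighted burden statistic ``Z = w'z / sqrt(w'R w)``."""
    w = np.asarray(weights, dtype=float)
    z = np.asarray(gwas_z, dtype=float)
    R = np.asarray(ld, dtype=float)
    denom = float(w @ R @ w)
    if denom <= 1e-12:
        raise ValueError("w'Rw is not positive; association undefined")
    Z = float(w @ z / np.sqrt(denom))
    return Z, float(2.0 * stats.norm.sf(abs(Z)))


def twas_table(results: list[dict], fdr: float = 0.1) -> pd.DataFrame:
    """Assemble per-gene TWAS rows and add BH q-values across tested genes."""
    df = pd.DataFrame(results)
    if df.empty:
        return df
    _, q, _, _ = multipletests(df["p"], method="fdr_bh")
    df["q"] = q
    df["significant"] = df["q"] < fdr
    return df


# ---------------------------------------------------------------------------
# SMR + HEIDI


def smr_test(
    beta_eqtl: float, se_eqtl: float, beta_gwas: float, se_gwas: float
) -> tuple[float, float, float]:
    """Single-instrument Mendelian randomization via summary statistics.

    ``b_xy = beta_gwas / beta_eqtl`` estimates the effect of a 1-unit
    expression change on the trait; the test statistic is
    ``T = z_g^2 z_e^2 / (z_g^2 + z_e^2)`` referred to chi-square(1).
    Returns ``(b_xy, T, p)``.
    """
    if beta_eqtl == 0:
        raise ValueError("eQTL effect is zero; instrument undefined")
    z_e = beta_eqtl / se_eqtl
    z_g = beta_gwas / se_gwas
    b_xy = beta_gwas / beta_eqtl
    denom = z_g**2 + z_e**2
    T = (z_g**2 * z_e**2) / denom if denom > 0 else 0.0
    return float(b_xy), float(T), float(stats.chi2.sf(T, 1))


def heidi_test(
    pair: RegionPair,
    top: int | None = None,
    r2_keep: tuple[float, float] = (0.05, 0.90),
    max_snps: int = 20,
) -> tuple[float, int]:
    """Heterogeneity-in-dependent-instruments test against linkage.

    Anchored at the top-|z_eQTL| variant (or ``top``), compares the
    Wald-ratio estimate ``b_xy`` at every eligible cis variant (LD r^2 with
    the anchor inside ``r2_keep``, capped at ``max_snps`` by descending
    eQTL |z|) with the anchor's estimate. The differences' covariance comes
    from the delta method with LD; the summed squared standardized
    differences are referred to a Satterthwaite-scaled chi-square. Small p
    means heterogeneity, i.e. linkage rather than a shared causal variant.
    Returns ``(p_heidi, n_snps_used)``; with fewer than 3 eligible variants
    the test is undefined and returns ``(nan, n)``.
    """
    z_e = pair.z_eqtl()
    if top is None:
        top = int(np.argmax(np.abs(z_e)))
    R = pair.ld
    r2 = R[top] ** 2
    lo, hi = r2_keep
    eligible = np.where((r2 >= lo) & (r2 <= hi) & (np.arange(len(r2)) != top))[0]
    if eligible.size > max_snps:
        order = np.argsort(-np.abs(z_e[eligible]), kind="mergesort")
        eligible = eligible[order[:max_snps]]
    if eligible.size < 3:
        return float("nan"), int(eligible.size)

    be, se_e = pair.beta_eqtl, pair.se_eqtl
    bg, se_g = pair.beta_gwas, pair.se_gwas
    bxy = bg / be
    idx = np.concatenate([[top], eligible])

    # delta-method covariance of b_xy across instruments (LD-correlated GWAS
    # and eQTL estimates; SMR-style approximation)
    m = idx.size
    cov = np.empty((m, m))
    for a in range(m):
        for b in range(m):
            i, j = idx[a], idx[b]
            r = R[i, j]
            cov[a, b] = (
                r * se_g[i] * se_g[j] / (be[i] * be[j])
                + r**2 * bxy[i] * bxy[j] / (z_e[i] * z_e[j])
            )
    d = bxy[idx[1:]] - bxy[top]
    cov_d = (
        cov[1:, 1:]
        - cov[1:, [0]]
        - cov[[0], 1:]
        + cov[0, 0]
    )
    cov_d = regularize_ld(cov_d, eps=1e-6 * max(np.abs(np.diag(cov_d)).max(), 1e-12))
    var_d = np.clip(np.diag(cov_d), 1e-300, None)
    zd = d / np.sqrt(var_d)
    T = float(zd @ zd)

    # null: sum of correlated chi-squares; Satterthwaite moment matching
    corr = cov_d / np.sqrt(np.outer(var_d, var_d))
    E = float(len(d))
    V = 2.0 * float((corr**2).sum())
    g = V / (2.0 * E)
    h = 2.0 * E**2 / V
    return float(stats.chi2.sf(T / g, h)), int(eligible.size)


def compute_trs(
    predicted_expr: pd.DataFrame, twas: pd.DataFrame, significant_only: bool = True
) -> pd.Series:
    """Transcriptional risk score: TWAS-Z-weighted genetic expression values.

    ``predicted_expr`` is samples x genes of genotype-predicted expression
    (standardized per gene); ``twas`` needs ``gene_id, z`` and a
    ``significant`` flag. Genes are weighted by their TWAS Z; by default
    only FDR-significant genes contribute.
    """
    use = twas.loc[twas["significant"]] if significant_only else twas
    genes = [g for g in use["gene_id"] if g in predicted_expr.columns]
    if not genes:
        import warnings

        warnings.warn("no significant TWAS genes; TRS is a zero vector")
        return pd.Series(0.0, index=predicted_expr.index, name="TRS")
    zmap = use.set_index("gene_id")["z"]
    X = predicted_expr[genes].to_numpy()
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    score = Xs @ zmap.loc[genes].to_numpy()
    return pd.Series(score, index=predicted_expr.index, name="TRS")


def prioritize(
    coloc: list[ColocResult],
    twas: pd.DataFrame,
    smr: pd.DataFrame,
    twas_fdr: float = 0.1,
    smr_fdr: float = 0.1,
    heidi_min: float = 0.01,
) -> pd.DataFrame:
    """The causal-gene call: coloc evidence AND (TWAS OR SMR+HEIDI) evidence.

    ``smr`` needs ``gene_id, p_smr, p_heidi``; a gene passes SMR when its BH
    q over tested genes is below ``smr_fdr`` and HEIDI does not reject
    (``p_heidi >= heidi_min`` or undefined). The returned table keeps the
    per-method evidence for every gene seen by any method.
    """
    coloc_map = {c.gene_id: c for c in coloc}
    genes = sorted(
        set(coloc_map)
        | set(twas["gene_id"] if not twas.empty else [])
        | set(smr["gene_id"] if not smr.empty else [])
    )
    smr = smr.copy()
    if not smr.empty:
        _, q, _, _ = multipletests(smr["p_smr"], method="fdr_bh")
        smr["q_smr"] = q
        heidi_ok = smr["p_heidi"].isna() | (smr["p_heidi"] >= heidi_min)
        smr["smr_pass"] = (smr["q_smr"] < smr_fdr) & heidi_ok
        smr_map = smr.set_index("gene_id")
    else:
        smr_map = pd.DataFrame()
    twas_map = twas.set_index("gene_id") if not twas.empty else pd.DataFrame()

    rows = []
    for g in genes:
        c = coloc_map.get(g)
        coloc_class = c.coloc_class if c else "none"
        twas_sig = bool(
            g in twas_map.index and twas_map.loc[g, "q"] < twas_fdr
        )
        smr_sig = bool(g in smr_map.index and smr_map.loc[g, "smr_pass"])
        rows.append(
            {
                "gene_id": g,
                "pp4": c.pp4 if c else np.nan,
                "pp3": c.pp3 if c else np.nan,
                "coloc_class": coloc_class,
                "twas_z": float(twas_map.loc[g, "z"]) if g in getattr(twas_map, "index", []) else np.nan,
                "twas_q": float(twas_map.loc[g, "q"]) if g in getattr(twas_map, "index", []) else np.nan,
                "smr_q": float(smr_map.loc[g, "q_smr"]) if g in getattr(smr_map, "index", []) else np.nan,
                "p_heidi": float(smr_map.loc[g, "p_heidi"]) if g in getattr(smr_map, "index", []) else np.nan,
                "causal": coloc_class in {"strong", "suggestive"}
                and (twas_sig or smr_sig),
            }
        )
    return pd.DataFrame(rows)
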