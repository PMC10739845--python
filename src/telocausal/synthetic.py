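"""Synthetic cohorts with planted ground truth.

Every generator here is a pure function of its arguments (including the
seed), so downstream recovery tests can compare estimates against the
:class:`~telocausal.containers.TruthSet` that produced the data.

The generative model, in brief:

* **Genotypes** — haplotypes from a latent Gaussian AR(1) copying process
  inside fixed-size blocks, thresholded at the allele frequency, so within-
  block LD is tunable (``ld_rho``) and cross-block LD is zero.
* **Expression** — per-module latent factors plus planted cis-eQTL dosage
  effects on the log scale; read counts are negative binomial around
  library-size-scaled means, and TPM is recomputed from the counts.
* **TL phenotype** — genetic score + expression score + Gaussian noise, with
  each component rescaled to its target variance fraction in-sample.
* **TRF gel lanes** — a unimodal fragment-length density mapped through a
  log-linear migration model; the probe binds proportionally to fragment
  length, so lane intensity carries an explicit x-length bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix, LaneProfile, TruthSet

__all__ = [
    "GelConfig",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_tl",
    "simulate_cohort_stats",
    "simulate_trf_lanes",
    "simulate_region_pair",
]

# non-ambiguous ref/alt pairs cycled over variants
_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    block_size: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    ld_rho: float = 0.8,
    chrom: str = "1",
    start_pos: int = 10_000,
    spacing: int = 5_000,
) -> GenotypeMatrix:
    """Simulate hard-call diploid genotypes with block LD structure.

    Haplotype alleles are generated by thresholding a latent AR(1) Gaussian
    process restarted at every block boundary: ``z_j = rho z_{j-1} +
    sqrt(1-rho^2) e_j`` and allele ``= 1`` iff ``z_j < Phi^{-1}(p_j)``, which
    preserves the marginal allele frequency ``p_j`` exactly while inducing
    within-block correlation that rises with ``ld_rho``.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if not (1 <= block_size <= n_variants):
        raise ValueError("block_size must be in [1, n_variants]")
    if not (0.0 <= ld_rho <= 1.0):
        raise ValueError("ld_rho must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_variants)
    thresh = stats.norm.ppf(p)

    n_hap = 2 * n_samples
    z = np.empty((n_hap, n_variants))
    innov = rng.standard_normal((n_hap, n_variants))
    carry = np.sqrt(max(0.0, 1.0 - ld_rho**2))
    for j in range(n_variants):
        if j % block_size == 0:
            z[:, j] = innov[:, j]
        else:
            z[:, j] = ld_rho * z[:, j - 1] + carry * innov[:, j]
    haplo = (z < thresh).astype(np.int8)
    dosage = (haplo[0::2] + haplo[1::2]).astype(float)

    alleles = [_ALLELE_CYCLE[j % len(_ALLELE_CYCLE)] for j in range(n_variants)]
    variants = pd.DataFrame(
        {
            "id": [f"snp{j:06d}" for j in range(n_variants)],
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(n_variants),
            "ref": [a[0] for a in alleles],
            "alt": [a[1] for a in alleles],
        }
    )
    samples = [f"sample{i:04d}" for i in range(n_samples)]
    return GenotypeMatrix(dosage, variants, samples)


def _module_factor_matrix(
    gene_modules: pd.Series, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Latent factor value per gene x sample according to module membership."""
    labels = gene_modules.unique()
    factors = {m: rng.standard_normal(n_samples) for m in labels}
    return np.vstack([factors[m] for m in gene_modules])


def simulate_expression(
    geno: GenotypeMatrix,
    truth: TruthSet,
    n_genes: int,
    n_modules: int = 3,
    seed: int = 0,
    module_loading: float = 1.0,
    noise_sd: float = 1.0,
    dispersion: float = 0.1,
    lib_size_range: tuple[float, float] = (8e6, 12e6),
    gene_length: int = 1_000,
) -> ExpressionMatrix:
    """Simulate counts and TPM with module structure and planted cis-eQTLs.

    Log-scale expression per gene is ``loading * module_factor + eQTL dosage
    effects + noise``; the systematic part is standardised to unit variance
    before the eQTL term is added so planted ``beta_eqtl`` values are in SD
    units of expression per effect allele. Counts are negative binomial
    (gamma-Poisson) with a single dispersion knob; TPM is recomputed from the
    counts so the two matrices are mutually consistent.
    """
    if n_modules > n_genes:
        raise ValueError("n_modules cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    n_samples = geno.n_samples

    gene_ids = [f"gene{g:04d}" for g in range(n_genes)]
    if truth.module_assignments:
        modules = pd.Series(
            [truth.module_assignments.get(g, "module0") for g in gene_ids],
            index=gene_ids,
        )
    else:
        modules = pd.Series(
            [f"module{g % n_modules}" for g in range(n_genes)], index=gene_ids
        )

    # spread TSS across the genotyped span so planted eQTLs can sit in cis
    pos = geno.variants["pos"].to_numpy()
    span_lo, span_hi = int(pos.min()), int(pos.max())
    tss = np.linspace(span_lo, span_hi, n_genes).astype(int)
    strand = np.where(np.arange(n_genes) % 2 == 0, "+", "-")
    body = 10_000
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": geno.variants["chrom"].iloc[0],
            "start": np.where(strand == "+", tss, np.maximum(tss - body + 1, 1)),
            "end": np.where(strand == "+", tss + body - 1, tss),
            "strand": strand,
            "tss": tss,
            "module": modules.to_numpy(),
        }
    )

    factor = _module_factor_matrix(modules, n_samples, rng)
    base = module_loading * factor + noise_sd * rng.standard_normal((n_genes, n_samples))
    base /= np.sqrt(module_loading**2 + noise_sd**2)

    # plant eQTL effects so beta is exact in units of the gene's total SD:
    # shrink the non-genetic part to keep total variance at 1
    var_idx = {v: j for j, v in enumerate(geno.variants["id"])}
    gene_idx = {g: i for i, g in enumerate(gene_ids)}
    genetic_part = np.zeros_like(base)
    for vid, gid, beta in truth.planted_eqtls:
        if vid not in var_idx or gid not in gene_idx:
            raise ValueError(f"planted eQTL ({vid}, {gid}) not present in inputs")
        dos = geno.dosages[:, var_idx[vid]]
        genetic_part[gene_idx[gid]] += beta * (dos - np.nanmean(dos))
    # anticipated log2-scale measurement noise of the NB counting process
    # (delta method), so the measured expression has ~unit variance and the
    # planted slope survives normalization unattenuated
    mu = rng.uniform(2.0, 8.0, size=n_genes)
    lib_mean = float(np.mean(lib_size_range))
    approx_count = lib_mean * np.power(2.0, mu) / np.power(2.0, mu).sum()
    var_meas = (dispersion + 1.0 / np.clip(approx_count, 1.0, None)) / np.log(2) ** 2

    gvar = genetic_part.var(axis=1)
    shrink = np.sqrt(np.clip(1.0 - gvar - var_meas, 0.0, None))
    base = shrink[:, None] * base + genetic_part
    log2_tpm = mu[:, None] + base
    rel = np.power(2.0, log2_tpm)
    rel /= rel.sum(axis=0, keepdims=True)

    lib = rng.uniform(*lib_size_range, size=n_samples)
    mean_counts = rel * lib[None, :]
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean_counts * dispersion)
    counts = rng.poisson(lam).astype(float)

    samples = list(geno.samples)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    rate = counts / gene_length
    tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6
    tpm_df = pd.DataFrame(tpm, index=gene_ids, columns=samples)
    return ExpressionMatrix(counts_df, tpm_df, genes)


def _scaled(term: np.ndarray, target_var: float) -> np.ndarray:
    sd = term.std()
    if sd == 0:
        raise ValueError("component with zero variance cannot carry signal")
    return term / sd * np.sqrt(target_var)


def simulate_tl(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix | None,
    truth: TruthSet,
    seed: int = 0,
    mean_age: float = 32.0,
    sd_age: float = 4.0,
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Simulate the TL phenotype from planted variant and expression effects.

    Returns ``(tl, covariates, constants)`` where ``tl`` is standardized
    (unit variance in-sample), covariates hold infant sex and maternal age
    (independent of TL by default), and ``constants`` records the scaling
    applied to each component so tests can reconstruct the decomposition.
    """
    rng = np.random.default_rng(seed)
    n = geno.n_samples

    genetic = np.zeros(n)
    if truth.h2_snp > 0:
        if not truth.causal_variants:
            raise ValueError("h2_snp > 0 but no causal variants planted")
        var_idx = {v: j for j, v in enumerate(geno.variants["id"])}
        raw = np.zeros(n)
        for vid, beta in truth.causal_variants:
            if vid not in var_idx:
                raise ValueError(f"causal variant {vid} absent from genotypes")
            raw += beta * geno.dosages[:, var_idx[vid]]
        genetic = _scaled(raw - raw.mean(), truth.h2_snp)

    expression = np.zeros(n)
    if truth.var_expr > 0:
        if expr is None or not truth.causal_genes:
            raise ValueError("var_expr > 0 but no causal genes/expression given")
        logtpm = np.log2(expr.tpm.to_numpy() + 1.0)
        z = (logtpm - logtpm.mean(axis=1, keepdims=True)) / logtpm.std(
            axis=1, keepdims=True
        )
        gidx = {g: i for i, g in enumerate(expr.gene_ids)}
        raw = np.zeros(n)
        for gid, beta in truth.causal_genes:
            if gid not in gidx:
                raise ValueError(f"causal gene {gid} absent from expression")
            raw += beta * z[gidx[gid]]
        expression = _scaled(raw - raw.mean(), truth.var_expr)

    noise_var = 1.0 - truth.h2_snp - truth.var_expr
    noise = rng.standard_normal(n)
    noise = (
        _scaled(noise - noise.mean(), noise_var) if noise_var > 0 else np.zeros(n)
    )
    tl = genetic + expression + noise

    covariates = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n).astype(float),
            "maternal_age": rng.normal(mean_age, sd_age, size=n),
        },
        index=geno.samples,
    )
    constants = {
        "genetic_var": float(genetic.var()),
        "expression_var": float(expression.var()),
        "noise_var": float(noise.var()),
        "genetic_score": genetic,
        "expression_score": expression,
    }
    return tl, covariates, constants


def simulate_cohort_stats(
    truth: TruthSet,
    cohorts: list[tuple[int, float, float]],
    panel: GenotypeMatrix,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Draw per-cohort GWAS summary statistics from the sampling distribution.

    ``cohorts`` is a list of ``(n, allele_freq_shift, heterogeneity)``. Each
    cohort's marginal effect at variant *i* is ``sum_j C_ij b_j / C_ii`` with
    ``C`` the dosage covariance from ``panel`` (so LD leaks causal signal to
    tagging variants), where causal effects ``b_j`` are perturbed per cohort
    by ``heterogeneity``-scaled Gaussian noise. Estimates are drawn as
    ``beta_hat ~ N(beta_marginal, se^2)`` with the OLS standard error at the
    cohort's sample size. ``heterogeneity = 0`` means all cohorts share one
    effect mean; a null variant's Z is standard normal.
    """
    if len(cohorts) < 1:
        raise ValueError("need at least one cohort")
    for n, _, _ in cohorts:
        if n < 10:
            raise ValueError("cohort sample size must be >= 10")
    rng = np.random.default_rng(seed)

    dos = panel.dosages
    dos = np.where(np.isnan(dos), np.nanmean(dos, axis=0, keepdims=True), dos)
    C = np.cov(dos, rowvar=False)
    C = np.atleast_2d(C)
    var_i = np.clip(np.diag(C), 1e-8, None)

    var_idx = {v: j for j, v in enumerate(panel.variants["id"])}
    b = np.zeros(panel.n_variants)
    for vid, beta in truth.causal_variants:
        if vid not in var_idx:
            raise ValueError(f"causal variant {vid} absent from panel")
        b[var_idx[vid]] = beta

    af = panel.allele_freq()
    out = []
    for c, (n, af_shift, het) in enumerate(cohorts):
        b_c = b.copy()
        nz = b_c != 0
        if het > 0 and nz.any():
            b_c[nz] *= 1.0 + het * rng.standard_normal(nz.sum())
        beta_marg = (C @ b_c) / var_i
        var_y = max(float(b_c @ C @ b_c) + 1.0, 1e-6)
        se = np.sqrt(var_y / (n * var_i))
        beta_hat = beta_marg + se * rng.standard_normal(panel.n_variants)
        z = beta_hat / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        eaf = np.clip(af + af_shift, 0.01, 0.99)
        df = pd.DataFrame(
            {
                "id": panel.variants["id"],
                "chrom": panel.variants["chrom"],
                "pos": panel.variants["pos"],
                "a1": panel.variants["alt"],
                "a2": panel.variants["ref"],
                "eaf": eaf,
                "beta": beta_hat,
                "se": se,
                "z": z,
                "p": np.clip(p, np.finfo(float).tiny, 1.0),
                "n": n,
                "cohort": f"cohort{c}",
            }
        )
        out.append(df)
    return out


@dataclass
class GelConfig:
    """Physical model of one southern-blot gel.

    ``migration`` holds the coefficients ``(c0, c1)`` of the log-linear
    migration map ``distance = c0 + c1 * log10(size_bp)`` with ``c1 < 0``
    (larger fragments migrate less). Defaults span roughly 2-48 kb over a
    500-pixel lane, a realistic window for TRF smears.
    """

    ladder_sizes: list[float] = field(
        default_factory=lambda: [48502.0, 21226.0, 9416.0, 6557.0, 4361.0, 2322.0]
    )
    migration: tuple[float, float] = (1508.6, -314.7)
    noise_sd: float = 1.5
    background_level: float = 5.0
    lane_length: int = 500

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.migration[1] >= 0:
            raise ValueError("migration slope must be negative")
        if sorted(self.ladder_sizes, reverse=True) != list(self.ladder_sizes):
            raise ValueError("ladder_sizes must be strictly decreasing")

    def distance_of(self, size_bp):
        c0, c1 = self.migration
        return c0 + c1 * np.log10(np.asarray(size_bp, dtype=float))

    def size_at(self, distance):
        c0, c1 = self.migration
        return np.power(10.0, (np.asarray(distance, dtype=float) - c0) / c1)


def simulate_trf_lanes(
    true_mean_tl: list[float],
    spread: float,
    gel: GelConfig | None = None,
    reference_tl: float = 6_000.0,
    seed: int = 0,
    total_signal: float = 1e4,
) -> tuple[LaneProfile, list[LaneProfile], list[bool]]:
    """Simulate a ladder lane plus a reference lane and sample lanes.

    Fragment abundance for each lane is a Gaussian density in fragment length
    centred on the lane's true mean TL with SD ``spread``; lane intensity at
    a pixel is ``background + noise + abundance x length x |dL/dpixel|`` —
    the x-length factor models the telomere probe binding more copies to
    longer fragments. Returns ``(ladder_lane, lanes, out_of_range_flags)``
    where ``lanes[0]`` is always the reference lane.
    """
    gel = gel or GelConfig()
    rng = np.random.default_rng(seed)
    pixels = np.arange(1.0, gel.lane_length + 1.0)
    sizes = gel.size_at(pixels)
    # Jacobian of the pixel->length map: fragment mass per pixel bin
    jac = np.abs(np.gradient(sizes, pixels))

    lo, hi = min(gel.ladder_sizes), max(gel.ladder_sizes)
    flags: list[bool] = []

    def sample_lane(tl: float, lane_id: str, is_reference: bool) -> LaneProfile:
        dens = stats.norm.pdf(sizes, loc=tl, scale=max(spread, 1e-6))
        signal = dens * sizes * jac
        tot = signal.sum()
        if tot > 0:
            signal = signal / tot * total_signal
        else:
            # spread below the pixel grid: a single sharp band
            signal = np.zeros_like(signal)
            signal[int(np.argmin(np.abs(sizes - tl)))] = total_signal
        intensity = (
            gel.background_level
            + signal
            + gel.noise_sd * rng.standard_normal(gel.lane_length)
        )
        flags.append(not (lo <= tl <= hi))
        return LaneProfile(lane_id, pixels, np.clip(intensity, 0.0, None),
                           is_reference=is_reference)

    ladder_int = np.full(gel.lane_length, gel.background_level)
    for s in gel.ladder_sizes:
        d = gel.distance_of(s)
        ladder_int = ladder_int + 100.0 * np.exp(-0.5 * ((pixels - d) / 1.5) ** 2)
    ladder_int = ladder_int + gel.noise_sd * rng.standard_normal(gel.lane_length)
    ladder = LaneProfile("ladder", pixels, np.clip(ladder_int, 0.0, None),
                         is_ladder=True)

    lanes = [sample_lane(reference_tl, "reference", True)]
    for i, tl in enumerate(true_mean_tl):
        lanes.append(sample_lane(tl, f"lane{i + 1:03d}", False))
    return ladder, lanes, flags


def simulate_region_pair(
    shared: bool,
    seed: int = 0,
    n_variants: int = 50,
    ld_rho: float = 0.9,
    z_eqtl: float = 8.0,
    z_gwas: float = 8.0,
    distinct_r2: float = 0.01,
    n_panel: int = 400,
    se_eqtl: float = 0.015,
    se_gwas: float = 0.0125,
):
    """Aligned eQTL + GWAS summary statistics for one cis region.

    Simulates an LD block, plants one causal variant for the eQTL trait at
    the block centre and either the same variant (``shared=True``) or the
    variant whose r^2 with the centre is closest to ``distinct_r2``
    (``shared=False``) for the GWAS trait, then draws marginal effect
    estimates from the correct sampling distribution: means proportional to
    the LD row of the causal variant, noise multivariate normal with the LD
    correlation. ``z_eqtl`` / ``z_gwas`` set the causal variant's expected
    z-score. Returns an :class:`~telocausal.integrate.RegionPair`.
    """
    from .integrate import RegionPair, regularize_ld

    rng = np.random.default_rng(seed)
    g = simulate_genotypes(n_panel, n_variants, n_variants, seed=seed, ld_rho=ld_rho)
    R = regularize_ld(np.corrcoef(g.dosages, rowvar=False))
    L = np.linalg.cholesky(R)
    c1 = n_variants // 2
    if shared:
        c2 = c1
    else:
        r2 = R[c1] ** 2
        c2 = int(np.argmin(np.abs(r2 - distinct_r2)))
    se_e = np.full(n_variants, se_eqtl)
    se_g = np.full(n_variants, se_gwas)
    beta_e = z_eqtl * se_eqtl * R[:, c1] + se_e * (L @ rng.standard_normal(n_variants))
    beta_g = z_gwas * se_gwas * R[:, c2] + se_g * (L @ rng.standard_normal(n_variants))
    return RegionPair(
        "geneR", list(g.variants["id"]), beta_e, se_e, beta_g, se_g, R
    )
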