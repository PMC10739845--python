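# Methods

This note documents the models behind each `telocausal` module, the
synthetic-data generators and what they do and do not emulate, the tunable
parameters with their defaults, and the numerical and design choices made
where the design was genuinely open.

## Synthetic cohorts (`telocausal.synthetic`)

Every generator is a pure function of its arguments including the seed, so
all downstream recovery claims are testable against the `TruthSet` that
produced the data.

**Genotypes.** Haplotypes come from a latent Gaussian AR(1) process
restarted at every block boundary: `z_j = ρ z_{j-1} + √(1−ρ²) ε_j`, allele
`= 1` iff `z_j < Φ⁻¹(p_j)`. Thresholding preserves each marginal allele
frequency `p_j ~ U(maf_range)` exactly while the copying parameter `ρ`
(default 0.8) tunes within-block LD; cross-block LD is exactly zero in the
generative law (finite panels still show noise-level r², which matters for
clumping — see below). Dosages are hard calls 0/1/2. Default MAF range
(0.05, 0.5) reflects a post-QC common-variant panel. This is a cartoon of
LD — no recombination maps, no population structure, no imputation
uncertainty — so tests of clumping and HEIDI show correctness of the
algorithms under tunable LD, not performance on human LD maps.

**Expression.** Log-scale expression is `loading × module_factor + planted
eQTL effects + noise`, mapped onto a log2-TPM baseline `U(2, 8)`, converted
to negative-binomial counts (gamma–Poisson, one dispersion knob, default
0.1 — typical bulk RNA-seq overdispersion) at library sizes `U(8M, 12M)`,
and TPM is recomputed from the counts so the two matrices are consistent.
Planted `beta_eqtl` values are calibrated in SD units of *measured*
expression: the non-genetic part is shrunk by the genetic variance **and**
the anticipated delta-method counting noise `(φ + 1/μ̄)/ln²2`, so that a
naive regression of normalized expression on dosage is unbiased for the
planted value (verified to ±0.05 over 50 seeds at n = 500). Genes pass the
expression filter (TPM ≥ 0.1 and count ≥ 6 in ≥ 20% of samples) by
construction at these baselines.

**TL phenotype.** `TL = genetic score + expression score + noise`, each
component rescaled in-sample so the realized variance fractions equal
`h2_snp` and `var_expr` exactly; covariates (infant sex, maternal age
N(32, 4²) — matching a typical birth-cohort demographic) are independent of
TL by default, since no strong demographic associations are expected at
birth.

**Cohort summary statistics.** Rather than simulating individual-level
cohorts of hundreds of thousands, per-variant estimates are drawn from the
sampling distribution of the marginal regression: the marginal effect is
`(C b)_i / C_ii` with `C` the dosage covariance of a reference panel (so LD
leaks causal signal into tags), `se_i = √(var_y/(n C_ii))`, and
`β̂ ~ N(β_marginal, se²)`. Heterogeneity multiplies causal effects by
`1 + h·N(0,1)` per cohort; `h = 0` gives one shared effect mean, and a null
variant's Z is standard normal (KS-checked).

**TRF lanes.** Fragment abundance is a Gaussian density in fragment length
centred on the lane's true mean TL (default spread 1200 bp, a realistic
smear width); migration follows `distance = c0 + c1·log10(size)` spanning
~2–48 kb over a 500-pixel lane; pixel intensity is `background + noise +
abundance × length × |dL/dpixel|` — the ×length factor models the telomere
probe hybridizing proportionally to fragment length. The ladder lane has
sharp peaks at six sizes from 48.5 kb to 2.3 kb. Smile/partial-digestion
artifacts and 2-D gel images are not modelled.

## TRF quantification (`telocausal.trf`)

Calibration detects ladder peaks (local maxima above a rolling-minimum
baseline) and fits `log10(size)` linearly on migration distance; the valid
range is the ladder's span and signal outside it is clipped with the
clipped fraction reported (extrapolating beyond the ladder is unreliable).
Lane quantification: (i) rolling-minimum background over a window of 10%
of the lane; (ii) pixel→length via the calibration; (iii) probe-bias
correction `a_i = OD_i / L_i`; (iv) `aTL_weighted = ΣOD / Σ(OD/L)` — the
mean of the corrected abundance distribution; (v) a Gaussian fitted to
(length, corrected abundance) by nonlinear least squares (init at the
corrected centroid/SD, tol 1e-8), whose mean is `aTL_gauss` and whose R²
gates acceptance at 60%. The default aTL is the Gaussian mean when
accepted, else the weighted mean. RTL divides by the same-gel reference
lane's aTL using the same estimator for both; rejected lanes get missing
RTL, never zero. STP is computed on raw band intensity by default (the
convention for this phenotype), with a bias-corrected option.

Two numerical caveats are intentional. The rolling-minimum background
erodes the interior of any plateau wider than its window, so idealized
perfectly-flat traces should be quantified with `background="none"`. And
because the corrected abundance still carries the pixel→length Jacobian
(∝ L on a log-linear gel), the estimator has a small upward bias that grows
with spread/TL; at the defaults it stays well inside the 5% recovery band
(measured median error ~1%).

## Genotype QC (`telocausal.qc`)

The exact HWE test conditions on the minor-allele count and sums the
probabilities of all heterozygote configurations no more probable than the
observed one (sum-of-≤-probability two-sided convention, not mid-p — the
standard genotype-QC choice). Variant filters: call rate < 0.95, MAF <
1e-4, HWE p < 1e-5; A/T and C/G variants are flagged strand-ambiguous but
left to the harmonization step to drop. IBD uses method-of-moments solving
of observed IBS-0/1/2 counts against their expectations given allele
frequencies; only the final `PI_HAT = P(IBD=1)/2 + P(IBD=2)` is truncated
to [0, 1] — clipping the intermediate state probabilities would bias
unrelated pairs upward. Related pairs (PI_HAT > 0.1875) lose their
lower-call-rate member, ties broken lexicographically. The contamination
heuristic scores the median absolute deviation of heterozygous BAF from
0.5 (flag at 0.07) plus a kernel-density dip check for bimodality; it is a
conservative automation of what is usually a visual inspection, and every
threshold is a parameter. Genetic-sex inference is out of scope (sex is
consumed as metadata). The post-imputation filter (info < 0.3, MAF < 0.01)
is a plain column filter on provided info scores; imputation itself is not
performed.

## GWAS meta-analysis (`telocausal.gwas`)

Cohorts are harmonized by `chrom:pos` match with identical or swapped
allele pairs (swaps flip the effect sign and mirror EAF), ambiguous
variants dropped, and a complete-case, MAF ≥ 0.01-in-every-cohort rule —
the shared-common-variant design that makes trans-cohort meta-analysis
well-defined when one cohort only covers common variants. Both fixed-effect
weightings are provided — inverse-variance (default) and sample-size-
weighted Z — because the two are both in wide use and differ only in
weighting; heterogeneity (Q, p_het, I² = max(0, (Q−df)/Q)) is computed from
per-cohort betas either way. Note I² is reported per variant and its
sampling distribution under homogeneity has mean ≈ 0.15 for k = 2; "I² ≈ 0"
holds on average/median, not per draw. Clumping is greedy smallest-p-first
(ties: position, then id) with composite (dosage) r² from the reference
panel; defaults 5e-8 / 10 Mb / r² 0.001. With a finite panel, null r²
between truly unlinked variants is ~1/n, so at r²_max = 0.001 loci closer
than the window can occasionally absorb each other's tags; recovery tests
therefore plant loci on separate chromosomes, as genome-wide loci
effectively are. Novelty: a sentinel is novel iff r² < 0.01 with every
known hit. Coordinates are 1-based inclusive; the effect allele is the
dosage-counted allele throughout.

## Polygenic score (`telocausal.prs`)

Classic clumping (250 kb, r² 0.1) + thresholding over the grid 5e-8 to 0.5
(step 5e-5 by default). Scores are `Σ w_v·dosage`, missing dosages imputed
at 2×AF (the PLINK convention). Threshold tuning maximizes incremental R² —
for a single added regressor this equals the squared partial correlation
times (1 − R²_cov), computed exactly. Because the grid collapses to at most
one model per distinct sentinel count, the sweep is one matrix–vector
product, and the permutation p (Freedman–Lane residual permutation, full
threshold search re-run per permutation to keep the selection honest) is
cheap even at 10 000 permutations. The empirical p floor is 1/(n_perm+1).

## cis-eQTL mapping (`telocausal.eqtl`)

Normalization is TMM (trim 30% on M, 5% on A, inverse-asymptotic-variance
weights, factors normalized to geometric mean 1; the reference sample is
the one whose upper quartile is closest to the mean) followed by a per-gene
rank-based inverse-normal transform with the Blom offset `(r − 3/8)/(n +
1/4)` and average ranks on ties. The cis window is TSS ± 1 Mb, inclusive,
TSS strand-aware. Covariates (genotype PCs, demographic columns, and
optional SVD-based hidden expression factors — learned-confounder factors
are consumed, not re-derived) are regressed out of both expression and
dosage, with degrees of freedom reduced accordingly; this equals the full
multiple-regression t-test (oracle-checked to 1e-8). Per-gene significance
uses permutation minima of the nominal p with a maximum-likelihood
Beta(a, b) fit; the beta-approximated p agrees with the direct empirical p
within ±0.03 and an MLE failure falls back to the direct value with a
flag. eGene FDR is Benjamini–Hochberg grouped per chromosome by default —
an unusual grouping kept deliberately, with a transcriptome-wide option.
Chromatin-state enrichment is a two-sided Fisher exact test on in-state
membership (BED half-open intervals) with Haldane correction for empty
cells.

## Causal integration (`telocausal.integrate`)

**Colocalization** uses the Wakefield approximate Bayes factor `log ABF =
½log(1−r) + ½z²r`, `r = W/(V+W)` with prior effect SD 0.15 for both
quantitative traits, and the standard per-variant priors p1 = p2 = 1e-4,
p12 = 1e-5 (these priors are the community defaults; analyses rarely state
them). Hypothesis sums run in log space; H3 is the cross-product minus the
diagonal. The two-tier call is strong (PP4 ≥ 0.8 and PP4/PP3 ≥ 5) or
suggestive (PP4 ≥ 0.5 and PP4/PP3 ≥ 3); single-variant regions have an
empty H3 sum and are flagged low-resolution.

**TWAS** weights are fit on covariate-residualized expression in the cis
window (500 kb either side of the gene for weight fitting), gated by a
Haseman–Elston regression cis-h² with a 200-permutation p (genes with p >
0.01 excluded). Methods: top1 (single best marginal variant), elastic net
(CV), BLUP (ridge with λ = m(1−h²)/h²). The association is the weighted
burden statistic `Z = w'z/√(w'Rw)` with the reference-panel LD matrix;
BH FDR < 0.1 flags significance. The transcriptional risk score sums
per-gene standardized genetically predicted expression weighted by TWAS Z
over FDR-significant genes (significant-only and standardized are
interpretive defaults, exposed as options).

**SMR** is the Wald ratio `b_xy = β_GWAS/β_eQTL` with `T_SMR =
z_g²z_e²/(z_g²+z_e²) ~ χ²₁`; instruments require eQTL p < 5e-8 (the tool
convention). **HEIDI** anchors at the top-|z_e| variant, keeps SNPs with
anchor r² in [0.05, 0.90] capped at 20 by descending |z_e|, computes the
per-SNP difference of Wald ratios with a delta-method covariance including
LD, and refers the summed squared standardized differences to a
Satterthwaite-scaled χ² (scale V/2E, df 2E²/V). p_HEIDI < 0.01 indicates
linkage and fails the gene; fewer than 3 eligible SNPs leaves the test
undefined and the gene passes with a flag. HEIDI's power is proportional
to instrument strength — at eQTL z ≈ 8 it barely separates shared from
linked signals, at z ≈ 12 (a typical strong top cis-eQTL) it rejects
linkage in ≥ 70% of r² ≈ 0.3 two-causal simulations while passing shared-
causal configurations ≥ 85% of the time.

**Prioritization**: causal ⇔ coloc class ∈ {strong, suggestive} AND (TWAS
q < 0.1 OR (SMR q < 0.1 AND HEIDI pass)). Requiring the HEIDI pass inside
the SMR arm follows HEIDI's role as a filter. LD matrices are symmetrized
with eigenvalues floored at 1e-6 before use as covariances.

## Co-expression (`telocausal.coexpr`)

Adjacency `|cor|^β` with β = 9; soft connectivity is the row sum. TOM
`(Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with unit diagonal;
modules come from average-linkage clustering of 1 − TOM cut at the 0.99
quantile of merge heights with minimum size 30 — a parameter-light stand-in
for dynamic tree cutting, whose full algorithm is out of proportion to its
role here (module counts are therefore not asserted as reproducible).
Eigengenes are first PCs of standardized module expression, sign-anchored
to the module mean. The sliding-window analysis ranks samples by RTL
descending (ties by sample id for determinism), uses windows of
round(0.25·n) samples stepping one-in/one-out, restricts genes to the top
30% by log-TPM variance (raw-TPM variance is dominated by high expressors),
and z-scores each gene's connectivity track. Track clustering is k-means
(k-means++, 10 restarts, fixed seed) with k chosen by the largest second
difference of the SSE curve (the elbow). Enrichment is one-sided
hypergeometric over user-supplied sets; no ontology database is bundled.

## TL association and prediction (`tlassoc`, `predict`)

Curated-set correlations use Pearson r with the two-sided t-test, BH within
the tested set at FDR 0.2, and an adjusted model `trait ~ gene + sex +
maternal age`; undetectable (zero-variance) genes are excluded with a log.

The elastic net minimizes `(1/2n)‖y−Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖²)` on
internally standardized features (coordinate descent, tol 1e-7, max 1e5
passes), with λ chosen by 10-fold CV on a geometric grid below λ_max =
max|X'y|/(nα) unless fixed. Folds are stratified by TL quartile (small-n
stability); `cv_r2` is the squared Pearson correlation of out-of-fold
predictions with y, and the in-sample r² is reported alongside because
which of the two a published model-comparison figure shows is often
ambiguous. The preset `published-2023` pins (α, λ) = (0.14, 0.18), a published
data-set-specific choice; the default is the CV search. The expression
signature takes genes with nonzero coefficients in a joint fit with PRS
and demographics (selection conditional on PRS) and keeps those whose
post-selection OLS refit has p < 0.05 — "significant coefficients" is not
otherwise defined, so this interpretation is explicit and flagged.
Transfer to a new cohort standardizes with the training constants and
mean-imputes missing features; the missing-fraction refusal threshold is a
parameter because a genotype-only cohort legitimately misses the whole
expression block.

## Problem sizes and what the tests show

The validation suite runs at desk scale, chosen as the smallest sizes at
which each statistical claim is comfortably powered: expression cohorts of
400–500 samples and 30–80 genes, reference panels of 400–2000 samples,
50-variant LD blocks, discovery cohorts of 20 000–50 000 simulated via the
summary-statistic sampling distribution, 2000 permutations per gene, and
10–50 Monte-Carlo replicates per claim. Passing tests demonstrate that the
estimators are correct and calibrated under the stated generative models;
they do not demonstrate performance on real LD, real expression networks,
or real gel artifacts, which the generators deliberately simplify.
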