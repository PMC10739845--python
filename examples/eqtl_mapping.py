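"""Placental-style cis-eQTL mapping on a synthetic cohort.

Expression (80 genes, 400 samples) carries one planted cis-eQTL of 0.8 SD
per effect allele. The pipeline is: expression filter, TMM + inverse-normal
normalization, covariate-adjusted nominal scan in a +/-1 Mb TSS window,
per-gene permutation p-values with a beta approximation, and per-chromosome
BH to call eGenes.
"""

import numpy as np
import pandas as pd

from telocausal import eqtl, synthetic
from telocausal.containers import TruthSet

geno = synthetic.simulate_genotypes(400, 60, 10, seed=21, spacing=20_000)
truth = TruthSet(planted_eqtls=[("snp000030", "gene0040", 0.8)])
expr = synthetic.simulate_expression(geno, truth, 80, seed=22)

kept = eqtl.filter_expressed(expr)
norm = eqtl.normalize_expression(kept)
pcs = eqtl.genotype_pcs(geno, n_pcs=5)
scan = eqtl.cis_scan(norm, expr.genes, geno, covariates=pcs)
print(f"nominal scan: {len(scan)} gene-variant pairs over "
      f"{norm.shape[0]} genes")

rows = []
gmeta = expr.genes.set_index("gene_id")
for gid in ["gene0040", "gene0010", "gene0070"]:
    tss = int(gmeta.loc[gid, "tss"])
    cis = np.where(np.abs(geno.variants["pos"] - tss) <= 1e6)[0]
    res = eqtl.permute_gene(
        norm.loc[gid].to_numpy(), geno.dosages[:, cis],
        list(geno.variants["id"].iloc[cis]), covariates=pcs.to_numpy(),
        n_perm=2000, seed=23,
    )
    rows.append({"gene_id": gid, "chrom": "1", "p": res.p_beta,
                 "best_variant": res.best_variant,
                 "p_direct": res.p_empirical})

calls = eqtl.fdr_genes(pd.DataFrame(rows), alpha=0.05)
print("\nper-gene permutation results (beta-approximated p):")
print(calls[["gene_id", "best_variant", "p", "q", "egene"]].to_string(
    index=False, float_format=lambda v: f"{v:.3g}"))
print("\ngene0040 carries the planted eQTL at snp000030; the two other "
      "genes are expected nulls.")

hit = scan.loc[(scan.gene_id == "gene0040") & (scan.id == "snp000030")]
print(f"planted effect estimate: {hit['beta'].iloc[0]:.3f} SD per allele "
      "(truth 0.8)")
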