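"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* genomic coordinates are 1-based and inclusive;
* the *effect allele* of a variant is the allele counted by the dosage
  (``alt`` for simulated data), so a dosage of 2 means two effect alleles;
* missing dosages are ``NaN`` in a float matrix; hard calls are 0/1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "TruthSet",
    "LaneProfile",
]

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant and sample metadata.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_samples, n_variants)`` holding effect-allele
        counts in ``{0, 1, 2}`` with ``NaN`` for missing calls.
    variants
        DataFrame with columns ``id, chrom, pos, ref, alt`` (one row per
        column of ``dosages``; ``alt`` is the effect allele).
    samples
        Sample identifiers, one per row of ``dosages``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant metadata does not match dosage columns")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("sample list does not match dosage rows")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Effect-allele frequency per variant, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        af = self.allele_freq()
        return np.minimum(af, 1.0 - af)

    def call_rate_variants(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def call_rate_samples(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=1)

    def is_ambiguous(self) -> np.ndarray:
        """Strand-ambiguous (A/T or C/G) flag per variant."""
        pairs = zip(self.variants["ref"], self.variants["alt"])
        return np.array([(r, a) in AMBIGUOUS_PAIRS for r, a in pairs])

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        d = self.dosages
        samples = self.samples
        variants = self.variants
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx, :]
            samples = [self.samples[i] for i in sample_idx]
        if variant_idx is not None:
            variant_idx = np.asarray(variant_idx)
            d = d[:, variant_idx]
            variants = self.variants.iloc[variant_idx]
        return GenotypeMatrix(d.copy(), variants.reset_index(drop=True), list(samples))

    def variant_index(self) -> pd.Index:
        return pd.Index(self.variants["id"])


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with gene annotation.

    ``counts`` and ``tpm`` are DataFrames indexed by gene id with sample-id
    columns. ``genes`` carries ``gene_id, chrom, start, end, strand, tss``;
    the TSS is strand-aware (start on ``+``, end on ``-``).
    """

    counts: pd.DataFrame
    tpm: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.tpm.index):
            raise ValueError("counts and tpm gene indices differ")
        if list(self.counts.columns) != list(self.tpm.columns):
            raise ValueError("counts and tpm sample columns differ")
        self.genes = self.genes.set_index(
            pd.Index(self.genes["gene_id"]), drop=False
        ).loc[self.counts.index]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.counts.loc[gene_ids], self.tpm.loc[gene_ids], self.genes.loc[gene_ids]
        )


@dataclass
class TruthSet:
    """Generative ground truth that downstream recovery tests compare against.

    ``h2_snp`` is the fraction of TL variance explained by the planted causal
    variants and ``var_expr`` the fraction explained by planted causal gene
    expression; their sum must not exceed 1.
    """

    causal_variants: list[tuple[str, float]] = field(default_factory=list)
    causal_genes: list[tuple[str, float]] = field(default_factory=list)
    planted_eqtls: list[tuple[str, str, float]] = field(default_factory=list)
    module_assignments: dict[str, str] = field(default_factory=dict)
    h2_snp: float = 0.0
    var_expr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2_snp <= 1.0 and 0.0 <= self.var_expr <= 1.0):
            raise ValueError("variance fractions must lie in [0, 1]")
        if self.h2_snp + self.var_expr > 1.0 + 1e-12:
            raise ValueError("h2_snp + var_expr must be <= 1")
        ids = [v for v, _ in self.causal_variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate causal variant ids")
        gids = [g for g, _ in self.causal_genes]
        if len(set(gids)) != len(gids):
            raise ValueError("duplicate causal gene ids")


@dataclass
class LaneProfile:
    """A densitometry trace: intensity sampled along the migration axis."""

    lane_id: str
    pixels: np.ndarray
    intensity: np.ndarray
    is_ladder: bool = False
    is_reference: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.pixels.ndim != 1 or self.intensity.shape != self.pixels.shape:
            raise ValueError("pixels and intensity must be 1-D and equal length")
        if np.any(np.diff(self.pixels) <= 0):
            raise ValueError("pixels must be strictly increasing")
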