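"""Readers and writers for the plain-text formats the pipeline exchanges:
VCF genotypes, METAL-like summary-statistics TSV, expression TSV, BED
chromatin states, and densitometry lane CSV. Writing is deterministic, so a
fixed simulation seed yields byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix, LaneProfile

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_summary_stats",
    "read_summary_stats",
    "write_expression",
    "read_expression",
    "write_lanes",
    "read_lanes",
    "read_bed_states",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call genotypes as an uncompressed VCF 4.2 with GT only."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(geno.samples),
    ]
    for j in range(geno.n_variants):
        v = geno.variants.iloc[j]
        calls = [
            "./." if np.isnan(d) else _GT[int(d)] for d in geno.dosages[:, j]
        ]
        lines.append(
            f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}"
            "\t.\t.\t.\tGT\t" + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (GT field) back into a GenotypeMatrix via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        gts = rec.genotype.array()[:, :2]
        dos = np.where((gts < 0).any(axis=1), np.nan, gts.clip(0).sum(axis=1))
        rows.append(dos.astype(float))
        meta.append(
            {
                "id": rec.ID,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
            }
        )
    return GenotypeMatrix(np.array(rows).T, pd.DataFrame(meta), samples)


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    """METAL-like TSV: SNP CHR BP A1 A2 EAF BETA SE Z P N [cohort...]."""
    out = stats.rename(
        columns={
            "id": "SNP",
            "chrom": "CHR",
            "pos": "BP",
            "a1": "A1",
            "a2": "A2",
            "eaf": "EAF",
            "beta": "BETA",
            "se": "SE",
            "z": "Z",
            "p": "P",
            "n": "N",
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(
        columns={
            "SNP": "id",
            "CHR": "chrom",
            "BP": "pos",
            "A1": "a1",
            "A2": "a2",
            "EAF": "eaf",
            "BETA": "beta",
            "SE": "se",
            "Z": "z",
            "P": "p",
            "N": "n",
        }
    )


def write_expression(expr: ExpressionMatrix, prefix: str | Path) -> None:
    """Write counts, TPM and gene annotation as `<prefix>.{counts,tpm,genes}.tsv`."""
    prefix = str(prefix)
    expr.counts.to_csv(prefix + ".counts.tsv", sep="\t", float_format="%.8g")
    expr.tpm.to_csv(prefix + ".tpm.tsv", sep="\t", float_format="%.8g")
    expr.genes.to_csv(prefix + ".genes.tsv", sep="\t", index=False)


def read_expression(prefix: str | Path) -> ExpressionMatrix:
    prefix = str(prefix)
    counts = pd.read_csv(prefix + ".counts.tsv", sep="\t", index_col=0)
    tpm = pd.read_csv(prefix + ".tpm.tsv", sep="\t", index_col=0)
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t")
    return ExpressionMatrix(counts, tpm, genes)


def write_lanes(lanes: list[LaneProfile], path: str | Path) -> None:
    """Long-format CSV: lane_id, pixel, intensity, is_ladder, is_reference."""
    rows = []
    for lane in lanes:
        for px, od in zip(lane.pixels, lane.intensity):
            rows.append(
                {
                    "lane_id": lane.lane_id,
                    "pixel": px,
                    "intensity": od,
                    "is_ladder": int(lane.is_ladder),
                    "is_reference": int(lane.is_reference),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")


def read_lanes(path: str | Path) -> list[LaneProfile]:
    df = pd.read_csv(path)
    lanes = []
    for lane_id, grp in df.groupby("lane_id", sort=False):
        grp = grp.sort_values("pixel")
        lanes.append(
            LaneProfile(
                str(lane_id),
                grp["pixel"].to_numpy(dtype=float),
                grp["intensity"].to_numpy(dtype=float),
                is_ladder=bool(grp["is_ladder"].iloc[0]),
                is_reference=bool(grp["is_reference"].iloc[0]),
            )
        )
    return lanes


def read_bed_states(path: str | Path) -> pd.DataFrame:
    """BED4 chromatin states: chrom, start (0-based), end, state."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "state"]
    )
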