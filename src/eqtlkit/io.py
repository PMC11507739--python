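"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF 4.2 with GT hard calls plus a DS dosage FORMAT
field (read back through cyvcf2), phenotypes as tab-separated BED-like
files (#chr, start, end, gene_id, strand, one column per sample), and GWAS
tracks / covariates as TSV with a header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simgen import ExpressionCounts, GenotypeMatrix, SummaryStatTrack

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_counts_bed",
    "read_counts_bed",
    "write_phenotype_bed",
    "read_phenotype_bed",
    "write_gwas_tsv",
    "read_gwas_tsv",
    "write_covariates_tsv",
    "read_covariates_tsv",
]


def _gt_call(dosage: float) -> str:
    d = int(round(dosage))
    return {0: "0/0", 1: "0/1", 2: "1/1"}[min(max(d, 0), 2)]


def write_vcf(geno: GenotypeMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        chroms = geno.variants["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for j, row in geno.variants.iterrows():
            cells = [
                f"{_gt_call(d)}:{d:.3f}" for d in geno.dosages[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages = [], []
    for rec in vcf:
        ds = rec.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:  # fall back to hard calls
            dose = np.array([sum(g[:2]) for g in rec.genotypes], dtype=float)
        dosages.append(dose)
        rows.append(
            {
                "variant_id": rec.ID,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
    mat = np.array(dosages).T
    variants = pd.DataFrame(rows)
    freq = mat.mean(axis=0) / 2.0
    variants["maf"] = np.minimum(freq, 1.0 - freq)
    return GenotypeMatrix(dosages=mat, variants=variants, samples=samples)


def _bed_frame(genes: pd.DataFrame, values: np.ndarray, samples) -> pd.DataFrame:
    meta = pd.DataFrame(
        {
            "#chr": genes["chrom"].values,
            "start": genes["start"].values,
            "end": genes["end"].values,
            "gene_id": genes["gene_id"].values,
            "strand": genes["strand"].values,
        }
    )
    vals = pd.DataFrame(values, columns=list(samples))
    return pd.concat([meta, vals], axis=1)


def write_counts_bed(counts: ExpressionCounts, path) -> None:
    _bed_frame(counts.genes, counts.counts, counts.samples).to_csv(
        path, sep="\t", index=False
    )


def read_counts_bed(path) -> ExpressionCounts:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["#chr", "start", "end", "gene_id", "strand"]
    samples = [c for c in df.columns if c not in meta_cols]
    genes = df[meta_cols].rename(columns={"#chr": "chrom"})
    return ExpressionCounts(
        counts=df[samples].to_numpy(),
        genes=genes.reset_index(drop=True),
        samples=samples,
    )


def write_phenotype_bed(values: pd.DataFrame, genes: pd.DataFrame, path) -> None:
    """``values``: genes x samples with gene_id index, aligned with ``genes``."""
    ordered = (
        genes.set_index("gene_id")
        .loc[values.index]
        .rename_axis("gene_id")
        .reset_index()
    )
    _bed_frame(ordered, values.to_numpy(), list(values.columns)).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_phenotype_bed(path):
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["#chr", "start", "end", "gene_id", "strand"]
    samples = [c for c in df.columns if c not in meta_cols]
    genes = df[meta_cols].rename(columns={"#chr": "chrom"})
    values = df.set_index("gene_id")[samples]
    return values, genes.reset_index(drop=True)


def write_gwas_tsv(track: SummaryStatTrack, path) -> None:
    table = track.table.copy()
    table["trait_id"] = track.trait_id
    table["trait_type"] = track.trait_type
    table["n"] = track.n
    table["case_fraction"] = (
        track.case_fraction if track.case_fraction is not None else ""
    )
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_gwas_tsv(path) -> SummaryStatTrack:
    df = pd.read_csv(path, sep="\t")
    trait_id = str(df["trait_id"].iloc[0])
    trait_type = str(df["trait_type"].iloc[0])
    n = int(df["n"].iloc[0])
    cf = df["case_fraction"].iloc[0]
    case_fraction = None if pd.isna(cf) or cf == "" else float(cf)
    cols = ["variant_id", "chrom", "pos", "ref", "alt", "beta", "se", "z", "p", "maf"]
    return SummaryStatTrack(
        trait_id=trait_id,
        trait_type=trait_type,
        table=df[cols].copy(),
        n=n,
        case_fraction=case_fraction,
    )


def write_covariates_tsv(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6g")


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
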