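"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as minimal VCF (GT; RNA calls add DP and AD) or as a
tabular dialect; counts, gene annotation, catalogs, covariates and truth
sidecars are TSV. VCF parsing goes through pysam; writing emits minimal
spec-conforming text.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from .datatypes import MISSING, EqtlCatalog, ExpressionMatrix, GenotypeMatrix, RnaCallSet

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_GT_DOSE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}

FLOAT_FMT = "%.10g"


def _vcf_header(
    samples: list[str], with_depth: bool, contigs: list[str] = ()
) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    if with_depth:
        lines += [
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        ]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    return "\n".join(lines) + "\n"


def write_genotype_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    contigs = list(pd.unique(gm.snps["chrom"]))
    with open(path, "w") as fh:
        fh.write(_vcf_header(gm.samples, False, contigs))
        for j, row in gm.snps.iterrows():
            calls = "\t".join(_GT_STR[int(c)] for c in gm.calls[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_genotype_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    vf = pysam.VariantFile(os.fspath(path))
    samples = list(vf.header.samples)
    snp_rows = []
    calls_rows = []
    for rec in vf:
        snp_rows.append(
            (rec.id, rec.chrom, rec.pos, rec.ref, rec.alts[0] if rec.alts else ".")
        )
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is not None and None not in gt:
                row[i] = _GT_DOSE.get(tuple(gt), MISSING)
        calls_rows.append(row)
    vf.close()
    snps = pd.DataFrame(
        snp_rows, columns=["snp_id", "chrom", "pos", "ref", "alt"]
    )
    calls = (
        np.array(calls_rows, dtype=np.int8).T
        if calls_rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def write_rna_vcf(
    rcs: RnaCallSet,
    snps: pd.DataFrame,
    path: str | os.PathLike,
) -> None:
    """RNA calls as VCF with GT, DP and AD; withheld sites are ./.

    ``snps`` supplies chrom/pos/ref/alt per snp_id (a GenotypeMatrix.snps
    table works).
    """
    meta = snps.set_index("snp_id")
    calls = rcs.calls
    depth = rcs.depth
    contigs = list(pd.unique(snps["chrom"]))
    with open(path, "w") as fh:
        fh.write(_vcf_header(rcs.samples, True, contigs))
        for j, snp_id in enumerate(rcs.snp_ids):
            row = meta.loc[snp_id]
            fields = []
            for i in range(len(rcs.samples)):
                gt = _GT_STR[int(calls[i, j])]
                fields.append(
                    f"{gt}:{depth[i, j]}:{rcs.ref_depth[i, j]},{rcs.alt_depth[i, j]}"
                )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{snp_id}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT:DP:AD\t" + "\t".join(fields) + "\n"
            )


def read_rna_vcf(path: str | os.PathLike) -> RnaCallSet:
    vf = pysam.VariantFile(os.fspath(path))
    samples = list(vf.header.samples)
    snp_ids = []
    ref_rows, alt_rows = [], []
    for rec in vf:
        snp_ids.append(rec.id)
        ref = np.zeros(len(samples), dtype=np.int64)
        alt = np.zeros(len(samples), dtype=np.int64)
        for i, s in enumerate(samples):
            ad = rec.samples[s].get("AD")
            if ad is not None and ad[0] is not None:
                ref[i], alt[i] = int(ad[0]), int(ad[1])
        ref_rows.append(ref)
        alt_rows.append(alt)
    vf.close()
    return RnaCallSet(
        samples=samples,
        snp_ids=snp_ids,
        ref_depth=np.array(ref_rows, dtype=np.int64).T
        if ref_rows
        else np.empty((len(samples), 0), dtype=np.int64),
        alt_depth=np.array(alt_rows, dtype=np.int64).T
        if alt_rows
        else np.empty((len(samples), 0), dtype=np.int64),
    )


def write_genotype_tsv(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    df = pd.concat(
        [
            gm.snps.reset_index(drop=True),
            pd.DataFrame(gm.calls.T, columns=gm.samples),
        ],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["snp_id", "chrom", "pos", "ref", "alt"]
    samples = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(
        samples=samples,
        snps=df[meta_cols].copy(),
        calls=df[samples].to_numpy(dtype=np.int8).T,
    )


def write_counts_tsv(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    pd.DataFrame(
        expr.counts, index=expr.genes["gene_id"], columns=expr.samples
    ).rename_axis("gene_id").to_csv(path, sep="\t")


def write_annotation_tsv(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = ["chrom", "start", "end", "strand", "gene_id", "gc", "length"]
    genes[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_expression_tsv(
    counts_path: str | os.PathLike, annotation_path: str | os.PathLike
) -> ExpressionMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    genes = pd.read_csv(annotation_path, sep="\t")
    genes = genes.set_index("gene_id").loc[counts.index].reset_index()
    return ExpressionMatrix(
        genes=genes,
        samples=list(counts.columns),
        counts=counts.to_numpy(),
    )


def write_catalog_tsv(catalog: EqtlCatalog, path: str | os.PathLike) -> None:
    catalog.pairs.to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path: str | os.PathLike) -> EqtlCatalog:
    return EqtlCatalog(pairs=pd.read_csv(path, sep="\t"))


def write_fixture(bundle, outdir: str | os.PathLike) -> dict[str, str]:
    """Emit a complete synthetic study to disk.

    Writes genotypes (VCF + TSV), RNA calls (VCF), counts, gene annotation
    (BED-like TSV, 1-based start/end columns as annotated), catalog,
    covariates and truth sidecars. Returns a name -> path manifest.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genotypes_vcf": os.path.join(outdir, "genotypes.vcf"),
        "genotypes_tsv": os.path.join(outdir, "genotypes.tsv"),
        "rna_vcf": os.path.join(outdir, "rna_calls.vcf"),
        "counts": os.path.join(outdir, "counts.tsv"),
        "annotation": os.path.join(outdir, "genes.tsv"),
        "catalog": os.path.join(outdir, "catalog.tsv"),
        "covariates": os.path.join(outdir, "covariates.tsv"),
        "truth_eqtls": os.path.join(outdir, "truth_eqtls.tsv"),
        "truth_contamination": os.path.join(outdir, "truth_contamination.tsv"),
        "truth_outliers": os.path.join(outdir, "truth_outliers.tsv"),
    }
    write_genotype_vcf(bundle.genotypes, paths["genotypes_vcf"])
    write_genotype_tsv(bundle.genotypes, paths["genotypes_tsv"])
    write_rna_vcf(bundle.rna_calls, bundle.genotypes.snps, paths["rna_vcf"])
    write_counts_tsv(bundle.expression, paths["counts"])
    write_annotation_tsv(bundle.expression.genes, paths["annotation"])
    write_catalog_tsv(bundle.catalog, paths["catalog"])
    bundle.covariates.to_csv(paths["covariates"], sep="\t")
    pd.DataFrame(
        bundle.truth.true_eqtls, columns=["snp_id", "gene_id", "effect"]
    ).to_csv(paths["truth_eqtls"], sep="\t", index=False, float_format=FLOAT_FMT)
    pd.DataFrame(
        [(s, d, f) for s, (d, f) in sorted(bundle.truth.contaminated.items())],
        columns=["sample", "donor", "fraction"],
    ).to_csv(
        paths["truth_contamination"], sep="\t", index=False, float_format=FLOAT_FMT
    )
    rows = [("global", s, "") for s in sorted(bundle.truth.global_outliers)]
    rows += [
        ("per_gene", s, g) for g, s in sorted(bundle.truth.per_gene_outliers)
    ]
    pd.DataFrame(rows, columns=["kind", "sample", "gene_id"]).to_csv(
        paths["truth_outliers"], sep="\t", index=False
    )
    return paths
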