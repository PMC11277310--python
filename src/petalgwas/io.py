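"""Readers and writers for the standard formats the pipeline touches.

VCF parsing goes through cyvcf2 and GFF3 through gffutils; genotype calls are
recoded to the additive 0/1/2 convention with -1 for missing. Multi-allelic
VCF records are skipped (the analyses are defined for biallelic SNPs) and the
skip count is logged. All interval arithmetic at these interfaces is 1-based
inclusive.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import MISSING, GeneModel, GenotypeMatrix, merge_intervals

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sample_subset: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Codes follow the additive convention (0 hom-ref, 1 het, 2 hom-alt,
    -1 missing). Variant order is preserved; multi-allelic records are
    skipped with a logged count.
    """
    path = str(path)
    vcf = VCF(path, gts012=True)
    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in vcf.samples]
        if unknown:
            raise KeyError(f"samples not present in {path}: {unknown}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)

    rows = []
    columns = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = rec.gt_types  # with gts012: 0=hom-ref,1=het,2=hom-alt,3=unknown
        codes = np.where(gts == 3, MISSING, gts).astype(np.int8)
        columns.append(codes)
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "id": rec.ID or f"{rec.CHROM}_{rec.POS}",
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
    vcf.close()
    if n_multi:
        logger.info("read_vcf: skipped %d multi-allelic records in %s", n_multi, path)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCFv4.2 file."""
    path = Path(path)
    chroms = pd.unique(G.variants["chrom"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=petalgwas\n")
        for chrom in chroms:
            max_pos = int(G.variants.loc[G.variants["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1_000_000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        for j, var in G.variants.iterrows():
            gts = "\t".join(_GT_STRINGS[int(c)] for c in G.calls[:, j])
            fh.write(
                f"{var.chrom}\t{var.pos}\t{var.id}\t{var.ref}\t{var.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene span + merged CDS intervals) from a GFF3 file.

    CDS features are attached to the gene they descend from (directly or via
    an mRNA); a CDS with no gene ancestor raises ``ValueError``.
    """
    path = str(path)
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # empty files raise inside gffutils
        if _gff3_is_empty(path):
            return []
        raise ValueError(f"cannot parse GFF3 {path}: {exc}") from exc

    genes: list[GeneModel] = []
    gene_ids = set()
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        cds = [
            (c.start, c.end)
            for c in db.children(gene, featuretype="CDS", order_by="start")
        ]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                gene_span=(gene.start, gene.end),
                cds_intervals=merge_intervals(cds),
            )
        )
        gene_ids.add(gene.id)

    # orphan check: every CDS must descend from some gene
    n_cds = sum(1 for _ in db.features_of_type("CDS"))
    n_attached = sum(
        1
        for g in db.features_of_type("gene")
        for _ in db.children(g, featuretype="CDS")
    )
    if n_attached < n_cds:
        raise ValueError(f"{n_cds - n_attached} CDS feature(s) with no parent gene in {path}")
    return genes


def _gff3_is_empty(path: str) -> bool:
    with open(path) as fh:
        return all(not line.strip() or line.startswith("#") for line in fh)


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal GFF3 (gene + mRNA + CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = g.gene_span
            fh.write(
                f"{g.chrom}\tpetalgwas\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tpetalgwas\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for k, (a, b) in enumerate(g.cds_intervals, 1):
                fh.write(
                    f"{g.chrom}\tpetalgwas\tCDS\t{a}\t{b}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{k};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# Marker / sample filtering
# ---------------------------------------------------------------------------

def apply_marker_filters(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    geno_max: float = 0.2,
    mind_max: float = 0.2,
    order: Sequence[str] = ("mind", "geno", "maf"),
) -> GenotypeMatrix:
    """Quality-filter a genotype matrix the way plink's -maf/-geno/-mind do.

    Stages (default order): drop samples with missing rate > ``mind_max``,
    then variants with missing rate > ``geno_max``, then variants with minor
    allele frequency < ``maf_min``. Per-stage removal counts are logged.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0 <= geno_max <= 1 and 0 <= mind_max <= 1):
        raise ValueError("geno_max and mind_max must be in [0, 1]")
    if set(order) != {"mind", "geno", "maf"}:
        raise ValueError(f"order must be a permutation of mind/geno/maf, got {order}")

    out = G
    for stage in order:
        if stage == "mind":
            keep = np.flatnonzero(out.missing_rate_per_sample() <= mind_max)
            n_drop = out.n_samples - keep.size
            if keep.size == 0:
                raise ValueError("mind filter removed every sample")
            out = out.take_samples(keep)
        elif stage == "geno":
            keep = np.flatnonzero(out.missing_rate_per_variant() <= geno_max)
            n_drop = out.n_variants - keep.size
            if keep.size == 0:
                raise ValueError("geno filter removed every variant")
            out = out.take_variants(keep)
        else:  # maf
            p = out.allele_frequencies()
            maf = np.minimum(p, 1 - p)
            keep = np.flatnonzero(np.nan_to_num(maf, nan=-1.0) >= maf_min)
            n_drop = out.n_variants - keep.size
            if keep.size == 0:
                raise ValueError("maf filter removed every variant")
            out = out.take_variants(keep)
        logger.info("filter %s: removed %d", stage, n_drop)
    return out


# ---------------------------------------------------------------------------
# Phenotype / generic tables
# ---------------------------------------------------------------------------

def read_phenotype_table(path: str | Path, sample_col: str = "sample") -> pd.DataFrame:
    """Read a delimited sample x trait table indexed by sample id."""
    df = pd.read_csv(path, sep=None, engine="python")
    if sample_col not in df.columns:
        raise ValueError(f"phenotype table lacks a '{sample_col}' column")
    if df[sample_col].duplicated().any():
        dups = df.loc[df[sample_col].duplicated(), sample_col].tolist()
        raise ValueError(f"duplicate sample ids in phenotype table: {dups}")
    return df.set_index(sample_col)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a tab-delimited table with header (empty frames give a header-only file)."""
    pd.DataFrame(df).to_csv(path, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# named writers for the pipeline's three record streams; all share one format
write_assoc_table = write_table
write_window_table = write_table
write_network_edges = write_table
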