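"""Readers and writers for the pipeline's on-disk formats.

GFF3 (1-based inclusive) + protein/CDS FASTA carry the gene annotation,
VCF v4.2 the panel genotypes, and tidy TSV tables everything else. Reading
goes through the standard parsers (gffutils, Bio.SeqIO, cyvcf2); writing
emits the minimal feature set as plain text so outputs are diffable.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .models import GeneModel, SNPRecord


# ---------------------------------------------------------------- annotation

def write_gff3(genes: Iterable[GeneModel], path: str,
               chromosome_length: int | None = None) -> None:
    """When ``chromosome_length`` is given, declare all 21 wheat chromosomes
    as sequence-regions even if some carry no genes."""
    from .models import CHROMOSOMES
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chromosome_length is not None:
            for chrom in CHROMOSOMES:
                fh.write(f"##sequence-region {chrom} 1 {chromosome_length}\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            attrs = f"ID={g.gene_id}"
            if g.sub_index is not None:
                attrs += f";sub_index={g.sub_index}"
            fh.write(
                f"{g.chromosome}\tsaltnac\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), start=1):
                fh.write(
                    f"{g.chromosome}\tsaltnac\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def write_fasta(records: dict[str, str], path: str) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def read_gff3(path: str, proteins: dict[str, str] | None = None,
              cds: dict[str, str] | None = None) -> list[GeneModel]:
    """Load gene models from GFF3, attaching sequences when provided."""
    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes["ID"][0]
        exons = sorted((e.start, e.end) for e in db.children(feat, featuretype="exon"))
        sub = feat.attributes.get("sub_index")
        genes.append(GeneModel(
            gene_id=gid, chromosome=feat.seqid, start=feat.start, end=feat.end,
            strand=feat.strand, exons=exons,
            protein=(proteins or {}).get(gid, ""),
            cds=(cds or {}).get(gid),
            sub_index=int(sub[0]) if sub else None,
        ))
    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return genes


def load_genes(gff_path: str, protein_fasta: str | None = None,
               cds_fasta: str | None = None) -> list[GeneModel]:
    prot = read_fasta(protein_fasta) if protein_fasta else None
    cds = read_fasta(cds_fasta) if cds_fasta else None
    return read_gff3(gff_path, proteins=prot, cds=cds)


# ---------------------------------------------------------------- genotypes

def write_vcf(snps: Sequence[SNPRecord], dosage: np.ndarray,
              accessions: Sequence[str], path: str) -> None:
    """Write homozygous-coded biallelic calls; dosage -1 means missing.

    ``dosage`` is accessions x snps with entries in {-1, 0, 1, 2}.
    """
    gt_map = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    idx = sorted(range(len(snps)),
                 key=lambda j: (snps[j].chromosome, snps[j].position, snps[j].snp_id))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({s.chromosome for s in snps}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(accessions) + "\n")
        for j in idx:
            s = snps[j]
            calls = "\t".join(gt_map[int(d)] for d in dosage[:, j])
            fh.write(f"{s.chromosome}\t{s.position}\t{s.snp_id}\t{s.ref}\t{s.alt}"
                     f"\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path: str) -> tuple[list[SNPRecord], np.ndarray, list[str]]:
    """Read biallelic calls back into (records, dosage matrix, accession names)."""
    vcf = VCF(path)
    accessions = list(vcf.samples)
    snps: list[SNPRecord] = []
    rows = []
    for var in vcf:
        snps.append(SNPRecord(
            snp_id=var.ID or f"{var.CHROM}:{var.POS}",
            chromosome=var.CHROM, position=var.POS,
            ref=var.REF, alt=var.ALT[0],
        ))
        dos = np.empty(len(accessions), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a0, a1 = gt[0], gt[1]
            dos[i] = -1 if (a0 < 0 or a1 < 0) else a0 + a1
        rows.append(dos)
    vcf.close()
    dosage = np.array(rows, dtype=np.int8).T if rows else np.empty((len(accessions), 0), np.int8)
    return snps, dosage, accessions


# ------------------------------------------------------------------- tables

def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def read_expression_tsv(path: str) -> pd.DataFrame:
    """Genes x samples FPKM table; sample columns look like ``T06_R2``."""
    return pd.read_csv(path, sep="\t", index_col=0)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
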