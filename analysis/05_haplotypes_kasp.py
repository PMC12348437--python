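#!/usr/bin/env python
"""Haplotypes and KASP markers for the genes carrying significant SNPs.

For every gene whose region holds a significant association, groups the
panel into gene-region haplotypes, tests the RSIR difference between Hap1
and Hap2, and designs a KASP primer triplet on the top SNP. Writes
haplotypes.tsv, haplotype_tests.tsv and kasp.tsv under results/analysis/.
"""

import os

import pandas as pd

from saltnac import association as am
from saltnac import io as snio
from saltnac.haplotype import (build_haplotypes, design_kasp,
                               gene_region_snps, haplotype_phenotype_test)
from saltnac.simulate import read_regions_fasta

HERE = os.path.dirname(os.path.abspath(__file__))
RES = os.path.join(HERE, "..", "results", "analysis")


def main() -> None:
    genes = snio.load_genes(f"{RES}/sim/genes.gff3", f"{RES}/sim/proteins.fasta",
                            f"{RES}/sim/cds.fasta")
    snps, dosage, accessions = snio.read_vcf(f"{RES}/sim/genotypes.vcf")
    am.qc_snps(snps, dosage)
    rsir = snio.read_tsv(f"{RES}/rsir.tsv").set_index("accession")
    assoc = snio.read_tsv(f"{RES}/association.tsv")
    regions = read_regions_fasta(f"{RES}/sim/regions.fasta")

    sig = assoc[assoc.significant]
    sig_snps = set(sig.snp_id)
    trait_of = dict(zip(sig.snp_id, sig.trait))
    by_id = {s.snp_id: j for j, s in enumerate(snps)}

    hap_rows, test_rows, kasp_rows = [], [], []
    for g in genes:
        region = gene_region_snps(g, snps)
        hit = [s for s in region if s.snp_id in sig_snps]
        if not hit:
            continue
        cols = [by_id[s.snp_id] for s in region]
        haps = build_haplotypes(region, dosage[:, cols], accessions,
                                gene_id=g.gene_id)
        for h in haps:
            for acc in h.accessions:
                hap_rows.append((g.gene_id, acc, h.label, h.allele_string))
        trait = trait_of[hit[0].snp_id]
        if len(haps) >= 2:
            cmp = haplotype_phenotype_test(haps, rsir, trait)
            test_rows.append((g.gene_id, trait, cmp.n_a, cmp.n_b, cmp.mean_a,
                              cmp.mean_b, cmp.p_value, cmp.significant,
                              cmp.direction))
        rstart, rseq = regions[g.gene_id]
        s = hit[0]
        try:
            k = design_kasp(rseq, s.position - rstart, s.ref, s.alt,
                            snp_id=s.snp_id)
            kasp_rows.append((g.gene_id, s.display_id, k.fam_primer,
                              k.hex_primer, k.common_reverse, k.product_length))
        except ValueError as err:
            print(f"  KASP design failed for {s.snp_id}: {err}")

    snio.write_tsv(pd.DataFrame(hap_rows, columns=[
        "gene_id", "accession", "haplotype", "allele_string"]),
        f"{RES}/haplotypes.tsv")
    snio.write_tsv(pd.DataFrame(test_rows, columns=[
        "gene_id", "trait", "n_hap1", "n_hap2", "mean_hap1", "mean_hap2",
        "p_value", "significant", "direction"]), f"{RES}/haplotype_tests.tsv")
    snio.write_tsv(pd.DataFrame(kasp_rows, columns=[
        "gene_id", "snp", "fam_primer", "hex_primer", "common_reverse",
        "product_length"]), f"{RES}/kasp.tsv")
    print(f"{len(test_rows)} haplotype contrasts tested, "
          f"{len(kasp_rows)} KASP designs written")
    for row in test_rows:
        print(f"  {row[0]} ({row[1]}): p={row[6]:.2e}, {row[8]}")


if __name__ == "__main__":
    main()
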