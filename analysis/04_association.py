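#!/usr/bin/env python
"""RSIR phenotypes, genotype QC and the per-SNP association scan.

Computes the relative salt-injury rate for six root traits, filters SNPs
(MAF > 10%, missing < 5%), and regresses each trait's RSIR on alt-allele
dosage with three genotype PCs. Writes rsir.tsv, association.tsv and a
Manhattan-ready table under results/analysis/.
"""

import argparse
import os

from saltnac import association as am
from saltnac import io as snio

HERE = os.path.dirname(os.path.abspath(__file__))
RES = os.path.join(HERE, "..", "results", "analysis")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--pcs", type=int, default=3)
    args = ap.parse_args()
    snps, dosage, accessions = snio.read_vcf(f"{RES}/sim/genotypes.vcf")
    pheno = snio.read_tsv(f"{RES}/sim/phenotypes.tsv")
    rsir = am.compute_rsir(pheno)
    am.qc_snps(snps, dosage)
    results = am.associate_all_traits(snps, dosage, accessions, rsir,
                                      n_pcs=args.pcs)
    snio.write_tsv(rsir.reset_index(), f"{RES}/rsir.tsv")
    snio.write_tsv(results, f"{RES}/association.tsv")
    snio.write_tsv(am.manhattan_table(results, snps), f"{RES}/manhattan.tsv")
    n_pass = sum(s.qc_pass for s in snps)
    sig = results[results.significant]
    print(f"{n_pass}/{len(snps)} SNPs pass QC; "
          f"{len(sig)} SNP-trait pairs significant at -log10 p > 4 "
          f"({sig.snp_id.nunique()} SNPs)")


if __name__ == "__main__":
    main()
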