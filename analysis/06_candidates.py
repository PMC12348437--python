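#!/usr/bin/env python
"""Intersect trajectory Group 4 with significant region SNPs.

The candidate rule: successively upregulated after salt stress (Group 4)
AND carrying at least one significant, QC-passing SNP in the gene region.
Compares the selection against the generator's truth labels and writes
candidates.tsv under results/analysis/.
"""

import os

import pandas as pd

from saltnac import expression as ex
from saltnac import io as snio
from saltnac.catalog import build_catalog
from saltnac.report import select_candidates
from saltnac.simulate import TruthSet

HERE = os.path.dirname(os.path.abspath(__file__))
RES = os.path.join(HERE, "..", "results", "analysis")


def main() -> None:
    genes = snio.load_genes(f"{RES}/sim/genes.gff3", f"{RES}/sim/proteins.fasta",
                            f"{RES}/sim/cds.fasta")
    fpkm = snio.read_expression_tsv(f"{RES}/sim/fpkm.tsv")
    by_time = ex.parse_sample_columns(fpkm.columns)
    members, _ = build_catalog(
        genes, fpkm_0h=fpkm[by_time[0]].mean(axis=1).to_dict())
    traj = snio.read_tsv(f"{RES}/trajectories.tsv")
    traj["group"] = traj.group.astype("Int64")
    assoc = snio.read_tsv(f"{RES}/association.tsv")
    snps, dosage, _ = snio.read_vcf(f"{RES}/sim/genotypes.vcf")
    from saltnac import association as am
    am.qc_snps(snps, dosage)

    candidates = select_candidates(genes, members, traj, assoc, snps)
    df = pd.DataFrame(
        [(c.member_number, c.gene_id, c.name, c.group,
          ";".join(f"{d}|{t}|{x}" for d, t, x in c.snps), c.evidence)
         for c in candidates],
        columns=["member", "gene_id", "name", "group", "snps", "evidence"])
    snio.write_tsv(df, f"{RES}/candidates.tsv")

    truth = TruthSet.from_json(f"{RES}/sim/truth.json")
    spiked = {sid.split("_snp")[0] for sid, _, _ in truth.causal_snps}
    got = set(df.gene_id)
    print(f"{len(candidates)} candidate gene(s):")
    for c in candidates:
        print(f"  {c.name} ({c.gene_id}): {c.evidence}")
    print(f"truth check: {len(got & spiked)}/{len(spiked)} spiked causal "
          f"genes recovered"
          + ("" if got == spiked else f"; extras: {sorted(got - spiked)}"))


if __name__ == "__main__":
    main()
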