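"""Pipeline orchestration and candidate-gene selection.

A candidate is a gene whose expression shows the successive-upregulation
trajectory (Group 4) and whose gene region (2000 bp upstream of the start
codon through 500 bp past the stop codon) carries at least one significant,
QC-passing SNP in the association scan.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from . import association as assoc_mod
from . import catalog as cat_mod
from . import expression as expr_mod
from . import haplotype as hap_mod
from . import io as snio
from .models import GeneModel, SNPRecord, ROOT_TRAITS
from .simulate import SimConfig, simulate_to_dir, read_regions_fasta


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class CandidateGene:
    member_number: int
    gene_id: str
    name: str
    group: int
    snps: list[tuple[str, str, str]]  # (display_id, trait, context)
    evidence: str = ""


@dataclass
class PipelineConfig:
    out_dir: str
    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | None = None  # use an existing bundle instead of simulating
    n_pcs: int = 3
    traits: tuple[str, ...] = ROOT_TRAITS
    identity_threshold: float = 0.9
    p_threshold: float = assoc_mod.P_SIGNIFICANT


def select_candidates(genes: list[GeneModel], members, trajectories: pd.DataFrame,
                      assoc: pd.DataFrame, snps: list[SNPRecord],
                      p_threshold: float = assoc_mod.P_SIGNIFICANT,
                      ) -> list[CandidateGene]:
    """Group-4 genes with >= 1 significant QC-passing SNP in their region."""
    for df, stage in ((trajectories, "trajectories"), (assoc, "association")):
        if df is None or (hasattr(df, "empty") and df.empty and stage == "trajectories"):
            raise PipelineError(f"missing upstream table from stage {stage}")
    name_of = {gid: m.names[gid] for m in members for gid in m.names}
    member_of = {gid: m.member_number for m in members for gid in m.copies}
    group_of = {gid: (int(gr) if pd.notna(gr) else None)
                for gid, gr in zip(trajectories.gene_id, trajectories.group)}
    snp_by_id = {s.snp_id: s for s in snps}
    sig = assoc[assoc.p_value < p_threshold]
    hits_by_snp: dict[str, list[str]] = {}
    for r in sig.itertuples():
        hits_by_snp.setdefault(r.snp_id, []).append(r.trait)

    out = []
    for g in genes:
        if g.gene_id not in member_of or group_of.get(g.gene_id) != 4:
            continue
        region = hap_mod.gene_region_snps(g, list(snp_by_id.values()))
        triples = []
        for s in region:
            if not s.qc_pass or s.snp_id not in hits_by_snp:
                continue
            try:
                context, _ = assoc_mod.annotate_snp_context(s, g)
            except ValueError:
                context = "na"
            for trait in sorted(set(hits_by_snp[s.snp_id])):
                triples.append((s.display_id, trait, context))
        if triples:
            out.append(CandidateGene(
                member_number=member_of[g.gene_id], gene_id=g.gene_id,
                name=name_of.get(g.gene_id, g.gene_id), group=4,
                snps=sorted(set(triples)),
                evidence=(f"Group 4 trajectory; {len(set(t[0] for t in triples))} "
                          f"significant region SNP(s)")))
    out.sort(key=lambda c: (c.member_number, c.gene_id))
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate (optional) -> catalog -> express -> associate -> haplotype ->
    candidates; returns the manifest (also written to out_dir)."""
    out = snio.ensure_dir(config.out_dir)
    manifest: dict = {"version": __version__, "seed": config.sim.seed,
                      "thresholds": {
                          "identity": config.identity_threshold,
                          "tandem_gap_bp": cat_mod.TANDEM_GAP_BP,
                          "log2fc": expr_mod.LOG2FC_THRESHOLD,
                          "de_fdr": expr_mod.FDR_THRESHOLD,
                          "maf_min": assoc_mod.MAF_MIN,
                          "missing_max": assoc_mod.MISSING_MAX,
                          "p_significant": config.p_threshold,
                          "n_pcs": config.n_pcs,
                      }, "stages": {}, "checksums": {}}

    # ---- simulate / load inputs
    try:
        if config.input_dir is None:
            paths = simulate_to_dir(config.sim, f"{out}/sim")
        else:
            d = config.input_dir
            paths = {k: f"{d}/{v}" for k, v in {
                "gff3": "genes.gff3", "proteins": "proteins.fasta",
                "cds": "cds.fasta", "regions": "regions.fasta",
                "fpkm": "fpkm.tsv", "vcf": "genotypes.vcf",
                "phenotypes": "phenotypes.tsv"}.items()}
        genes = snio.load_genes(paths["gff3"], paths["proteins"], paths["cds"])
        fpkm = snio.read_expression_tsv(paths["fpkm"])
        manifest["stages"]["simulate"] = {"n_genes": len(genes)}
    except (OSError, ValueError) as e:
        raise PipelineError(f"stage simulate failed: {e}") from e

    # ---- catalog
    try:
        by_time = expr_mod.parse_sample_columns(fpkm.columns)
        fpkm_0h = fpkm[by_time[0]].mean(axis=1).to_dict()
        members, summary = cat_mod.build_catalog(
            genes, fpkm_0h=fpkm_0h, identity_threshold=config.identity_threshold)
        genes_by_id = {g.gene_id: g for g in genes}
        cat_rows = []
        for m in members:
            cid = {gid: f"m{m.member_number}c{i + 1}"
                   for i, cl in enumerate(m.clusters) for gid in cl}
            for gid in m.copies:
                g = genes_by_id[gid]
                cat_rows.append((gid, m.names[gid], m.member_number, g.chromosome,
                                 g.start, g.end, cid.get(gid, "")))
        cat_df = pd.DataFrame(cat_rows, columns=[
            "gene_id", "name", "member", "chromosome", "start", "end", "cluster_id"])
        snio.write_tsv(cat_df, f"{out}/catalog.tsv")
        with open(f"{out}/catalog_summary.json", "w") as fh:
            json.dump(summary.__dict__, fh, indent=1, sort_keys=True)
        manifest["stages"]["catalog"] = {"n_members": len(members),
                                         "n_family_genes": summary.n_genes}
    except (KeyError, ValueError) as e:
        raise PipelineError(f"stage catalog failed: {e}") from e

    # ---- expression trajectories
    try:
        de = expr_mod.de_scan(fpkm)
        traj = expr_mod.classify_trajectories(de)
        snio.write_tsv(de, f"{out}/de_calls.tsv")
        snio.write_tsv(traj, f"{out}/trajectories.tsv")
        manifest["stages"]["express"] = {
            "n_responsive": int(traj.salt_responsive.sum()),
            "n_group4": int((traj.group == 4).sum())}
    except ValueError as e:
        raise PipelineError(f"stage express failed: {e}") from e

    # ---- association
    try:
        snps, dosage, accessions = snio.read_vcf(paths["vcf"])
        pheno = snio.read_tsv(paths["phenotypes"])
        rsir = assoc_mod.compute_rsir(pheno)
        assoc_mod.qc_snps(snps, dosage)
        results = assoc_mod.associate_all_traits(
            snps, dosage, accessions, rsir[list(config.traits)],
            n_pcs=config.n_pcs)
        results["significant"] = results.p_value < config.p_threshold
        snio.write_tsv(rsir.reset_index(), f"{out}/rsir.tsv")
        snio.write_tsv(results, f"{out}/association.tsv")
        snio.write_tsv(assoc_mod.manhattan_table(results, snps),
                       f"{out}/manhattan.tsv")
        manifest["stages"]["associate"] = {
            "n_snps": len(snps),
            "n_qc_pass": int(sum(s.qc_pass for s in snps)),
            "n_significant": int(results.significant.sum())}
    except (OSError, KeyError, ValueError) as e:
        raise PipelineError(f"stage associate failed: {e}") from e

    # ---- candidates
    try:
        candidates = select_candidates(genes, members, traj, results, snps,
                                       p_threshold=config.p_threshold)
        cand_df = pd.DataFrame(
            [(c.member_number, c.gene_id, c.name, c.group,
              ";".join(f"{d}|{t}|{x}" for d, t, x in c.snps), c.evidence)
             for c in candidates],
            columns=["member", "gene_id", "name", "group", "snps", "evidence"])
        snio.write_tsv(cand_df, f"{out}/candidates.tsv")
        manifest["stages"]["candidates"] = {"n_candidates": len(candidates)}
    except (KeyError, ValueError) as e:
        raise PipelineError(f"stage candidates failed: {e}") from e

    # ---- haplotypes + KASP for each candidate
    try:
        regions = read_regions_fasta(paths["regions"])
        snp_index = {s.snp_id: j for j, s in enumerate(snps)}
        hap_rows, kasp_rows, test_reports = [], [], {}
        for c in candidates:
            g = genes_by_id[c.gene_id]
            region = hap_mod.gene_region_snps(g, snps)
            cols = [snp_index[s.snp_id] for s in region]
            haps = hap_mod.build_haplotypes(region, dosage[:, cols], accessions,
                                            gene_id=c.gene_id)
            for h in haps:
                for acc in h.accessions:
                    hap_rows.append((c.gene_id, c.name, acc, h.label,
                                     h.allele_string))
            trait = c.snps[0][1]
            if len(haps) >= 2 and all(len(h.accessions) >= 2 for h in haps[:2]):
                cmp = hap_mod.haplotype_phenotype_test(haps, rsir, trait)
                test_reports[c.name] = {
                    "trait": trait, "p_value": cmp.p_value,
                    "significant": cmp.significant, "direction": cmp.direction,
                    "mean_hap1": cmp.mean_a, "mean_hap2": cmp.mean_b}
            exonic = [s for s in region if s.qc_pass]
            if exonic and c.gene_id in regions:
                s = exonic[0]
                rstart, rseq = regions[c.gene_id]
                i = s.position - rstart
                try:
                    k = hap_mod.design_kasp(rseq, i, s.ref, s.alt, snp_id=s.snp_id)
                    kasp_rows.append((c.name, s.snp_id, k.fam_primer, k.hex_primer,
                                      k.common_reverse, k.product_length))
                except ValueError as e:
                    kasp_rows.append((c.name, s.snp_id, "", "", "", 0))
        snio.write_tsv(pd.DataFrame(hap_rows, columns=[
            "gene_id", "name", "accession", "haplotype", "allele_string"]),
            f"{out}/haplotypes.tsv")
        snio.write_tsv(pd.DataFrame(kasp_rows, columns=[
            "gene", "snp_id", "fam_primer", "hex_primer", "common_reverse",
            "product_length"]), f"{out}/kasp.tsv")
        with open(f"{out}/haplotype_tests.json", "w") as fh:
            json.dump(test_reports, fh, indent=1, sort_keys=True)
        manifest["stages"]["haplotype"] = {"n_assignments": len(hap_rows),
                                           "n_kasp": len(kasp_rows)}
    except (OSError, KeyError, ValueError) as e:
        raise PipelineError(f"stage haplotype failed: {e}") from e

    for name in ("catalog.tsv", "de_calls.tsv", "trajectories.tsv", "rsir.tsv",
                 "association.tsv", "manhattan.tsv", "candidates.tsv",
                 "haplotypes.tsv", "kasp.tsv"):
        manifest["checksums"][name] = _sha256(f"{out}/{name}")
    with open(f"{out}/manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
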