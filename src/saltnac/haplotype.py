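"""Gene-region haplotypes, haplotype-phenotype tests, KASP primer design
and two-group trait comparisons.

KASP genotyping uses two allele-specific forward primers that share a
gene-specific 3' part ending on the SNP base and differ only there; each
carries one of the two universal fluorophore tails (FAM / HEX), and a
common reverse primer closes the amplicon.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneModel, GroupComparison, Haplotype, KASPDesign, SNPRecord

logger = logging.getLogger(__name__)

FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
HEX_TAIL = "GAAGGTCGGAGTCAACGGATT"

PROMOTER_BP = 2000
DOWNSTREAM_BP = 500
HAP_TEST_ALPHA = 0.01


# ----------------------------------------------------------- region SNPs

def gene_region_snps(gene: GeneModel, snps: list[SNPRecord]) -> list[SNPRecord]:
    """SNPs within [start codon - 2000 bp, stop codon + 500 bp], 5'->3'."""
    if gene.strand == "+":
        lo, hi = gene.start - PROMOTER_BP, gene.end + DOWNSTREAM_BP
    else:
        lo, hi = gene.start - DOWNSTREAM_BP, gene.end + PROMOTER_BP
    hits = [s for s in snps
            if s.chromosome == gene.chromosome and lo <= s.position <= hi]
    hits.sort(key=lambda s: (s.position, s.snp_id),
              reverse=(gene.strand == "-"))
    return hits


# ------------------------------------------------------------ haplotypes

def build_haplotypes(snps: list[SNPRecord], dosage: np.ndarray,
                     accessions: list[str], gene_id: str = "") -> list[Haplotype]:
    """Distinct allele strings over the region SNPs among retained accessions.

    The panel is treated as inbred: any accession with a missing or
    heterozygous call in the region is excluded (logged). Labels Hap1,
    Hap2, ... go by descending carrier count, ties broken by allele string.
    """
    if dosage.shape != (len(accessions), len(snps)):
        raise ValueError("dosage must be accessions x region SNPs")
    groups: dict[str, list[str]] = {}
    n_excluded = 0
    for i, acc in enumerate(accessions):
        row = dosage[i]
        if np.any(row < 0) or np.any(row == 1):
            n_excluded += 1
            continue
        allele = "".join(s.alt if row[j] == 2 else s.ref
                         for j, s in enumerate(snps))
        groups.setdefault(allele, []).append(acc)
    if n_excluded:
        logger.info("excluded %d accession(s) with missing/het region calls",
                    n_excluded)
    if not groups:
        logger.warning("all accessions excluded; no haplotypes for %s", gene_id)
        return []
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [Haplotype(gene_id=gene_id, snp_ids=[s.snp_id for s in snps],
                      allele_string=allele, accessions=sorted(accs),
                      label=f"Hap{i + 1}")
            for i, (allele, accs) in enumerate(ordered)]


# ----------------------------------------------------------------- tests

def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    return ""


def haplotype_phenotype_test(haplotypes: list[Haplotype], rsir: pd.DataFrame,
                             trait: str, alpha: float = HAP_TEST_ALPHA,
                             ) -> GroupComparison:
    """Welch t-test of a trait's RSIR between Hap1 and Hap2 accessions."""
    by_label = {h.label: h for h in haplotypes}
    if "Hap1" not in by_label or "Hap2" not in by_label:
        raise ValueError("need at least two haplotype groups")
    vals = {}
    for label in ("Hap1", "Hap2"):
        accs = [a for a in by_label[label].accessions if a in rsir.index]
        v = rsir.loc[accs, trait].dropna().to_numpy(float)
        if len(v) < 2:
            raise ValueError(f"{label} has fewer than 2 phenotyped accessions")
        vals[label] = v
    t, p = _welch(vals["Hap1"], vals["Hap2"])
    m1, m2 = vals["Hap1"].mean(), vals["Hap2"].mean()
    direction = ("Hap2 lower" if m2 < m1 else
                 "Hap1 lower" if m1 < m2 else "equal")
    return GroupComparison(trait=trait, mean_a=float(m1), mean_b=float(m2),
                           n_a=len(vals["Hap1"]), n_b=len(vals["Hap2"]),
                           t_statistic=t, p_value=p, significant=p < alpha,
                           stars=_stars(p), direction=direction)


def compare_groups(values_a, values_b, trait: str = "",
                   alpha: float = HAP_TEST_ALPHA) -> GroupComparison:
    """Unequal-variance t-test between two trait samples (n >= 2 each)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    t, p = _welch(a, b)
    return GroupComparison(trait=trait, mean_a=float(a.mean()),
                           mean_b=float(b.mean()), n_a=len(a), n_b=len(b),
                           t_statistic=t, p_value=p, significant=p < alpha,
                           stars=_stars(p),
                           direction=("A lower" if a.mean() < b.mean()
                                      else "B lower" if b.mean() < a.mean()
                                      else "equal"))


# ------------------------------------------------------------ KASP design

def estimate_tm(primer: str) -> float:
    """Wallace 4GC+2AT rule up to 14 bp, GC-fraction linear formula above."""
    seq = primer.upper()
    gc = seq.count("G") + seq.count("C")
    if len(seq) <= 14:
        return float(4 * gc + 2 * (len(seq) - gc))
    return float(64.9 + 41.0 * (gc - 16.4) / len(seq))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def design_kasp(flank: str, snp_index: int, ref: str, alt: str,
                snp_id: str = "", target_tm: float = 60.0,
                fwd_len_range: tuple[int, int] = (18, 25),
                rev_offset_range: tuple[int, int] = (30, 120),
                ) -> KASPDesign:
    """Design the allele-specific forward pair and common reverse primer.

    ``flank`` is the plus-strand sequence around the SNP; ``snp_index`` is
    the 0-based position of the variant base within it. The gene-specific
    forward part is the window ending on the SNP whose estimated Tm is
    closest to ``target_tm`` (ties to the shorter window); the reverse
    primer sits on the opposite strand with its 3' end 30-120 bp
    downstream, chosen the same way. Deterministic throughout.
    """
    flank = flank.upper()
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    if not (len(ref) == len(alt) == 1 and set(ref + alt) <= set("ACGT")):
        raise ValueError("alleles must be single bases")
    if snp_index < 60 or len(flank) - 1 - snp_index < 60:
        raise ValueError("need >= 60 bp of flank on each side of the SNP")
    if flank[snp_index] not in (ref, alt):
        raise ValueError("flank base at SNP matches neither allele")

    lo, hi = fwd_len_range
    best = None
    for L in range(lo, hi + 1):
        if snp_index - L + 1 < 0:
            continue
        part = flank[snp_index - L + 1:snp_index] + ref
        score = (abs(estimate_tm(part) - target_tm), L)
        if best is None or score < best[0]:
            best = (score, part)
    if best is None:
        raise ValueError("no forward window satisfies the length bounds")
    fwd_specific = best[1]
    tm_fwd = estimate_tm(fwd_specific)
    fam = FAM_TAIL + fwd_specific
    hex_ = HEX_TAIL + fwd_specific[:-1] + alt

    olo, ohi = rev_offset_range
    best_rev = None
    for off in range(olo, ohi + 1):
        for L in range(lo, hi + 1):
            a = snp_index + off
            b = a + L
            if b > len(flank):
                continue
            primer = _revcomp(flank[a:b])
            score = (abs(estimate_tm(primer) - target_tm), off, L)
            if best_rev is None or score < best_rev[0]:
                best_rev = (score, primer, a, b)
    if best_rev is None:
        raise ValueError("no reverse window fits in the flank")
    _, rev_primer, a, b = best_rev
    fwd_start = snp_index - len(fwd_specific) + 1
    product_length = b - fwd_start
    return KASPDesign(snp_id=snp_id, fam_primer=fam, hex_primer=hex_,
                      common_reverse=rev_primer, product_length=product_length,
                      tm_forward=tm_fwd, tm_reverse=estimate_tm(rev_primer))
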