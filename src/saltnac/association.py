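"""Relative salt-injury rates, genotype QC and the per-SNP association scan.

RSIR for a root trait is ``(X_CK - X_NaCl) / X_CK x 100%`` where X is the
replicate-level mean over plants; the accession value is the mean of the
per-replicate ratios. The scan regresses RSIR on alt-allele dosage (0/1/2)
with optional genotype principal components as covariates; q-values are
Benjamini-Hochberg over the scan and a SNP is significant when
``-log10 p > 4`` (p < 1e-4), read strictly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import Seq

from .expression import bh_fdr
from .models import GeneModel, SNPRecord, ROOT_TRAITS, CHROMOSOMES

logger = logging.getLogger(__name__)

MAF_MIN = 0.10          # strict >
MISSING_MAX = 0.05      # strict <
P_SIGNIFICANT = 1e-4    # strict <, i.e. -log10 p > 4
PROMOTER_BP = 2000
DOWNSTREAM_BP = 500


# ------------------------------------------------------------------- RSIR

def compute_rsir(pheno: pd.DataFrame) -> pd.DataFrame:
    """Accession x trait RSIR (%) from a tidy phenotype table.

    ``pheno`` columns: accession, trait, condition (CK/NaCl), replicate,
    plant, value. Replicates with X_CK = 0 are undefined and dropped with a
    log entry; an accession x trait cell with no usable replicate is NaN.
    """
    need = {"accession", "trait", "condition", "replicate", "value"}
    if not need.issubset(pheno.columns):
        raise ValueError(f"phenotype table needs columns {sorted(need)}")
    means = (pheno.groupby(["accession", "trait", "condition", "replicate"],
                           sort=True).value.mean().unstack("condition"))
    if not {"CK", "NaCl"}.issubset(means.columns):
        raise ValueError("both CK and NaCl conditions are required")
    bad = means["CK"] == 0
    if bad.any():
        logger.warning("dropping %d replicate(s) with X_CK = 0", int(bad.sum()))
        means = means[~bad]
    ratio = (means["CK"] - means["NaCl"]) / means["CK"] * 100.0
    rsir = ratio.groupby(["accession", "trait"]).mean().unstack("trait")
    rsir.index.name = "accession"
    return rsir


# --------------------------------------------------------------------- QC

def qc_snps(snps: list[SNPRecord], dosage: np.ndarray) -> list[SNPRecord]:
    """Fill maf / missing_rate / qc_pass in place (and return the list).

    MAF is computed on non-missing alleles only; both filters are strict
    (> 10% MAF, < 5% missing).
    """
    n_acc = dosage.shape[0]
    for j, s in enumerate(snps):
        col = dosage[:, j]
        miss = col < 0
        s.missing_rate = float(miss.mean()) if n_acc else 1.0
        n_alleles = 2 * int((~miss).sum())
        if n_alleles == 0:
            s.maf = 0.0
        else:
            af = float(col[~miss].sum()) / n_alleles
            s.maf = min(af, 1.0 - af)
        s.qc_pass = (s.maf > MAF_MIN) and (s.missing_rate < MISSING_MAX)
    return snps


# ------------------------------------------------------------------- scan

def genotype_pcs(dosage: np.ndarray, n_pcs: int) -> np.ndarray:
    """Top principal components of the mean-imputed, centered dosage matrix."""
    if n_pcs == 0:
        return np.empty((dosage.shape[0], 0))
    X = dosage.astype(float)
    X[X < 0] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X -= X.mean(axis=0)
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    if X.shape[1] == 0:
        return np.zeros((dosage.shape[0], n_pcs))
    u, s_, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_pcs, len(s_))
    pcs = u[:, :k] * s_[:k]
    if k < n_pcs:
        pcs = np.hstack([pcs, np.zeros((dosage.shape[0], n_pcs - k))])
    return pcs


def _ols_dosage_p(y: np.ndarray, dose: np.ndarray, covar: np.ndarray,
                  ) -> tuple[float, float]:
    """(beta, p) for the dosage coefficient in y ~ 1 + dose + covar."""
    n = len(y)
    X = np.column_stack([np.ones(n), dose] + ([covar] if covar.size else []))
    k = X.shape[1]
    if n <= k:
        raise ValueError("not enough observations for the model")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - rank
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    if se == 0:
        # zero residual: a perfect fit is maximally significant, a constant
        # null fit is not evidence at all
        return float(coef[1]), 0.0 if coef[1] != 0 else 1.0
    t = coef[1] / se
    return float(coef[1]), float(2 * stats.t.sf(abs(t), dof))


def associate(snps: list[SNPRecord], dosage: np.ndarray,
              accessions: list[str], rsir: pd.DataFrame, trait: str,
              n_pcs: int = 3, qc_pass_only: bool = True) -> pd.DataFrame:
    """Per-SNP linear-model scan of one trait's RSIR.

    Missing genotypes are dropped per SNP (``n_used`` recorded); SNPs with
    no dosage variance after dropping are skipped with a log entry.
    """
    if trait not in rsir.columns:
        raise ValueError(f"trait {trait!r} not in RSIR table")
    y_all = rsir[trait].reindex(accessions).to_numpy(float)
    usable = ~np.isnan(y_all)
    if usable.sum() < 3:
        raise ValueError("need >= 3 accessions with genotype and phenotype")
    if np.nanstd(y_all) == 0:
        raise ValueError(f"phenotype {trait} is constant")
    idx = [j for j, s in enumerate(snps) if s.qc_pass or not qc_pass_only]
    pcs = genotype_pcs(dosage[:, idx] if idx else dosage, n_pcs)

    rows = []
    for j in idx:
        s = snps[j]
        col = dosage[:, j].astype(float)
        mask = usable & (col >= 0)
        dose, y = col[mask], y_all[mask]
        if len(y) < 3 or dose.std() == 0:
            logger.info("skipping %s: no usable dosage variance", s.snp_id)
            continue
        beta, p = _ols_dosage_p(y, dose, pcs[mask])
        rows.append((s.snp_id, trait, int(len(y)), beta, p))
    out = pd.DataFrame(rows, columns=["snp_id", "trait", "n_used", "beta", "p_value"])
    if len(out):
        out["q_value"] = bh_fdr(out.p_value.to_numpy())
        with np.errstate(divide="ignore"):
            out["neg_log10_p"] = -np.log10(out.p_value)
        out["significant"] = out.p_value < P_SIGNIFICANT
    else:
        out["q_value"] = out["neg_log10_p"] = []
        out["significant"] = []
    return out


def associate_all_traits(snps, dosage, accessions, rsir, n_pcs: int = 3,
                         qc_pass_only: bool = True) -> pd.DataFrame:
    frames = [associate(snps, dosage, accessions, rsir, t, n_pcs=n_pcs,
                        qc_pass_only=qc_pass_only)
              for t in ROOT_TRAITS if t in rsir.columns]
    return pd.concat(frames, ignore_index=True)


# ------------------------------------------------------------- annotation

def _cds_index(gene: GeneModel, position: int) -> int | None:
    """0-based index of a genomic position within the spliced CDS, else None."""
    exons = sorted(gene.exons)
    if gene.strand == "+":
        offset = 0
        for s, e in exons:
            if s <= position <= e:
                return offset + (position - s)
            offset += e - s + 1
        return None
    offset = 0
    for s, e in reversed(exons):
        if s <= position <= e:
            return offset + (e - position)
        offset += e - s + 1
    return None


def annotate_snp_context(snp: SNPRecord, gene: GeneModel,
                         ) -> tuple[str, str]:
    """(context, coding_effect) for a SNP within a gene's region window.

    Promoter = 2000 bp 5' of the start codon, 3'-UTR window = 500 bp 3' of
    the stop codon, both strand-aware; exon/intron by the exon intervals.
    Coding effect compares ref vs alt codon through the standard table.
    """
    pos = snp.position
    if gene.strand == "+":
        win_lo, win_hi = gene.start - PROMOTER_BP, gene.end + DOWNSTREAM_BP
        promoter = gene.start - PROMOTER_BP <= pos < gene.start
        utr3 = gene.end < pos <= gene.end + DOWNSTREAM_BP
    else:
        win_lo, win_hi = gene.start - DOWNSTREAM_BP, gene.end + PROMOTER_BP
        promoter = gene.end < pos <= gene.end + PROMOTER_BP
        utr3 = gene.start - DOWNSTREAM_BP <= pos < gene.start
    if not win_lo <= pos <= win_hi:
        raise ValueError(f"{snp.snp_id} at {pos} outside window of {gene.gene_id}")
    if promoter:
        return "promoter", "na"
    if utr3:
        return "utr3", "na"
    ci = _cds_index(gene, pos)
    if ci is None:
        return "intron", "na"
    if not gene.cds:
        return "exon", "na"
    cds = gene.cds.upper()
    ref_b, alt_b = snp.ref.upper(), snp.alt.upper()
    if gene.strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        ref_b, alt_b = ref_b.translate(comp), alt_b.translate(comp)
    if cds[ci] != ref_b:
        raise ValueError(f"{snp.snp_id}: ref allele does not match CDS base")
    c0 = ci // 3 * 3
    ref_codon = cds[c0:c0 + 3]
    alt_codon = ref_codon[:ci - c0] + alt_b + ref_codon[ci - c0 + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "nonsense"
    else:
        effect = "missense"
    return "exon", effect


# -------------------------------------------------------------- manhattan

def manhattan_table(results: pd.DataFrame, snps: list[SNPRecord]) -> pd.DataFrame:
    """Plot-ready table: chromosome order 1A..7D, cumulative coordinate."""
    if results.empty:
        return pd.DataFrame(columns=["snp_id", "trait", "chromosome", "position",
                                     "cumulative_pos", "neg_log10_p"])
    info = {s.snp_id: s for s in snps}
    df = results.copy()
    df["chromosome"] = [info[i].chromosome for i in df.snp_id]
    df["position"] = [info[i].position for i in df.snp_id]
    order = {c: i for i, c in enumerate(CHROMOSOMES)}
    spans = df.groupby("chromosome").position.max()
    offset, offsets = 0, {}
    for chrom in sorted(spans.index, key=order.get):
        offsets[chrom] = offset
        offset += int(spans[chrom]) + 1
    df["cumulative_pos"] = [offsets[c] + p for c, p in zip(df.chromosome, df.position)]
    df["chrom_order"] = df.chromosome.map(order)
    df = df.sort_values(["trait", "chrom_order", "position", "snp_id"],
                        kind="stable").drop(columns="chrom_order")
    return df.reset_index(drop=True)
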