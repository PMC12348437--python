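"""Seeded generator for a synthetic hexaploid genome and study panel.

The generator emulates the structure every downstream stage assumes: a
21-chromosome (1A..7D) genome carrying a transcription-factor family whose
members have homoeologous copies on the A/B/D subgenomes and occasional
tandem clusters; a planted 30-residue consensus motif standing in for the
family's DNA-binding domain; five-time-point salt-stress expression
trajectories in four archetype groups; and a selfing accession panel with
two-haplotype gene regions whose causal alleles act on the NaCl condition
only, so the relative salt-injury rate carries the spiked signal.

Every random draw comes from one ``numpy.random.Generator`` seeded from
``SimConfig.seed``; a fixed config is byte-identical across runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .models import GeneModel, SNPRecord, ROOT_TRAITS, SUBGENOMES, TIME_POINTS
from . import io as snio

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

# Planted consensus standing in for the NAM/NAC DNA-binding domain. Length 30.
NAM_CONSENSUS = "WLPPGFRFHPTDEELVVHYLKRKVAGKPLP"

# One codon per amino acid used for back-translation (plus synonymous
# alternatives drawn at random for wobble variation).
_CODONS = {
    "A": ["GCT", "GCC", "GCA"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGA"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC"], "K": ["AAA", "AAG"],
    "L": ["CTT", "CTG"], "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCA"], "Q": ["CAA", "CAG"], "R": ["CGT", "AGA"],
    "S": ["TCT", "AGC"], "T": ["ACT", "ACC"], "V": ["GTT", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}

TRAIT_MEANS = {  # CK condition means, trait units (cm, cm^2, cm^3, mm, counts)
    "TRL": 50.0, "RSA": 30.0, "RV": 2.0, "RD": 0.5, "RTN": 400.0, "RBN": 300.0,
}

ARCHETYPE_LFC = {  # log2 fold change vs 0 h at 1, 6, 24, 48 HAT
    "group1": (-1.5, -2.0, -2.5, -3.0),   # sustained downregulation
    "group2": (-2.0, -0.5, 1.0, 2.0),     # early dip then steady rise
    "group3": (0.0, 2.0, 2.0, 0.0),       # transient mid-course induction
    "group4": (1.3, 2.0, 2.8, 3.5),       # successive upregulation
    "nonDE": (0.0, 0.0, 0.0, 0.0),
}


class SizingError(ValueError):
    """Chromosome too short to place the requested genes."""


@dataclass
class CausalSpec:
    member: int
    trait: str
    variance_explained: float


@dataclass
class SimConfig:
    seed: int = 1
    n_members: int = 30
    subgenome_presence: float = 0.8
    tandem_fraction: float = 0.27
    tandem_cluster_size_range: tuple[int, int] = (2, 9)
    chromosome_length: int = 600_000_000
    decoy_fraction: float = 0.2
    n_accessions: int = 114
    snps_per_gene_region: int = 4
    causal_spec: list[CausalSpec] = field(default_factory=list)
    causal_maf: float = 0.3
    trajectory_mix: dict[str, float] = field(default_factory=lambda: {
        "group1": 0.05, "group2": 0.05, "group3": 0.05, "group4": 0.175,
        "nonDE": 0.675,
    })
    replicate_cv: float = 0.1
    plant_cv: float = 0.2
    n_plants: int = 10
    n_phenotype_reps: int = 3
    missing_rate: float = 0.01
    het_rate: float = 0.0
    haplotype_structure: str = "two_block"  # or "independent"
    maf_range: tuple[float, float] = (0.15, 0.5)
    base_injury: float = 0.3
    accession_injury_sd: float = 0.05
    mapped_millions: float = 20.0

    def __post_init__(self) -> None:
        total = sum(self.trajectory_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"trajectory_mix sums to {total}, not 1")
        for name in ("n_members", "n_accessions", "snps_per_gene_region",
                     "n_plants", "n_phenotype_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for cs in self.causal_spec:
            if not 0 <= cs.variance_explained < 1:
                raise ValueError("variance_explained must be in [0, 1)")
            if cs.trait not in ROOT_TRAITS:
                raise ValueError(f"unknown trait {cs.trait!r}")
        if not 0 <= self.subgenome_presence <= 1:
            raise ValueError("subgenome_presence must be a probability")
        if self.haplotype_structure not in ("two_block", "independent"):
            raise ValueError("haplotype_structure must be two_block|independent")


@dataclass
class TruthSet:
    """Oracle labels for recovery tests: who belongs where, and why."""

    member_of: dict[str, int | None] = field(default_factory=dict)
    cluster_of: dict[str, str | None] = field(default_factory=dict)
    trajectory_of: dict[str, str] = field(default_factory=dict)
    causal_snps: list[tuple[str, str, float]] = field(default_factory=list)
    hap_block: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        d["causal_snps"] = [tuple(x) for x in d.get("causal_snps", [])]
        return cls(**d)


@dataclass
class GenomeSim:
    genes: list[GeneModel]
    regions: dict[str, tuple[int, str]]  # gene_id -> (genomic start of region, seq)
    truth: TruthSet


@dataclass
class PopulationSim:
    snps: list[SNPRecord]
    dosage: np.ndarray  # accessions x snps, {-1,0,1,2}
    accessions: list[str]
    phenotypes: pd.DataFrame  # tidy: accession, trait, condition, replicate, plant, value
    truth: TruthSet


# ----------------------------------------------------------------- genome

def _random_protein(rng: np.random.Generator, with_motif: bool) -> str:
    length = int(rng.integers(280, 341))
    seq = rng.choice(list(AMINO_ACIDS), size=length)
    if with_motif:
        pos = int(rng.integers(10, length - len(NAM_CONSENSUS) - 10))
        seq[pos:pos + len(NAM_CONSENSUS)] = list(NAM_CONSENSUS)
    return "".join(seq)


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    """Substitute residues at ``rate`` but never inside the planted motif."""
    motif_at = protein.find(NAM_CONSENSUS)
    out = list(protein)
    for i in range(len(out)):
        if motif_at >= 0 and motif_at <= i < motif_at + len(NAM_CONSENSUS):
            continue
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
    return "".join(out)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [_CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in protein]
    codons.append("TGA")
    return "".join(codons)


def _build_gene(rng: np.random.Generator, gene_id: str, chromosome: str,
                body_start: int, protein: str, strand: str,
                promoter_len: int = 2000, downstream_len: int = 500,
                ) -> tuple[GeneModel, int, str]:
    """Lay a coding gene down at ``body_start`` and return its region sequence.

    The region spans promoter + gene body + downstream flank in genomic (+)
    orientation; for a minus-strand gene the transcript-oriented sequence is
    reverse-complemented before placement.
    """
    cds = _back_translate(rng, protein)
    n_exons = int(rng.integers(1, 4))
    cuts = sorted(rng.choice(np.arange(3, len(cds) - 3, 3), size=n_exons - 1,
                             replace=False)) if n_exons > 1 else []
    pieces, prev = [], 0
    for c in list(cuts) + [len(cds)]:
        pieces.append(cds[prev:int(c)])
        prev = int(c)
    introns = ["".join(rng.choice(list(NUCLEOTIDES), size=int(rng.integers(100, 401))))
               for _ in range(len(pieces) - 1)]
    body = pieces[0]
    exon_local = [(0, len(pieces[0]) - 1)]  # transcript-oriented offsets in body
    for intr, piece in zip(introns, pieces[1:]):
        body += intr
        exon_local.append((len(body), len(body) + len(piece) - 1))
        body += piece
    promoter = "".join(rng.choice(list(NUCLEOTIDES), size=promoter_len))
    downstream = "".join(rng.choice(list(NUCLEOTIDES), size=downstream_len))
    region_tx = promoter + body + downstream

    if strand == "+":
        region = region_tx
        gene_start = body_start
        gene_end = body_start + len(body) - 1
        exons = [(gene_start + s, gene_start + e) for s, e in exon_local]
        region_start = gene_start - promoter_len
    else:
        region = _revcomp(region_tx)
        gene_end = body_start + len(body) - 1  # genomic span unchanged
        gene_start = body_start
        # transcript 5' end maps to the genomic high-coordinate end
        exons = sorted((gene_end - e, gene_end - s) for s, e in exon_local)
        region_start = gene_start - downstream_len
    gene = GeneModel(gene_id=gene_id, chromosome=chromosome, start=gene_start,
                     end=gene_end, strand=strand, protein=protein, cds=cds,
                     exons=exons)
    return gene, region_start, region


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_genome(config: SimConfig) -> GenomeSim:
    """Place family members (with homoeologs, tandem clusters) plus decoys."""
    rng = np.random.default_rng(config.seed)
    genes: list[GeneModel] = []
    regions: dict[str, tuple[int, str]] = {}
    truth = TruthSet()

    lo, hi = config.tandem_cluster_size_range
    if config.chromosome_length < 5_000 + (hi - 1) * 10_000_000 * (config.tandem_fraction > 0) \
            or config.chromosome_length < 200_000:
        raise SizingError(
            f"chromosome_length={config.chromosome_length} too small to place genes")

    cluster_sizes = np.arange(lo, hi + 1)
    cluster_probs = 0.5 ** cluster_sizes
    cluster_probs = cluster_probs / cluster_probs.sum()

    for m in range(1, config.n_members + 1):
        group = int(rng.integers(1, 8))
        present = [s for s in SUBGENOMES if rng.random() < config.subgenome_presence]
        if not present:
            present = [SUBGENOMES[int(rng.integers(3))]]
        ancestral = _random_protein(rng, with_motif=True)
        base_pos = int(rng.uniform(0.05, 0.85) * config.chromosome_length)
        has_tandem = rng.random() < config.tandem_fraction
        tandem_sub = present[int(rng.integers(len(present)))] if has_tandem else None
        cluster_size = int(rng.choice(cluster_sizes, p=cluster_probs)) if has_tandem else 1

        for sub in present:
            chrom = f"{group}{sub}"
            n_here = cluster_size if sub == tandem_sub else 1
            pos = base_pos + int(rng.integers(-50_000, 50_000))
            cluster_id = f"m{m}:{chrom}" if n_here > 1 else None
            for k in range(n_here):
                gid = f"SYN{m:03d}{sub}{k + 1}"
                protein = _mutate_protein(rng, ancestral, 0.02)
                gene, region_start, region = _build_gene(
                    rng, gid, chrom, pos, protein,
                    strand="+" if rng.random() < 0.5 else "-")
                genes.append(gene)
                regions[gid] = (region_start, region)
                truth.member_of[gid] = m
                truth.cluster_of[gid] = cluster_id
                gap = int(rng.integers(500_000, 8_000_001))
                pos = gene.end + gap
                if pos + 20_000 > config.chromosome_length:
                    raise SizingError("chromosome_length too small for tandem cluster")

    n_family = len(genes)
    n_decoys = int(round(config.decoy_fraction * n_family))
    for d in range(1, n_decoys + 1):
        gid = f"DECOY{d:03d}"
        chrom = f"{int(rng.integers(1, 8))}{SUBGENOMES[int(rng.integers(3))]}"
        pos = int(rng.uniform(0.05, 0.9) * config.chromosome_length)
        protein = _random_protein(rng, with_motif=False)
        gene, region_start, region = _build_gene(
            rng, gid, chrom, pos, protein,
            strand="+" if rng.random() < 0.5 else "-")
        genes.append(gene)
        regions[gid] = (region_start, region)
        truth.member_of[gid] = None
        truth.cluster_of[gid] = None

    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return GenomeSim(genes=genes, regions=regions, truth=truth)


# ------------------------------------------------------------- expression

def generate_expression(genes: list[GeneModel], config: SimConfig,
                        truth: TruthSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM and fragment-count tables (genes x 15 samples), labelling truth.

    Family genes draw an archetype from ``trajectory_mix`` (members named in
    ``causal_spec`` are forced to the successively-upregulated group so the
    candidate stage has its spiked positives); decoys and nonDE genes get
    flat profiles over a spread of baselines including silent and
    low-expression genes.
    """
    rng = np.random.default_rng(config.seed + 1)
    labels = list(config.trajectory_mix)
    probs = np.array([config.trajectory_mix[k] for k in labels])
    causal_members = {cs.member for cs in config.causal_spec}
    sigma = np.sqrt(np.log(1 + config.replicate_cv ** 2))

    samples = [f"T{t:02d}_R{r}" for t in TIME_POINTS for r in (1, 2, 3)]
    fpkm_rows, count_rows = [], []
    for g in genes:
        member = truth.member_of.get(g.gene_id)
        if member is None:
            label = "nonDE"
        elif member in causal_members:
            label = "group4"
        else:
            label = labels[int(rng.choice(len(labels), p=probs))]
        truth.trajectory_of[g.gene_id] = label

        if label == "nonDE":
            u = rng.random()
            if u < 0.25:
                baseline = 0.0
            elif u < 0.6:
                baseline = float(rng.uniform(0.05, 0.9))
            else:
                baseline = float(np.exp(rng.uniform(np.log(1.5), np.log(60))))
        else:
            baseline = float(np.exp(rng.uniform(np.log(5), np.log(80))))

        lfc = (0.0,) + ARCHETYPE_LFC[label]
        row = []
        for ti, t in enumerate(TIME_POINTS):
            mean = baseline * 2.0 ** lfc[ti]
            for _ in range(3):
                noise = np.exp(rng.normal(-sigma ** 2 / 2, sigma)) if sigma > 0 else 1.0
                row.append(mean * noise)
        fpkm_rows.append(row)
        length_kb = len(g.cds or "") / 1000 or 1.0
        count_rows.append([int(round(v * config.mapped_millions * length_kb))
                           for v in row])

    fpkm = pd.DataFrame(fpkm_rows, index=[g.gene_id for g in genes], columns=samples)
    counts = pd.DataFrame(count_rows, index=fpkm.index, columns=samples)
    fpkm.index.name = counts.index.name = "gene_id"
    return fpkm, counts


# ------------------------------------------------------------- population

def representative_gene(genes: list[GeneModel], truth: TruthSet,
                        member: int) -> GeneModel:
    """First copy of a member in (chromosome, start) order."""
    copies = [g for g in genes if truth.member_of.get(g.gene_id) == member]
    if not copies:
        raise KeyError(f"no genes for member {member}")
    return min(copies, key=lambda g: (g.chromosome, g.start, g.gene_id))


def _region_window(g: GeneModel, promoter: int = 2000, downstream: int = 500,
                   ) -> tuple[int, int]:
    if g.strand == "+":
        return g.start - promoter, g.end + downstream
    return g.start - downstream, g.end + promoter


def generate_population(genes: list[GeneModel], config: SimConfig,
                        truth: TruthSet,
                        regions: dict[str, tuple[int, str]] | None = None,
                        ) -> PopulationSim:
    """Inbred panel genotypes plus CK/NaCl root phenotypes.

    Each non-decoy gene region carries ``snps_per_gene_region`` homozygous
    biallelic SNPs. Under the default two-block structure all region SNPs
    ride one accession partition, so the region shows exactly two haplotypes
    in the absence of missing calls. The NaCl trait value is the CK value
    scaled by (1 - injury); causal members add a dosage term to injury sized
    so the relative salt-injury rate carries the requested share of variance.
    """
    rng = np.random.default_rng(config.seed + 2)
    accessions = [f"Acc{i + 1:03d}" for i in range(config.n_accessions)]
    n_acc = config.n_accessions

    causal_by_member = {cs.member: cs for cs in config.causal_spec}
    member_reps = {m: representative_gene(genes, truth, m).gene_id
                   for m in causal_by_member}

    snps: list[SNPRecord] = []
    dos_cols: list[np.ndarray] = []
    gene_block: dict[str, np.ndarray] = {}
    used_pos: dict[str, set[int]] = {}

    family_genes = [g for g in genes if truth.member_of.get(g.gene_id) is not None]
    for g in family_genes:
        member = truth.member_of[g.gene_id]
        is_causal_rep = member_reps.get(member) == g.gene_id
        q = config.causal_maf if is_causal_rep else float(rng.uniform(*config.maf_range))
        block = (rng.random(n_acc) < q).astype(np.int8)
        gene_block[g.gene_id] = block
        truth.hap_block[g.gene_id] = dict(zip(accessions, block.tolist()))

        lo, hi = _region_window(g)
        region = regions.get(g.gene_id) if regions else None
        taken = used_pos.setdefault(g.chromosome, set())
        for j in range(config.snps_per_gene_region):
            while True:
                pos = int(rng.integers(lo, hi + 1))
                if pos not in taken:
                    taken.add(pos)
                    break
            if region is not None:
                rstart, rseq = region
                ref = rseq[pos - rstart] if 0 <= pos - rstart < len(rseq) else "A"
            else:
                ref = NUCLEOTIDES[int(rng.integers(4))]
            alt = NUCLEOTIDES[int(rng.choice([i for i in range(4)
                                              if NUCLEOTIDES[i] != ref]))]
            if config.haplotype_structure == "independent":
                qj = float(rng.uniform(*config.maf_range))
                carrier = (rng.random(n_acc) < qj).astype(np.int8)
            else:
                carrier = block
            dos = (2 * carrier).astype(np.int8)
            if config.het_rate > 0:
                het = rng.random(n_acc) < config.het_rate
                dos[het] = 1
            miss = rng.random(n_acc) < config.missing_rate
            dos[miss] = -1
            snps.append(SNPRecord(snp_id=f"{g.gene_id}_snp{j + 1}",
                                  chromosome=g.chromosome, position=pos,
                                  ref=ref, alt=alt))
            dos_cols.append(dos)

    dosage = (np.column_stack(dos_cols) if dos_cols
              else np.empty((n_acc, 0), np.int8))

    # effect sizes: share of RSIR variance explained by the causal dosage
    meas_var = ((1 - config.base_injury) ** 2 * 2 * config.plant_cv ** 2
                / (config.n_plants * config.n_phenotype_reps))
    sigma_resid = float(np.sqrt(config.accession_injury_sd ** 2 + meas_var))
    betas: dict[tuple[int, str], float] = {}
    for cs in config.causal_spec:
        q = config.causal_maf
        sd_dos = float(np.sqrt(4 * q * (1 - q)))
        beta = np.sqrt(cs.variance_explained / (1 - cs.variance_explained)) \
            * sigma_resid / sd_dos
        if beta > 0.3:
            warnings.warn(f"variance_explained={cs.variance_explained} infeasible "
                          f"given plant_cv; effect truncated")
            beta = 0.3
        betas[(cs.member, cs.trait)] = float(beta)
        rep = member_reps[cs.member]
        for s in snps:
            if s.snp_id.startswith(rep + "_snp"):
                truth.causal_snps.append((s.snp_id, cs.trait, float(beta)))

    rows = []
    for trait in ROOT_TRAITS:
        mu = TRAIT_MEANS[trait]
        acc_scale = np.exp(rng.normal(0, 0.1, size=n_acc))
        injury = config.base_injury + rng.normal(
            0, config.accession_injury_sd, size=n_acc)
        for (member, tr), beta in betas.items():
            if tr != trait:
                continue
            block = gene_block[member_reps[member]]
            dose = 2.0 * block
            injury = injury + beta * (dose - dose.mean())
        injury = np.clip(injury, 0.01, 0.95)
        for rep_i in range(1, config.n_phenotype_reps + 1):
            for cond in ("CK", "NaCl"):
                mean = mu * acc_scale * (1.0 if cond == "CK" else (1 - injury))
                vals = rng.normal(mean[:, None],
                                  (config.plant_cv * mean)[:, None],
                                  size=(n_acc, config.n_plants))
                vals = np.maximum(vals, 0.01 * mean[:, None])
                for ai, acc in enumerate(accessions):
                    for pi in range(config.n_plants):
                        rows.append((acc, trait, cond, rep_i, pi + 1,
                                     float(vals[ai, pi])))
    pheno = pd.DataFrame(rows, columns=["accession", "trait", "condition",
                                        "replicate", "plant", "value"])
    return PopulationSim(snps=snps, dosage=dosage, accessions=accessions,
                         phenotypes=pheno, truth=truth)


# ----------------------------------------------------------------- driver

def simulate_to_dir(config: SimConfig, outdir: str) -> dict[str, str]:
    """Run all three generators and write the on-disk bundle; return paths."""
    snio.ensure_dir(outdir)
    genome = generate_genome(config)
    fpkm, counts = generate_expression(genome.genes, config, genome.truth)
    pop = generate_population(genome.genes, config, genome.truth,
                              regions=genome.regions)

    paths = {
        "gff3": f"{outdir}/genes.gff3",
        "proteins": f"{outdir}/proteins.fasta",
        "cds": f"{outdir}/cds.fasta",
        "regions": f"{outdir}/regions.fasta",
        "fpkm": f"{outdir}/fpkm.tsv",
        "counts": f"{outdir}/counts.tsv",
        "vcf": f"{outdir}/genotypes.vcf",
        "phenotypes": f"{outdir}/phenotypes.tsv",
        "truth": f"{outdir}/truth.json",
    }
    snio.write_gff3(genome.genes, paths["gff3"],
                    chromosome_length=config.chromosome_length)
    snio.write_fasta({g.gene_id: g.protein for g in genome.genes}, paths["proteins"])
    snio.write_fasta({g.gene_id: g.cds for g in genome.genes if g.cds}, paths["cds"])
    with open(paths["regions"], "w") as fh:
        for gid in sorted(genome.regions):
            rstart, seq = genome.regions[gid]
            fh.write(f">{gid} region_start={rstart}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    snio.write_tsv(fpkm.reset_index(), paths["fpkm"])
    snio.write_tsv(counts.reset_index(), paths["counts"])
    snio.write_vcf(pop.snps, pop.dosage, pop.accessions, paths["vcf"])
    snio.write_tsv(pop.phenotypes, paths["phenotypes"])
    genome.truth.to_json(paths["truth"])
    return paths


def read_regions_fasta(path: str) -> dict[str, tuple[int, str]]:
    regions = {}
    from Bio import SeqIO
    for rec in SeqIO.parse(path, "fasta"):
        start = int(dict(kv.split("=") for kv in rec.description.split()[1:])
                    ["region_start"])
        regions[rec.id] = (start, str(rec.seq).upper())
    return regions
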