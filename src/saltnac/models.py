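"""Core domain types shared across the pipeline stages.

Coordinates are 1-based inclusive throughout (GFF3 convention). Chromosomes
are the 21 hexaploid-wheat labels ``1A``..``7D``: the digit is the homoeologous
group, the letter the subgenome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SUBGENOMES = ("A", "B", "D")
CHROMOSOMES = tuple(f"{g}{s}" for g in range(1, 8) for s in SUBGENOMES)

ROOT_TRAITS = ("TRL", "RSA", "RV", "RD", "RTN", "RBN")
TIME_POINTS = (0, 1, 6, 24, 48)  # hours after NaCl treatment


def parse_chromosome(label: str) -> tuple[int, str]:
    """Split ``"3B"`` into ``(3, "B")``; raise on anything else."""
    if len(label) != 2 or label[1] not in SUBGENOMES or not label[0].isdigit():
        raise ValueError(f"not a wheat chromosome label: {label!r}")
    group = int(label[0])
    if not 1 <= group <= 7:
        raise ValueError(f"chromosome group out of range: {label!r}")
    return group, label[1]


@dataclass
class GeneModel:
    """One annotated gene copy: coordinates, strand, sequences, exons."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    protein: str = ""
    cds: str | None = None
    exons: list[tuple[int, int]] = field(default_factory=list)
    # sub-index distinguishing nested duplicates when the source annotation
    # provides one (drives the ".j" name suffix); None otherwise
    sub_index: int | None = None

    def __post_init__(self) -> None:
        parse_chromosome(self.chromosome)
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.cds is not None and len(self.cds) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def group_number(self) -> int:
        return parse_chromosome(self.chromosome)[0]

    @property
    def subgenome(self) -> str:
        return parse_chromosome(self.chromosome)[1]


@dataclass
class FamilyMember:
    """A homoeolog group: its copies, tandem clusters and assigned names."""

    member_number: int = 0
    copies: list[str] = field(default_factory=list)
    clusters: list[list[str]] = field(default_factory=list)
    names: dict[str, str] = field(default_factory=dict)


@dataclass
class DECall:
    """Differential-expression verdict for one gene at one treated time point."""

    gene_id: str
    time: int
    log2fc: float
    p_value: float
    fdr: float
    verdict: str  # up / down / ns


@dataclass
class SNPRecord:
    snp_id: str
    chromosome: str
    position: int
    ref: str
    alt: str
    maf: float = 0.0
    missing_rate: float = 0.0
    qc_pass: bool = False
    context: str | None = None  # promoter / exon / intron / utr3
    coding_effect: str | None = None  # synonymous / missense / nonsense / na

    @property
    def display_id(self) -> str:
        """Short id used in reports: last four digits of the position plus alleles."""
        return f"{self.position % 10000:04d}[{self.ref}/{self.alt}]"


@dataclass
class Haplotype:
    gene_id: str
    snp_ids: list[str]
    allele_string: str
    accessions: list[str]
    label: str = ""


@dataclass
class KASPDesign:
    snp_id: str
    fam_primer: str
    hex_primer: str
    common_reverse: str
    product_length: int
    tm_forward: float
    tm_reverse: float


@dataclass
class GroupComparison:
    trait: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    significant: bool
    stars: str = ""
    direction: str = ""
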