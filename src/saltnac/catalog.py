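"""Family cataloguing: domain screen, homoeolog grouping, tandem clusters,
systematic naming, expression classing and catalog summary.

A "member" is a homoeolog group — the set of corresponding gene copies on
the A/B/D subgenomes, plus any tandem duplicates of those copies. Members
are numbered along the genome (chromosome group 1 through 7, then physical
position) and copies named ``<prefix><number>-<subgenome>[<rank>][.<sub>]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import edlib
import networkx as nx
import numpy as np

from .models import GeneModel, FamilyMember, SUBGENOMES
from .simulate import NAM_CONSENSUS, AMINO_ACIDS

TANDEM_GAP_BP = 10_000_000


# ------------------------------------------------------------ domain scan

def motif_score(protein: str, motif: str = NAM_CONSENSUS) -> int:
    """Best-window count of positions matching the consensus."""
    if len(protein) < len(motif):
        return sum(a == b for a, b in zip(protein, motif))
    p = np.frombuffer(protein.encode(), dtype="S1")
    m = np.frombuffer(motif.encode(), dtype="S1")
    k = len(motif)
    windows = np.lib.stride_tricks.sliding_window_view(p, k)
    return int((windows == m).sum(axis=1).max())


def scan_nam_domain(proteins: dict[str, str], motif: str = NAM_CONSENSUS,
                    threshold: float | None = None) -> list[str]:
    """Gene ids whose best motif-window score reaches ``threshold``.

    The default threshold is 90% of the consensus self-score, i.e. up to
    10% mismatching positions are tolerated in the best window.
    """
    if threshold is None:
        threshold = 0.9 * len(motif)
    valid = set(AMINO_ACIDS) | {"X", "*"}
    kept = []
    for gid in sorted(proteins):
        seq = proteins[gid].upper()
        bad = set(seq) - valid
        if bad:
            raise ValueError(f"{gid}: non-amino-acid characters {sorted(bad)}")
        if motif_score(seq, motif) >= threshold:
            kept.append(gid)
    return kept


# ------------------------------------------------------- homoeolog groups

def protein_identity(a: str, b: str) -> float:
    """Global-alignment identity: 1 - edit distance / longer length."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def group_homoeologs(genes: list[GeneModel], identity_threshold: float = 0.9,
                     provided_map: dict[str, int] | None = None,
                     ) -> list[FamilyMember]:
    """Partition genes into members.

    With ``provided_map`` (an external homoeologue annotation, the faithful
    path) the partition is read off directly. Otherwise members are the
    connected components of the graph joining genes of the same chromosome
    group whose protein identity reaches the threshold — across subgenomes
    (homoeologs) or on the same chromosome (tandem duplicates).
    """
    if provided_map is not None:
        missing = [g.gene_id for g in genes if g.gene_id not in provided_map]
        if missing:
            raise ValueError(f"provided_map misses genes: {missing[:5]}")
        by_label: dict[int, list[str]] = {}
        for g in genes:
            by_label.setdefault(provided_map[g.gene_id], []).append(g.gene_id)
        return [FamilyMember(copies=sorted(v)) for _, v in sorted(by_label.items())]

    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    graph = nx.Graph()
    graph.add_nodes_from(g.gene_id for g in genes)
    by_group: dict[int, list[GeneModel]] = {}
    for g in genes:
        by_group.setdefault(g.group_number, []).append(g)
    for group_genes in by_group.values():
        for i, a in enumerate(group_genes):
            for b in group_genes[i + 1:]:
                related = (a.subgenome != b.subgenome
                           or a.chromosome == b.chromosome)
                if related and protein_identity(a.protein, b.protein) >= identity_threshold:
                    graph.add_edge(a.gene_id, b.gene_id)
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort()
    return [FamilyMember(copies=c) for c in comps]


# --------------------------------------------------------- tandem clusters

def detect_tandem_clusters(member: FamilyMember,
                           genes_by_id: dict[str, GeneModel]) -> list[list[str]]:
    """Maximal single-linkage chains of a member's copies on one chromosome
    with consecutive start-coordinate gaps <= 10 Mb; chains of >= 2 genes."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for gid in member.copies:
        g = genes_by_id[gid]
        by_chrom.setdefault(g.chromosome, []).append(g)
    clusters = []
    for chrom in sorted(by_chrom):
        copies = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        chain = [copies[0]]
        for g in copies[1:]:
            if g.start - chain[-1].start <= TANDEM_GAP_BP:
                chain.append(g)
            else:
                if len(chain) >= 2:
                    clusters.append([c.gene_id for c in chain])
                chain = [g]
        if len(chain) >= 2:
            clusters.append([c.gene_id for c in chain])
    return clusters


# ----------------------------------------------------------------- naming

def assign_names(members: list[FamilyMember],
                 genes_by_id: dict[str, GeneModel],
                 prefix: str = "TaNAC") -> list[FamilyMember]:
    """Number members along the genome and name every copy.

    Members are ordered by (lowest chromosome group among copies, lowest
    start on that group, subgenome A<B<D, gene id) and numbered from 1.
    A copy's name is ``prefix + number + "-" + subgenome``; a positional
    rank is appended when its chromosome carries more than one copy of the
    member, and a ``.j`` sub-index when the input annotation provides one.
    """
    seen: set[str] = set()
    for m in members:
        for gid in m.copies:
            if gid in seen:
                raise ValueError(f"duplicate gene id {gid}")
            seen.add(gid)

    def sort_key(m: FamilyMember):
        gs = [genes_by_id[c] for c in m.copies]
        gmin = min(g.group_number for g in gs)
        on_group = [g for g in gs if g.group_number == gmin]
        start = min(g.start for g in on_group)
        sub = min(SUBGENOMES.index(g.subgenome) for g in on_group
                  if g.start == start)
        return (gmin, start, sub, min(g.gene_id for g in on_group))

    ordered = sorted(members, key=sort_key)
    out = []
    for num, m in enumerate(ordered, start=1):
        named = FamilyMember(member_number=num, copies=sorted(m.copies),
                             clusters=[list(c) for c in m.clusters])
        by_chrom: dict[str, list[GeneModel]] = {}
        for gid in named.copies:
            g = genes_by_id[gid]
            by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.start, g.gene_id))
            multi = len(gs) > 1
            for k, g in enumerate(gs, start=1):
                name = f"{prefix}{num}-{g.subgenome}"
                if multi:
                    name += str(k)
                if g.sub_index is not None:
                    name += f".{g.sub_index}"
                named.names[g.gene_id] = name
        out.append(named)
    return out


# ------------------------------------------------- reference cross-match

def match_reference_sequences(catalog_proteins: dict[str, str],
                              external: dict[str, str]) -> list[tuple[str, str | None]]:
    """Match external records to catalog genes by exact full-length identity
    (the 100%-similarity rule); several external names may hit one gene."""
    by_seq: dict[str, str] = {}
    for gid in sorted(catalog_proteins):
        by_seq.setdefault(catalog_proteins[gid].upper(), gid)
    return [(ext_id, by_seq.get(external[ext_id].upper()))
            for ext_id in sorted(external)]


# ------------------------------------------------------ expression class

EXPRESSION_EPS = 1e-9


def classify_expression_level(mean_fpkm: float) -> str:
    """none / low / normal by the FPKM-below-1 rule (silent means <= 1e-9)."""
    if mean_fpkm < 0:
        raise ValueError(f"negative FPKM: {mean_fpkm}")
    if mean_fpkm <= EXPRESSION_EPS:
        return "none"
    return "low" if mean_fpkm < 1.0 else "normal"


def percent(count: int, total: int) -> float:
    """100*count/total rounded half-up to 2 decimal places."""
    if total <= 0:
        raise ValueError("total must be positive")
    return float((Decimal(100) * Decimal(count) / Decimal(total))
                 .quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CatalogSummary:
    n_genes: int
    n_members: int
    per_chromosome: dict[str, int]
    n_tandem_members: int
    class_counts: dict[str, int]
    class_percentages: dict[str, float]
    tandem_member_pct: float = field(default=0.0)


def summarize_catalog(members: list[FamilyMember],
                      genes_by_id: dict[str, GeneModel],
                      expression_class: dict[str, str]) -> CatalogSummary:
    gene_ids = [gid for m in members for gid in m.copies]
    n = len(gene_ids)
    if n == 0:
        raise ValueError("empty catalog")
    unclassified = [g for g in gene_ids if g not in expression_class]
    if unclassified:
        raise ValueError(f"genes without expression class: {unclassified[:5]}")
    per_chrom: dict[str, int] = {}
    for gid in gene_ids:
        c = genes_by_id[gid].chromosome
        per_chrom[c] = per_chrom.get(c, 0) + 1
    counts = {"normal": 0, "low": 0, "none": 0}
    for gid in gene_ids:
        counts[expression_class[gid]] += 1
    n_tandem = sum(1 for m in members if m.clusters)
    return CatalogSummary(
        n_genes=n, n_members=len(members),
        per_chromosome=dict(sorted(per_chrom.items())),
        n_tandem_members=n_tandem,
        class_counts=counts,
        class_percentages={k: percent(v, n) for k, v in counts.items()},
        tandem_member_pct=percent(n_tandem, len(members)),
    )


# ----------------------------------------------------------- convenience

def build_catalog(genes: list[GeneModel], fpkm_0h: dict[str, float] | None = None,
                  identity_threshold: float = 0.9,
                  provided_map: dict[str, int] | None = None,
                  motif: str = NAM_CONSENSUS,
                  prefix: str = "TaNAC") -> tuple[list[FamilyMember], CatalogSummary | None]:
    """Screen, group, cluster and name in one pass.

    ``fpkm_0h`` (mean reference-condition FPKM per gene) enables the
    expression classing and summary; without it only the named members are
    returned.
    """
    genes_by_id = {g.gene_id: g for g in genes}
    kept = set(scan_nam_domain({g.gene_id: g.protein for g in genes}, motif=motif))
    family = [g for g in genes if g.gene_id in kept]
    members = group_homoeologs(family, identity_threshold=identity_threshold,
                               provided_map=provided_map)
    for m in members:
        m.clusters = detect_tandem_clusters(m, genes_by_id)
    members = assign_names(members, genes_by_id, prefix=prefix)
    summary = None
    if fpkm_0h is not None:
        classes = {gid: classify_expression_level(fpkm_0h[gid])
                   for m in members for gid in m.copies}
        summary = summarize_catalog(members, genes_by_id, classes)
    return members, summary
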