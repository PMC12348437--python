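"""Domain screen, member grouping, tandem chaining, naming and summary."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saltnac.catalog import (assign_names, build_catalog,
                             classify_expression_level, detect_tandem_clusters,
                             group_homoeologs, match_reference_sequences,
                             motif_score, percent, protein_identity,
                             scan_nam_domain, summarize_catalog)
from saltnac.models import FamilyMember, GeneModel
from saltnac.simulate import NAM_CONSENSUS


def _gene(gid, chrom, start, protein="", end=None, sub_index=None):
    return GeneModel(gene_id=gid, chromosome=chrom, start=start,
                     end=end or start + 1000, protein=protein,
                     sub_index=sub_index)


class TestDomainScan:
    def test_planted_consensus_retained(self, rng):
        flank = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100))
        prots = {"hit": flank[:50] + NAM_CONSENSUS + flank[50:]}
        assert scan_nam_domain(prots) == ["hit"]

    def test_random_decoy_excluded(self, rng):
        decoy = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 300))
        assert scan_nam_domain({"decoy": decoy}) == []

    def test_empty_input_is_empty_output(self):
        assert scan_nam_domain({}) == []

    def test_non_amino_acid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            scan_nam_domain({"bad": "MKL1QQ"})

    def test_score_counts_best_window_matches(self):
        prot = "A" * 20 + NAM_CONSENSUS + "A" * 20
        assert motif_score(prot) == len(NAM_CONSENSUS)
        # three mismatches drop the score by exactly three
        mutated = NAM_CONSENSUS[:5] + "AAA" + NAM_CONSENSUS[8:]
        assert motif_score("G" * 10 + mutated + "G" * 10) == len(NAM_CONSENSUS) - 3


class TestHomoeologGrouping:
    def test_triad_at_high_identity_is_one_member(self, rng):
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))
        copies = []
        for chrom in ("2A", "2B", "2D"):
            mut = list(base)
            for i in rng.choice(200, size=8, replace=False):  # 96% identity
                mut[i] = "W"
            copies.append(_gene(f"g{chrom}", chrom, 100, "".join(mut)))
        members = group_homoeologs(copies, identity_threshold=0.9)
        assert len(members) == 1 and len(members[0].copies) == 3

    def test_unrelated_genes_stay_singletons(self, rng):
        a = _gene("a", "2A", 100, "".join(rng.choice(list("ACDEFGHIK"), 150)))
        b = _gene("b", "3B", 100, "".join(rng.choice(list("LMNPQRSTV"), 150)))
        members = group_homoeologs([a, b], identity_threshold=0.9)
        assert sorted(len(m.copies) for m in members) == [1, 1]

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            group_homoeologs([], identity_threshold=1.5)

    def test_provided_map_is_taken_verbatim(self):
        genes = [_gene("x", "1A", 1), _gene("y", "1B", 1), _gene("z", "1D", 1)]
        members = group_homoeologs(genes, provided_map={"x": 7, "y": 7, "z": 9})
        parts = sorted(sorted(m.copies) for m in members)
        assert parts == [["x", "y"], ["z"]]

    def test_recovers_simulated_membership(self, genome):
        truth_parts = {}
        family = []
        for g in genome.genes:
            m = genome.truth.member_of[g.gene_id]
            if m is not None:
                truth_parts.setdefault(m, set()).add(g.gene_id)
                family.append(g)
        members = group_homoeologs(family, identity_threshold=0.9)
        got = sorted(sorted(m.copies) for m in members)
        assert got == sorted(sorted(v) for v in truth_parts.values())

    def test_identity_is_symmetric_and_bounded(self, rng):
        a = "".join(rng.choice(list("ACDEFG"), 80))
        b = "".join(rng.choice(list("ACDEFG"), 95))
        ab, ba = protein_identity(a, b), protein_identity(b, a)
        assert ab == ba and 0.0 <= ab <= 1.0
        assert protein_identity(a, a) == 1.0


def _brute_force_clusters(starts: list[int], gap: int = 10_000_000):
    """Transitive closure of the pairwise same-chromosome <=gap relation."""
    n = len(starts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(starts[i] - starts[j]) <= gap:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return sorted(sorted(starts[i] for i in idx)
                  for idx in comps.values() if len(idx) >= 2)


class TestTandemClusters:
    @pytest.mark.parametrize("starts,expected", [
        ([1_000_000, 9_000_000], [[1_000_000, 9_000_000]]),
        ([1_000_000, 25_000_000], []),
        ([1_000_000, 9_000_000, 18_000_000],
         [[1_000_000, 9_000_000, 18_000_000]]),
    ])
    def test_chaining_examples(self, starts, expected):
        genes = {f"g{i}": _gene(f"g{i}", "2D", s) for i, s in enumerate(starts)}
        member = FamilyMember(copies=sorted(genes))
        clusters = detect_tandem_clusters(member, genes)
        got = sorted(sorted(genes[g].start for g in c) for c in clusters)
        assert got == expected

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 21))
            starts = sorted(int(s) for s in
                            rng.integers(1, 80_000_000, size=n))
            starts = list(dict.fromkeys(starts))
            genes = {f"g{i:02d}": _gene(f"g{i:02d}", "5B", s)
                     for i, s in enumerate(starts)}
            member = FamilyMember(copies=sorted(genes))
            got = sorted(sorted(genes[g].start for g in c)
                         for c in detect_tandem_clusters(member, genes))
            assert got == _brute_force_clusters(starts)

    def test_clusters_are_per_chromosome(self):
        genes = {"a": _gene("a", "2A", 1_000_000), "b": _gene("b", "2D", 1_500_000)}
        member = FamilyMember(copies=["a", "b"])
        assert detect_tandem_clusters(member, genes) == []


class TestNaming:
    def test_single_copy_member_gets_subgenome_letter(self):
        genes = {"g1": _gene("g1", "3B", 500)}
        # pad with 32 earlier members so this one lands at number 33
        members = [FamilyMember(copies=["g1"])]
        pad = {}
        for i in range(32):
            gid = f"p{i:02d}"
            pad[gid] = _gene(gid, "1A", 1000 + i * 100_000)
            members.append(FamilyMember(copies=[gid]))
        named = assign_names(members, {**genes, **pad})
        by_gene = {g: n for m in named for g, n in m.names.items()}
        assert by_gene["g1"] == "TaNAC33-B"

    def test_tandem_rank_and_sub_index(self):
        genes = {
            "a": _gene("a", "2D", 1_000_000),
            "b": _gene("b", "2D", 3_000_000),
            "c": _gene("c", "2D", 5_000_000, sub_index=2),
        }
        named = assign_names([FamilyMember(copies=["a", "b", "c"])], genes,
                             prefix="TaNAC")
        # naming here yields member number 1; the grammar is what matters
        assert named[0].names == {"a": "TaNAC1-D1", "b": "TaNAC1-D2",
                                  "c": "TaNAC1-D3.2"}

    def test_lower_chromosome_group_numbered_first(self):
        genes = {"x": _gene("x", "2A", 10), "y": _gene("y", "1D", 10**8)}
        named = assign_names([FamilyMember(copies=["x"]),
                              FamilyMember(copies=["y"])], genes)
        nums = {m.copies[0]: m.member_number for m in named}
        assert nums["y"] == 1 and nums["x"] == 2

    def test_order_invariant_to_input_permutation(self, genome):
        family = [g for g in genome.genes
                  if genome.truth.member_of[g.gene_id] is not None]
        by_id = {g.gene_id: g for g in family}
        members = group_homoeologs(family, identity_threshold=0.9)
        fwd = assign_names(members, by_id)
        rev = assign_names([FamilyMember(copies=list(reversed(m.copies)))
                            for m in reversed(members)], by_id)
        names_fwd = {g: n for m in fwd for g, n in m.names.items()}
        names_rev = {g: n for m in rev for g, n in m.names.items()}
        assert names_fwd == names_rev

    def test_duplicate_gene_ids_rejected(self):
        genes = {"a": _gene("a", "1A", 1)}
        with pytest.raises(ValueError, match="duplicate"):
            assign_names([FamilyMember(copies=["a"]),
                          FamilyMember(copies=["a"])], genes)

    def test_every_copy_named_once_catalog_wide(self, genome, expression_tables):
        members, _ = build_catalog(genome.genes)
        names = [n for m in members for n in m.names.values()]
        copies = [c for m in members for c in m.copies]
        assert len(names) == len(set(names)) == len(copies)


class TestReferenceMatch:
    def test_exact_copy_matches(self):
        table = match_reference_sequences({"g1": "MKLV"}, {"ext": "mklv"})
        assert table == [("ext", "g1")]

    def test_one_residue_difference_unmatched(self):
        table = match_reference_sequences({"g1": "MKLV"}, {"ext": "MKLI"})
        assert table == [("ext", None)]

    def test_many_reported_names_map_to_one_gene(self):
        table = match_reference_sequences(
            {"g1": "MKLV"}, {"extA": "MKLV", "extB": "MKLV"})
        assert table == [("extA", "g1"), ("extB", "g1")]


class TestExpressionClassAndSummary:
    @pytest.mark.parametrize("fpkm,cls", [
        (5.2, "normal"), (1.0, "normal"), (0.4, "low"), (1e-8, "low"),
        (0.0, "none"), (1e-10, "none"),
    ])
    def test_classing(self, fpkm, cls):
        assert classify_expression_level(fpkm) == cls

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            classify_expression_level(-0.1)

    @pytest.mark.parametrize("count,total,expected", [
        (145, 446, 32.51), (182, 446, 40.81), (119, 446, 26.68),
        (32, 118, 27.12), (0, 10, 0.0), (1, 3, 33.33),
    ])
    def test_percent_rounds_half_up(self, count, total, expected):
        assert percent(count, total) == expected

    def test_summary_counts_sum_and_empty_rejected(self, genome):
        members, summary = build_catalog(
            genome.genes,
            fpkm_0h={g.gene_id: 2.0 for g in genome.genes})
        assert sum(summary.class_counts.values()) == summary.n_genes
        assert abs(sum(summary.class_percentages.values()) - 100) <= 0.02
        with pytest.raises(ValueError, match="empty"):
            summarize_catalog([], {}, {})


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(1, 60_000_000), min_size=1, max_size=15, unique=True))
def test_tandem_chaining_property(starts):
    genes = {f"g{i:02d}": _gene(f"g{i:02d}", "7D", s)
             for i, s in enumerate(sorted(starts))}
    member = FamilyMember(copies=sorted(genes))
    got = sorted(sorted(genes[g].start for g in c)
                 for c in detect_tandem_clusters(member, genes))
    assert got == _brute_force_clusters(sorted(starts))
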