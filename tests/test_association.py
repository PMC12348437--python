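"""RSIR arithmetic, SNP QC boundaries, the linear-model scan and annotation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saltnac import association as am
from saltnac.models import GeneModel, SNPRecord
from saltnac.simulate import SimConfig, generate_genome, generate_population


def _pheno(rows):
    return pd.DataFrame(rows, columns=["accession", "trait", "condition",
                                       "replicate", "plant", "value"])


class TestRsir:
    def test_thirty_percent_injury(self):
        rows = [("a1", "TRL", cond, r, p, v)
                for r in (1, 2, 3) for p in (1, 2)
                for cond, v in (("CK", 10.0), ("NaCl", 7.0))]
        rsir = am.compute_rsir(_pheno(rows))
        assert rsir.loc["a1", "TRL"] == pytest.approx(30.0)

    def test_equal_conditions_zero_and_negative_retained(self):
        rows = [("a1", "TRL", "CK", 1, 1, 5.0), ("a1", "TRL", "NaCl", 1, 1, 5.0),
                ("a2", "TRL", "CK", 1, 1, 5.0), ("a2", "TRL", "NaCl", 1, 1, 8.0)]
        rsir = am.compute_rsir(_pheno(rows))
        assert rsir.loc["a1", "TRL"] == pytest.approx(0.0)
        assert rsir.loc["a2", "TRL"] == pytest.approx(-60.0)

    def test_replicate_then_mean_ordering(self):
        # per-replicate ratio first, then averaged: (30% + 50%) / 2
        rows = [("a1", "RV", "CK", 1, 1, 10.0), ("a1", "RV", "NaCl", 1, 1, 7.0),
                ("a1", "RV", "CK", 2, 1, 20.0), ("a1", "RV", "NaCl", 2, 1, 10.0)]
        assert am.compute_rsir(_pheno(rows)).loc["a1", "RV"] == pytest.approx(40.0)

    def test_invariant_to_plant_and_replicate_order(self, rng):
        rows = [("a1", "TRL", cond, r, p, float(10 + rng.random()))
                for r in (1, 2, 3) for p in range(1, 6)
                for cond in ("CK", "NaCl")]
        df = _pheno(rows)
        shuffled = df.sample(frac=1, random_state=5)
        assert am.compute_rsir(df).loc["a1", "TRL"] == pytest.approx(
            am.compute_rsir(shuffled).loc["a1", "TRL"])

    def test_zero_control_dropped(self):
        rows = [("a1", "TRL", "CK", 1, 1, 0.0), ("a1", "TRL", "NaCl", 1, 1, 1.0),
                ("a2", "TRL", "CK", 1, 1, 10.0), ("a2", "TRL", "NaCl", 1, 1, 8.0)]
        rsir = am.compute_rsir(_pheno(rows))
        # the undefined a1 cell is excluded entirely
        assert "a1" not in rsir.index or np.isnan(rsir.loc["a1", "TRL"])
        assert rsir.loc["a2", "TRL"] == pytest.approx(20.0)


def _snp(snp_id="s1", chrom="1B", pos=1000, ref="A", alt="G"):
    return SNPRecord(snp_id=snp_id, chromosome=chrom, position=pos,
                     ref=ref, alt=alt)


class TestQc:
    def test_maf_exactly_ten_percent_fails(self):
        # 10 hom-alt among 100 accessions: 20/200 alleles, MAF = 0.10
        dos = np.zeros((100, 1), np.int8)
        dos[:10, 0] = 2
        s = am.qc_snps([_snp()], dos)[0]
        assert s.maf == pytest.approx(0.10) and not s.qc_pass

    def test_six_missing_of_114_fails(self):
        dos = np.zeros((114, 1), np.int8)
        dos[:40, 0] = 2
        dos[-6:, 0] = -1
        s = am.qc_snps([_snp()], dos)[0]
        assert s.missing_rate == pytest.approx(6 / 114) and not s.qc_pass

    def test_maf_026_no_missing_passes(self):
        dos = np.zeros((100, 1), np.int8)
        dos[:26, 0] = 2
        s = am.qc_snps([_snp()], dos)[0]
        assert s.maf == pytest.approx(0.26) and s.qc_pass

    def test_monomorphic_fails_with_zero_maf(self):
        s = am.qc_snps([_snp()], np.zeros((50, 1), np.int8))[0]
        assert s.maf == 0.0 and not s.qc_pass

    def test_maf_uses_non_missing_alleles_only(self):
        dos = np.full((10, 1), -1, np.int8)
        dos[:4, 0] = 2
        dos[4:8, 0] = 0
        s = am.qc_snps([_snp()], dos)[0]
        assert s.maf == pytest.approx(0.5)


class TestScan:
    @staticmethod
    def _scan_inputs(rng, n=40, n_snps=25):
        dos = (2 * (rng.random((n, n_snps)) < 0.3)).astype(np.int8)
        snps = [_snp(f"s{j}", pos=1000 + j) for j in range(n_snps)]
        am.qc_snps(snps, dos)
        acc = [f"A{i}" for i in range(n)]
        return snps, dos, acc

    def test_closed_form_correlation_t(self, rng):
        """With no covariates the scan p must equal the correlation t-test."""
        snps, dos, acc = self._scan_inputs(rng)
        y = rng.normal(30, 6, size=len(acc))
        rsir = pd.DataFrame({"TRL": y}, index=acc)
        res = am.associate(snps, dos, acc, rsir, "TRL", n_pcs=0,
                           qc_pass_only=False)
        for r in res.itertuples():
            j = int(r.snp_id[1:])
            d = dos[:, j].astype(float)
            mask = d >= 0
            rho = np.corrcoef(d[mask], y[mask])[0, 1]
            n = mask.sum()
            t = abs(rho) * np.sqrt((n - 2) / (1 - rho ** 2))
            p_closed = 2 * stats.t.sf(t, n - 2)
            assert abs(r.p_value - p_closed) < 1e-10

    def test_proportional_phenotype_is_extreme(self, rng):
        dos = np.repeat([0, 2], 6).astype(np.int8).reshape(-1, 1)
        snps = am.qc_snps([_snp()], dos)
        acc = [f"A{i}" for i in range(12)]
        y = 3.0 * dos[:, 0] + 10.0
        rsir = pd.DataFrame({"TRL": y + rng.normal(0, 1e-6, 12)}, index=acc)
        res = am.associate(snps, dos, acc, rsir, "TRL", n_pcs=0)
        assert res.p_value.iloc[0] < 1e-6
        # permutation oracle: no permuted labelling gets close
        obs = abs(np.corrcoef(dos[:, 0], rsir.TRL)[0, 1])
        g = np.random.default_rng(0)
        hits = sum(abs(np.corrcoef(dos[:, 0], g.permutation(rsir.TRL))[0, 1])
                   >= obs - 1e-12 for _ in range(20_000))
        assert (hits + 1) / 20_001 < 5e-3

    def test_null_p_values_uniform(self):
        cfg = SimConfig(seed=77, n_members=30, snps_per_gene_region=12,
                        haplotype_structure="independent", missing_rate=0.0)
        sim = generate_genome(cfg)
        pop = generate_population(sim.genes, cfg, sim.truth, regions=sim.regions)
        am.qc_snps(pop.snps, pop.dosage)
        rsir = am.compute_rsir(pop.phenotypes)
        res = am.associate(pop.snps, pop.dosage, pop.accessions, rsir, "TRL",
                           n_pcs=0)
        assert len(res) >= 1000
        ks = stats.kstest(res.p_value, "uniform")
        assert ks.pvalue > 0.01
        assert int((res.neg_log10_p > 4).sum()) <= 5 * len(res) / 1000

    def test_boundary_p_not_significant(self, rng, monkeypatch):
        snps, dos, acc = self._scan_inputs(rng, n_snps=1)
        rsir = pd.DataFrame({"TRL": rng.normal(30, 6, len(acc))}, index=acc)
        monkeypatch.setattr(am, "_ols_dosage_p", lambda *a: (1.0, 1e-4))
        res = am.associate(snps, dos, acc, rsir, "TRL", n_pcs=0,
                           qc_pass_only=False)
        assert res.neg_log10_p.iloc[0] == pytest.approx(4.0)
        assert not res.significant.iloc[0]

    def test_constant_phenotype_rejected(self, rng):
        snps, dos, acc = self._scan_inputs(rng)
        rsir = pd.DataFrame({"TRL": np.full(len(acc), 5.0)}, index=acc)
        with pytest.raises(ValueError, match="constant"):
            am.associate(snps, dos, acc, rsir, "TRL")

    def test_zero_variance_snp_skipped(self, rng):
        dos = np.zeros((20, 1), np.int8)
        snps = [_snp()]
        acc = [f"A{i}" for i in range(20)]
        rsir = pd.DataFrame({"TRL": rng.normal(30, 6, 20)}, index=acc)
        res = am.associate(snps, dos, acc, rsir, "TRL", qc_pass_only=False)
        assert res.empty

    def test_n_used_accounts_for_missing(self, rng):
        snps, dos, acc = self._scan_inputs(rng, n_snps=1)
        dos[:5, 0] = -1
        rsir = pd.DataFrame({"TRL": rng.normal(30, 6, len(acc))}, index=acc)
        res = am.associate(snps, dos, acc, rsir, "TRL", n_pcs=0,
                           qc_pass_only=False)
        assert res.n_used.iloc[0] == len(acc) - 5


def _coding_gene(strand="+"):
    # 2 exons; CDS = ATG GCT CGA TGC CAA TGA split 9 | 9 around a 100 bp intron
    cds = "ATGGCTCGATGCCAATGA"
    if strand == "+":
        exons = [(1001, 1009), (1110, 1118)]
        start, end = 1001, 1118
    else:
        exons = [(1001, 1009), (1110, 1118)]
        start, end = 1001, 1118
    return GeneModel(gene_id="g", chromosome="2D", start=start, end=end,
                     strand=strand, cds=cds, exons=exons)


class TestAnnotation:
    def test_synonymous_cga_to_cgg(self):
        gene = _coding_gene("+")
        # CDS index 8 = third base of codon CGA -> position 1009
        snp = _snp(pos=1009, ref="A", alt="G")
        assert am.annotate_snp_context(snp, gene) == ("exon", "synonymous")

    def test_nonsense_caa_to_taa(self):
        gene = _coding_gene("+")
        # codon CAA occupies CDS 12..14 -> genomic 1113..1115 (second exon)
        snp = _snp(pos=1113, ref="C", alt="T")
        assert am.annotate_snp_context(snp, gene) == ("exon", "nonsense")

    def test_missense(self):
        gene = _coding_gene("+")
        snp = _snp(pos=1005, ref="C", alt="A")  # GCT -> GAT: Ala -> Asp
        assert am.annotate_snp_context(snp, gene) == ("exon", "missense")

    def test_intron_and_utr3(self):
        gene = _coding_gene("+")
        assert am.annotate_snp_context(_snp(pos=1050, ref="A", alt="G"),
                                       gene)[0] == "intron"
        assert am.annotate_snp_context(_snp(pos=1300, ref="A", alt="G"),
                                       gene)[0] == "utr3"

    def test_promoter_strand_aware(self):
        plus = _coding_gene("+")
        assert am.annotate_snp_context(_snp(pos=1001 - 1500, ref="A", alt="G"),
                                       plus)[0] == "promoter"
        minus = _coding_gene("-")
        # on the minus strand the promoter is 5' of the start codon at the
        # high-coordinate end
        assert am.annotate_snp_context(_snp(pos=1118 + 1500, ref="A", alt="G"),
                                       minus)[0] == "promoter"

    def test_outside_window_rejected(self):
        with pytest.raises(ValueError, match="outside window"):
            am.annotate_snp_context(_snp(pos=500_000, ref="A", alt="G"),
                                    _coding_gene("+"))

    def test_minus_strand_coding_effect(self):
        # same CDS laid on the minus strand: genomic base is the complement
        cds = "ATGGCTCGATGCCAATGA"
        gene = GeneModel(gene_id="g", chromosome="2D", start=1001, end=1018,
                         strand="-", cds=cds, exons=[(1001, 1018)])
        # CDS index 8 ('A' of CGA) sits at genomic 1018 - 8 = 1010, base 'T'
        snp = _snp(pos=1010, ref="T", alt="C")  # A->G on the coding strand
        assert am.annotate_snp_context(snp, gene) == ("exon", "synonymous")


class TestManhattan:
    def test_cumulative_offsets_monotone_in_chromosome_order(self):
        snps = [_snp("a", "1A", 50), _snp("b", "2B", 10), _snp("c", "1A", 80)]
        res = pd.DataFrame({"snp_id": ["a", "b", "c"], "trait": "TRL",
                            "p_value": [0.1, 0.2, 0.3],
                            "neg_log10_p": [1.0, 0.7, 0.5]})
        tab = am.manhattan_table(res, snps)
        assert list(tab.snp_id) == ["a", "c", "b"]
        assert tab.cumulative_pos.is_monotonic_increasing

    def test_empty_input_gives_empty_table(self):
        assert am.manhattan_table(pd.DataFrame(), []).empty

    def test_position_ties_stable_by_snp_id(self):
        snps = [_snp("s2", "3B", 100), _snp("s1", "3B", 100)]
        res = pd.DataFrame({"snp_id": ["s2", "s1"], "trait": "TRL",
                            "p_value": [0.5, 0.5], "neg_log10_p": [0.3, 0.3]})
        tab = am.manhattan_table(res, snps)
        assert list(tab.snp_id) == ["s1", "s2"]
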