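# Methods

This note documents the models and procedures the package implements, the
defaults it chooses where the underlying protocol leaves room, and what the
synthetic data do and do not establish.

## Family catalog

**Domain screen.** The family is defined by a conserved ~30-residue
DNA-binding region. Production surveys find it with a profile HMM; here the
screen is a consensus-motif scan: the best protein window is scored by
matching positions against a 30-residue consensus, and a gene is retained
when the score reaches 90% of the consensus self-score (≤ 3 mismatches in
the best window). This is a deliberate stand-in — it gives the screen a
crisp, testable decision boundary, and the synthetic generator plants the
same consensus, so sensitivity/specificity of the stand-in is exact on
synthetic data. On real proteins a profile search (e.g. hmmer with the
family model) should replace it; the rest of the pipeline only consumes
the retained id list.

**Members.** A member is the set of corresponding copies across the A/B/D
subgenomes plus their tandem duplicates. When an external homoeologue
annotation is available it is taken verbatim (`provided_map`), which is the
faithful path. The inferred fallback joins genes of the same chromosome
group (1–7) whose global protein identity (1 − edit distance / longer
length, via edlib) is ≥ 0.9, either across subgenomes (homoeologs) or on
the same chromosome (tandem duplicates); members are the connected
components. The same-chromosome edge is a package choice: without it a
tandem duplicate with no cross-subgenome partner could never join its
member, contradicting the definition of a tandem cluster as same-member
copies.

**Tandem clusters.** "Within 10 Mb" is read as single-linkage chaining on
consecutive start-coordinate gaps, not as an all-pairs rule: clusters of up
to nine genes are reported in this family, which is implausible if every
pair must sit within 10 Mb. Gaps are measured between start coordinates;
strand is ignored.

**Names.** Members are ordered by (lowest chromosome group, lowest start on
that group, subgenome A<B<D, gene id) and numbered from 1. Every copy name
carries its subgenome letter (`TaNAC33-B`); a positional rank is appended
when one chromosome holds several copies (`TaNAC26-D3`), and a dotted
sub-index when the input annotation distinguishes nested duplicates
(`TaNAC26-D3.2`). The dotted grammar is not fully specified in the
literature this mirrors; the package grammar is explicit and deterministic,
but exact reproduction of any published name set is not claimed.

**Expression classes.** A gene is *silent* when its reference-condition
FPKM is ≤ 1e-9 (measured zero up to float noise), *low* below 1, *normal*
at ≥ 1. Percentages are rounded half-up to 2 dp.

## Expression trajectories

The DE test is a replicate-level Welch t-test on log2(FPKM+1), with fold
change computed on replicate means with a pseudocount of 1, and BH FDR
across genes within each time point. The count-based NB machinery of
dedicated DE packages is intentionally not reimplemented; users with such
output can ingest it (`ingest_de_table`) and everything downstream is
unchanged. Thresholds: |log2FC| ≥ 1 and FDR ≤ 0.01. With both replicate
vectors constant, p is pinned to 1 (equal means) or 0 (different) so the
noise-free limit is well defined.

The four verbal trajectory descriptions are formalized as ordered rules on
the four treated calls (1, 6, 24, 48 h):

1. **Group 2** — down verdict at 1 h AND point-estimate log2FC
   non-decreasing across 1→6→24→48 (an early dip that keeps rising is
   Group 2 even if it never reaches an up verdict);
2. **Group 1** — otherwise, no up verdicts;
3. **Group 4** — otherwise, no down verdicts and up verdicts at both 24 and
   48 h (successive upregulation must still be up at the late points);
4. **Group 3** — everything else (transient/specific induction).

The rule order resolves the overlaps in the verbal definitions; the
requirement of up calls at 24 *and* 48 h for Group 4 is the package's
formalization of "successive upregulation".

## RSIR and association

RSIR is computed per replicate (ratio of plant-mean CK and NaCl values)
and then averaged over replicates — ratio first, mean second. A replicate
with X_CK = 0 is undefined and dropped with a log entry. Negative RSIR
(growth under salt) is retained.

QC keeps SNPs with MAF > 0.10 and missing rate < 0.05, both strict
inequalities, MAF on non-missing alleles only. The scan is an ordinary
least-squares model RSIR ~ 1 + dosage (+ top-k genotype PCs), p from the
dosage t-statistic, missing genotypes dropped per SNP with `n_used`
recorded, q-values by BH over the scan. Mixed-model/kinship corrections
are out of scope; with no population structure in the synthetic panel the
PC covariates default to 3 but can be set to 0, where the scan p equals the
closed-form correlation t-test exactly. Significance is p < 1e-4
(−log10 p > 4, strict).

SNP context is strand-aware: promoter = 2000 bp 5′ of the start codon,
3′-UTR window = 500 bp 3′ of the stop codon, exon/intron by annotation;
coding effects (synonymous / missense / nonsense) come from standard-table
translation of the ref and alt codons.

## Haplotypes and KASP

Accessions with any missing or heterozygous call in a gene region are
excluded from haplotyping rather than phased — the panel is inbred and the
expected structure is two clean groups. Labels go by descending carrier
count with allele-string lexicographic tie-break. The Hap1/Hap2 phenotype
contrast is a Welch t-test at p < 0.01, reported with its direction (lower
RSIR = better tolerance).

KASP design is deterministic and dependency-free: the gene-specific forward
part is the 18–25 bp window ending on the SNP whose estimated Tm is closest
to 60 °C (Wallace 4GC+2AT rule up to 14 bp, a GC-fraction linear formula
above; ties to the shorter window); the FAM-tailed primer ends on the ref
allele and the HEX-tailed on the alt (the tail↔allele mapping is a
convention, not a constraint); the common reverse primer sits on the
opposite strand with its 3′ end 30–120 bp downstream, chosen by the same
Tm rule. Hairpin/dimer screening and other primer-quality criteria beyond
length and Tm are out of scope.

## Synthetic data

The generator emulates, per seed, everything downstream stages assume:

- a 21-chromosome genome (1A..7D) with `n_members` family members, each
  present on a subgenome with probability `subgenome_presence` (0.8),
  copies ≥ 95% identical in protein sequence, plus `tandem_fraction`
  (0.27, the family's observed tandem share) of members carrying a cluster
  of 2–9 copies at consecutive gaps ≤ 8 Mb, and ~20% decoy genes without
  the domain motif;
- five-time-point, three-replicate FPKM with lognormal replicate noise
  (`replicate_cv` 0.1) around four archetype log2FC curves — e.g. the
  successive-upregulation archetype is (+1.3, +2.0, +2.8, +3.5) — and a
  nonDE background spanning silent, low and normal baselines;
- a 114-accession inbred panel in which each gene region's SNPs ride one
  two-way accession partition (so a clean region shows exactly two
  haplotypes), with homozygous calls, 1% missingness, and MAF drawn from
  (0.15, 0.5) (0.3 for causal regions);
- root phenotypes for six traits under CK and NaCl: ten plants per
  replicate, three replicates, plant-level CV 0.2, and an accession injury
  rate 0.30 ± 0.05 to which a causal dosage term is added, scaled so the
  dosage explains the requested share of the final RSIR variance (the
  scaling accounts analytically for plant- and replicate-level measurement
  noise in the ratio). Effects act on the NaCl condition only, so CK traits
  are effect-free and RSIR carries the whole signal.

Replicate and plant-level variability are package choices (no published
values exist for them); they are sized so that the study's decision
thresholds sit well inside the operating range rather than at its edge.

**What passing tests show — and don't.** Recovery results on this
generator validate the pipeline's logic and numerics: labels are
recoverable exactly in the noise-free limit and at stated rates under
noise. They do not show that the thresholds are well-calibrated for real
wheat data: the generator has no LD decay within regions, no population
structure or kinship, lognormal-only expression noise, and archetypes that
match the trajectory rules by construction. Real panels need the
mixed-model caveats above and a real domain screen.

## Numerical choices

- One `numpy.random.Generator` per generator stage, seeded from
  `SimConfig.seed`; fixed config ⇒ byte-identical output files.
- Degenerate tests (zero variance both sides) are pinned to p = 1 / p = 0
  rather than NaN; a perfect regression fit reports p = 0.
- Ties: member ordering (A<B<D, then gene id), haplotype labels
  (frequency, then allele string), manhattan rows (chromosome order,
  position, snp id), KASP windows (Tm distance, then shorter/closer).
- BH is `statsmodels.multipletests(method="fdr_bh")`; an independent
  sort-and-cummin oracle guards it in the tests.

## Problem sizes used in the shipped runs

The demo study is a 30-member family (~100 genes, ~350 SNPs) on a
114-accession panel; power is estimated over 200 regenerated panels of a
12-member genome; the null calibration scans ~1000 independent SNPs; the
noisy trajectory-recovery check uses a 65-member genome (> 200 genes).
These sizes keep the whole suite and the acceptance script within a few
minutes on one CPU while leaving every estimate's Monte-Carlo error well
below the margins being asserted.

## Known limitations

- The association model is a fixed-effects GLM; kinship/mixed models and
  genome-wide scans are out of scope.
- The motif screen is not a profile HMM; borderline real-family proteins
  will behave differently than synthetic ones.
- Tree building (family phylogeny), read alignment, and wet-lab protocol
  steps (PCR programs, EMS mutation confirmation) are not modeled.
- Exact reproduction of published member names and q-values is not
  possible without the original annotation and panel genotypes; the
  package reproduces the *arithmetic* (summary percentages, thresholds,
  formulas) and the *procedures* instead.
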