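# Demo study conditions: a 30-member family on a 21-chromosome genome,
# a 114-accession panel, and three spiked causal members whose regions
# explain 25% of the RSIR variance for one root trait each.
n_members: 30
n_accessions: 114
snps_per_gene_region: 4
tandem_fraction: 0.27
replicate_cv: 0.1
plant_cv: 0.2
n_plants: 10
n_phenotype_reps: 3
missing_rate: 0.01
causal_maf: 0.3
causal_spec:
  - {member: 5, trait: TRL, variance_explained: 0.25}
  - {member: 12, trait: RV, variance_explained: 0.25}
  - {member: 20, trait: RTN, variance_explained: 0.25}
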