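# Study-scale simulation: two species (one highly selfing, one mixed-mating),
# 13 + 12 collection sites, 33 + 31 accessions (<= 3 per site), two selfed
# offspring phenotyped per accession, one genotyped offspring for all but
# three accessions (61 genotyped). Between-species Fst targets 0.44.
# Trait means follow the published species means; `qst` sets the implied
# between-accession variance so the true Qst* matches the published
# per-trait estimate. mean: [cordatotriloba, lacunosa] (sorted label order).
n_loci: 5000
target_fst: 0.44
ancestral_beta: [1.0, 1.0]
seed: 0
design:
  species: [cordatotriloba, lacunosa]
  sites: [13, 12]
  accessions: [33, 31]
  replicates: 2
  genotyped_per_accession: 1
  ungenotyped_accessions: 3
  f_is: [0.7, 0.95]
  site_variance: 0.0
traits:
  - {name: internode_1, mean: [5.67, 13.37], qst: 0.738}
  - {name: internode_2, mean: [6.22, 13.35], qst: 0.537}
  - {name: internode_3, mean: [20.80, 52.20], qst: 0.559}
  - {name: flowers_per_day, mean: [1.87, 4.09], qst: 0.671}
  - {name: inflorescence_length, mean: [19.85, 9.59], qst: 0.355}
  - {name: corolla_length, mean: [32.09, 20.00], qst: 0.837}
  - {name: corolla_width, mean: [34.44, 15.09], qst: 0.892}
  - {name: nectar_volume, mean: [3.33, 0.77], qst: 0.753, min_value: 0.0}
  - {name: nectar_sugar, mean: [361.40, 228.06], qst: 0.824}
  - {name: pollen_per_ovule, mean: [213.00, 157.79], qst: 0.400, min_value: 1.0}
  - {name: herkogamy, mean: [3.35, 0.28], qst: 0.766, integer_round: true}
  - {name: sepal_length, mean: [11.17, 11.16], var_accession: 0.4, var_error: 0.4}
  - {name: leaf_length_width, mean: [1.11, 1.10], var_accession: 0.004, var_error: 0.004}
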