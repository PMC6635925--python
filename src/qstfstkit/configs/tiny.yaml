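# Desk-scale smoke-test fixture: minimal design that still satisfies every
# structural invariant (two species, nested sites/accessions, replication).
n_loci: 80
target_fst: 0.44
ancestral_beta: [1.0, 1.0]
seed: 0
design:
  species: [cordatotriloba, lacunosa]
  sites: [2, 2]
  accessions: [5, 5]
  replicates: 2
  genotyped_per_accession: 1
  ungenotyped_accessions: 0
  f_is: [0.7, 0.95]
traits:
  - {name: corolla_width, mean: [34.44, 15.09], qst: 0.892}
  - {name: nectar_volume, mean: [3.33, 0.77], qst: 0.753, min_value: 0.0}
  - {name: sepal_length, mean: [11.17, 11.16], var_accession: 0.4, var_error: 0.4}
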