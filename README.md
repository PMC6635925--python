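# qstfstkit

Selection-versus-drift inference for quantitative trait divergence between a
highly selfing species and its mixed-mating sister, via univariate and
multivariate Qst–Fst comparisons.

## The problem

When two related plant species differ in a suite of traits — smaller corollas,
less nectar, fewer pollen grains per ovule, reduced herkogamy (the
"selfing syndrome") — the divergence may reflect natural selection or may be
nothing more than genetic drift. The Qst–Fst framework compares the
differentiation of quantitative traits (Qst) against the differentiation of
putatively neutral SNPs (Fst): under pure drift Qst ≈ Fst, while Qst ≫ Fst
indicates divergent selection.

`qstfstkit` implements the full inference pipeline for the two-species nested
design (species → site → accession → selfed-offspring replicate):

- **Genotype side.** Biallelic SNP matrices from VCF or flat tables; "all"
  (polymorphic in ≥ 1 species) and "shared" (polymorphic in both)
  ascertainment; multi-locus Weir–Cockerham θ and Hudson Fst in
  ratio-of-averages form, with percentile bootstrap CIs over loci.
- **Phenotype side.** Measurement-derivation formulas (microcapillary nectar
  volume, refractometer w/w → mg/ml sugar with dilution correction, pollen per
  ovule), per-individual averaging, a three-level nested ANOVA divergence
  screen with Benjamini–Hochberg FDR, and the conservative trait
  differentiation estimate
  **Qst\* = σ²_BetwSp / (σ²_BetwSp + 2 σ²_BetwAcc)**, where the
  between-accession component over-estimates V_A in inbred material, biasing
  the test toward the null.
- **Univariate tests.** A *standard bootstrap* (accessions resampled with
  replacement within species, jointly driving Qst and Fst;
  p = proportion of D = Qst − Fst ≤ 0) and a *parametric bootstrap* that
  simulates neutral D using the drift expectation
  σ²_BetwSp ≈ 2 F̄st V_A / (1 − F̄st) with χ²-distributed mean squares.
- **Multivariate test.** Proportionality of the between-species (G_S) and
  accession-level (G_A) trait covariance matrices: the ML coefficient ρ_Obs
  (Wishart profile likelihood of the species-level SSCP with scale
  G_A(1 + n₀ρ)) with an accession-bootstrap CI, against the neutral
  expectation ρ_Exp = Fst(1 − Fst) (selfing) or 2Fst(1 − Fst) (outcrossing).
- **Synthetic data.** A Balding–Nichols genotype simulator (Fst is a direct
  input; per-species inbreeding coefficients control heterozygosity) and a
  nested-design phenotype simulator whose true Qst\* is known in closed form,
  so every stage is testable without any external download.

## Worked example

Run the packaged study-scale simulation (2 species, 25 sites, 64 accessions,
61 genotyped individuals, 5,000 SNPs at Fst ≈ 0.44, 13 traits) end to end:

```bash
cat > run.yaml <<EOF
simulation: paper_like
seed: 7
n_boot: 1000
output_dir: paper_run
EOF
qstfstkit run-all run.yaml
```

This prints (abridged):

```
Trait divergence (nested ANOVA; * = significant after FDR):
  * corolla_width          F=  455.309 p_fdr=1.525e-15 reldiv=0.54 Qst*=0.927
  * herkogamy              F=  158.470 p_fdr=2.197e-11 reldiv=0.77 Qst*=0.806
  * nectar_volume          F=  123.072 p_fdr=2.257e-10 reldiv=0.72 Qst*=0.767
    sepal_length           F=    0.197 p_fdr=0.6614 reldiv=0.01 Qst*=   NA

Fst (Weir-Cockerham, percentile bootstrap CI over loci):
    all     Fst=0.433 95% CI (0.423, 0.444) n_loci=5000
    shared  Fst=0.346 95% CI (0.334, 0.359) n_loci=2780

Univariate Qst-Fst p-values:
    corolla_width          Qst*=0.927 standard_all=0.000 parametric_all=0.001 ...
    internode_3            Qst*=0.367 standard_all=0.698 parametric_all=0.383 ...

Multivariate proportionality: rho_obs=4.568 CI (3.953, 8.406)
    vs rho_exp=0.2456 CI (0.2441, 0.2469) -> nonneutral
```

Reading the output: the divergence screen stars traits whose species effect
survives the FDR correction; Fst from "all" SNPs exceeds Fst from "shared"
SNPs (the two ascertainments bracket the ascertainment bias); traits
simulated with strong divergence (corolla width, Qst\* ≈ 0.93 vs
Fst ≈ 0.43) are flagged by both bootstrap tests, with the parametric
p-values systematically larger (the two-group χ²₁ null is wide), while
weakly diverged traits (internode 3, pollen) are not; and the multivariate
ρ_Obs CI sits far from the neutral ρ_Exp ≈ 0.25, so the trait suite as a
whole diverged non-neutrally.

Each subcommand (`simulate`, `fst`, `diverge`, `qst`, `uni`, `multi`) exposes
one stage; `qstfstkit --help` lists them.

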