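# Methods

This note documents the statistical models implemented in `qstfstkit`, the
choices made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Fst estimation

Both estimators are multi-locus **ratio-of-averages**: per-locus numerator
and denominator components are summed across loci before dividing. This is
the standard way to stabilise Fst when many loci have little information, and
it is what makes the locus bootstrap below coherent.

**Weir–Cockerham θ (two populations).** For each locus, with observed
per-species sample sizes n₁, n₂ (called individuals only), alternate-allele
frequencies p₁, p₂ and heterozygote frequencies h₁, h₂:

    n̄ = (n₁+n₂)/2,  n_c = (2n̄ − (n₁²+n₂²)/(2n̄)),
    p̄ = weighted mean frequency, s² = weighted frequency variance,
    h̄ = weighted heterozygote frequency,
    a  = n̄/n_c [ s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1) ]       (among species)
    b  = n̄/(n̄−1) [ p̄(1−p̄) − s²/2 − (2n̄−1)/(4n̄) h̄ ]      (among individuals)
    c  = h̄/2                                               (within individuals)

and θ = Σa / Σ(a+b+c). Loci with zero total variance contribute nothing.
Negative multi-locus values (small-sample artifacts near zero
differentiation) are reported as computed, never clamped. Species are the
two "populations"; no site-level hierarchy is fitted, because the design
detects essentially no within-species population structure.

**Hudson.** Per locus, with allele-copy sample sizes m = 2 × called
individuals: numerator (p₁−p₂)² − p₁(1−p₁)/(m₁−1) − p₂(1−p₂)/(m₂−1),
denominator p₁(1−p₂) + p₂(1−p₁). Reported alongside θ; the two agree
closely on all simulated regimes (asserted in the tests).

**Missing data.** Genotypes are never imputed; per-locus sample sizes are
recomputed per estimator. A call-rate hard filter (default: at most one
uncalled individual per locus) runs before estimation, matching a
near-complete-call SNP set.

**Ascertainment.** `all` keeps loci polymorphic in at least one species;
`shared` keeps loci polymorphic in both. Shared ⊆ all on every input, and on
data containing species-private variants Fst(all) ≥ Fst(shared) — the two
modes bracket the ascertainment bias in opposite directions. A locus fixed
for different alleles in the two species is monomorphic *within* each and is
excluded by both modes.

**Confidence intervals.** Percentile bootstrap over loci (default 1,000
replicates), deterministic given the seed. The choice of resampling unit is
a design decision: locus resampling is the convention of the R package
ecosystem this estimator comes from, and Fst uncertainty here is
locus-driven (61 individuals, thousands of SNPs).

## Nested ANOVA and Qst*

All variance components are **method-of-moments** estimates from mean
squares. In balanced designs these coincide with REML; they are closed-form,
dependency-free, and exactly reproducible. Raw (possibly negative) moment
estimates are retained alongside the clamped (≥ 0) values used downstream.

**Divergence screen** (per trait): three-level nested ANOVA, species /
site-in-species / accession-in-site / residual, on per-individual means. The
species mean square is tested against the **site-in-species** stratum
(standard nested-EMS logic; the accession stratum is used only if the design
has no site replication). Benjamini–Hochberg FDR is applied across the trait
family in one step. Pollen per ovule is log-transformed by default (counts
are right-skewed); all other traits are analysed untransformed. The
transformation set is a per-trait configuration, not a hard-coded rule.

**Qst\*** uses the two-level decomposition (species / accession-in-species /
replicate), ignoring sites:

    Qst* = σ²_BetwSp / (σ²_BetwSp + 2 σ²_BetwAcc).

With highly inbred accessions the between-accession component estimates the
total genetic variance V_G ≥ V_A, so Qst\* under-estimates true Qst and the
Qst–Fst comparison is conservative. Unbalanced designs use the weighted
(Sokal–Rohlf) coefficients

    k_rep  = (N − Σᵢⱼ n²ᵢⱼ/nᵢ.) / (A − s)
    k_betw = (Σᵢⱼ n²ᵢⱼ/nᵢ. − Σᵢⱼ n²ᵢⱼ/N) / (s − 1)
    k_acc  = (N − Σᵢ n²ᵢ./N) / (s − 1)

relating expected mean squares to components; all reduce to the replicate
and accession counts in the balanced case (tested against an independent
balanced-case oracle).

## Univariate Qst–Fst tests

**Standard bootstrap.** Accessions are resampled with replacement within
each species; one draw determines *both* the phenotype rows (all replicates
of the chosen accessions, repeats kept as distinct pseudo-accessions) and
the genotype columns (the chosen accessions' genotyped offspring). Qst\*,
Fst and D = Qst\* − Fst are recomputed per iteration;
p = proportion of D ≤ 0. When phenotyped and genotyped accession sets do not
overlap, a flag switches to independent per-table resampling. Resamples that
collapse a species to a single distinct accession are redrawn and logged.
The raw proportion is reported (a p of 0 at 1,000 reps means "< 0.001"); an
optional flag floors the count at 1.

**Parametric bootstrap.** The neutral distribution of D is simulated from
the data's variance scaffolding. Per iteration:

1. Fst is re-estimated from a bootstrap over loci (locus resampling, since
   Fst uncertainty is locus-driven — accession resampling belongs to the
   standard bootstrap).
2. The neutral between-species component is set to the drift expectation
   σ²_BetwSp = 2 Fst V_A / (1 − Fst), with V_A = σ²_BetwAcc divided by the
   sib-relatedness coefficient — 1 for selfed offspring, so the component
   (which estimates V_G ≥ V_A) keeps the test conservative.
3. Species- and accession-level mean squares are drawn from χ² distributions
   scaled by their expectations, with df_B = s − 1 = 1 and
   df_A = A − 2. The single degree of freedom at the species level is the
   dominant driver of this test's low power with two groups.
4. The mean squares are re-solved for components (clamped at zero) and
   recombined; p = proportion of simulated neutral D ≥ observed D.

The mean of the simulated σ²_BetwSp reproduces the drift expectation up to
Monte-Carlo error (asserted in the tests), and on drift-only simulations the
parametric test rejects no more often than the standard bootstrap —
conservative, as expected for a two-group comparison.

## Multivariate proportionality test

Accession means of the selected traits (early growth entering as the
internode sum) are transformed toward normality (log for pollen by default;
per-trait configurable) and **mean-standardised** (divided by the trait's
grand mean). A one-factor MANOVA with species as the factor yields the
within-species mean-square matrix G_A = (residual SSCP)/df_A and the
species-level mean-square matrix MS_B = (between SSCP)/1, from which
G_S = (MS_B − G_A)/n₀ with the unbalanced two-group coefficient
n₀ = (N − Σ nᵢ²/N)/(s−1).

**Conditioning.** Matrices are symmetrised, rounded to 12 decimals (guarding
against loss of symmetry through loss of significance) and eigenvalues below
a floor (default 10⁻¹⁰ × largest) are lifted, so downstream linear algebra
sees positive-definite inputs. The operation is idempotent and never lowers
the smallest eigenvalue.

**ρ_Obs.** Under the proportional model the species-level SSCP
B = df_B·MS_B is Wishart with scale G_A(1 + n₀ρ). The log-density is
profiled over the single unknown ρ by bracketed one-dimensional search
(relative tolerance 10⁻⁸, lower bound 0). On exactly proportional pairs
(G_S = c·G_A) the maximiser is c — recovered to 10⁻⁶ in the tests — and for
one trait it collapses to the scalar ratio g_s/g_a. Because the search
conditions on the *estimated* G_A, ρ̂ carries a small-sample inflation of
order df_A/(df_A − p − 1) (≈ 19% at 62 df and 9 traits); the accession
bootstrap CI reflects the same conditioning, and the construction-oracle
tests account for it explicitly.

**Decision rule.** No analytic CI exists for ρ_Obs (one species-level degree
of freedom), so a percentile CI comes from resampling accessions within
species (1,000 replicates; rank-deficient resamples redrawn with a logged
count). ρ_Exp = m·Fst(1 − Fst) with m = 1 for the selfing-appropriate
multiplier (default; m = 2 for outcrossers is exposed and does not change
qualitative outcomes at these Fst values), and its CI is the Fst CI mapped
through the same function (monotone below Fst = 0.5; the peak is handled
when an interval straddles 0.5). The verdict is **nonneutral** iff the two
open intervals are disjoint.

## Synthetic data generator

The generator's defaults reproduce the study dimensions: two species
(one highly selfing, one mixed-mating), 13 + 12 collection sites, 33 + 31
accessions with at most three per site, two phenotyped selfed offspring per
accession, and one genotyped offspring for all but three accessions
(61 genotyped individuals); between-species Fst targets 0.44.

**Genotypes** follow the Balding–Nichols model: ancestral frequency
p ~ Beta(1, 1), species frequencies ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so F is
a direct input. Individual genotypes use per-species inbreeding coefficients
(defaults 0.7 for the mixed mater, 0.95 for the selfer — high homozygosity
of selfed offspring of partly inbred wild plants); the heterozygote
probability is 2p_s(1−p_s)(1−f). Loci monomorphic in both species are
redrawn, so every simulated locus passes the "all" filter. The
Weir–Cockerham estimate recovers the target within ±0.03 at 5,000 loci.

**Phenotypes**: value = species mean + accession effect N(0, σ²_acc) +
residual N(0, σ²_err). Site effects default to zero (the study design found
no detectable within-species structure) with an optional variance knob.
Because species means are set directly, the implied true Qst\* is
σ²_sp/(σ²_sp + 2σ²_acc) with σ²_sp = (m₁−m₂)²/2, enabling closed-form
recovery tests. The packaged `paper_like` config sets each trait's
accession variance from its published Qst value and uses
σ²_err = σ²_acc — residual noise of the same magnitude as the genetic
signal, the convention used throughout the calibration suites. Herkogamy is
simulated on a latent normal scale with integer rounding into [0, 5]
enabled in the realism config (rounding is disabled in recovery tests, where
exact closed-form recovery matters and generic trait names are used).
Correlated multi-trait phenotypes for the proportionality test draw
accession effects from MVN(0, G_A) and species effects from MVN(0, ρ·G_A).

**What the generator does not emulate**, and hence what passing tests do not
demonstrate about real data: linkage disequilibrium between loci (the study
verified LD pruning did not change estimates), pleiotropy between traits and
genotypes (traits and SNPs are simulated independently), greenhouse
non-flowering (the simulator phenotypes every individual, so the paper-like
dataset has 128 phenotyped plants where the study had 114 after exclusions),
selection acting through correlated characters, and non-Gaussian trait
distributions beyond the pollen log-scale and herkogamy rounding. Nectar
volume and pollen are floored at 0 and 1 respectively in the realism config
to avoid impossible negative measurements; this slightly truncates their
lower tails.

## Numerical choices and problem sizes

- Bootstrap p-values and CIs are deterministic given the run seed; seeds for
  sub-analyses are split from it with a seed sequence.
- Variance components are clamped at zero for reporting; the raw moment
  estimates are retained for diagnostics.
- Qst\* with both components zero, Fst with no polymorphic locus, the
  parametric test with V̂_A ≤ 0, and relative divergence with both means ≤ 0
  are all *signalled* (raised) rather than silently defaulted; inside
  bootstrap loops a degenerate Qst\* resample contributes 0 and degenerate
  accession draws are redrawn with a logged count.
- The calibration suites run at deliberately modest sizes chosen to keep the
  whole test suite fast while leaving comfortable Monte-Carlo margins:
  1,000–2,000 loci, 200 bootstrap reps and 100 seeds for the univariate null
  calibration; 2,000 loci, 1,000 reps and 20 seeds for the multivariate
  verdict calibration; 5,000 loci for Fst recovery. The corresponding
  tolerances come from the Monte-Carlo error at those sizes, not the other
  way round.

## Known limitations

- Method-of-moments components differ from REML in unbalanced designs; the
  divergence F-test denominator (site stratum) is one standard choice among
  defensible alternatives.
- The parametric null's df bookkeeping (χ²₁ at the species level) makes the
  test very conservative for two groups — a property, not a bug, but one to
  keep in mind when p-values hover near α.
- ρ̂ is consistent but biased upward at finite df (inverse-Wishart factor
  above); with two groups its sampling distribution is wide
  (≈ ρ·χ²_p/p across replicate species histories), which the accession
  bootstrap CI only partially captures.
- The verdict rule (CI disjointness) is a decision heuristic, not a
  calibrated hypothesis test; the calibration suite quantifies its operating
  characteristics under the generator's assumptions only.
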