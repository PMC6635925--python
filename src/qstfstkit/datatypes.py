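"""Core data containers for the Qst-Fst analysis pipeline.

Two substrates flow through the pipeline: a biallelic genotype matrix for two
species (the basis of Fst) and a nested-design phenotype table
(species -> site -> accession -> selfed-offspring replicate, the basis of Qst).
Everything downstream -- variance components, Fst estimates, Qst* estimates,
bootstrap test results, G-matrix pairs -- is a small frozen record defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for an uncalled genotype

#: allowed values for the 5-point leaf dissection score
DISSECTION_LEVELS = frozenset({0.0, 0.25, 0.5, 0.75, 1.0})

#: canonical long-form phenotype columns
PHENO_COLUMNS = ["individual", "species", "site", "accession", "trait", "value"]


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class EstimationError(ValueError):
    """A statistic is undefined on the given data (e.g. no polymorphic loci)."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci, stored as alternate-allele counts.

    ``geno[i, l]`` is 0, 1 or 2 (count of the alternate allele carried by
    individual ``i`` at locus ``l``) or ``MISSING`` (-1). Exactly two species
    labels must be present; phase is never stored. ``accessions`` links each
    genotyped individual back to its maternal seed family so that accession
    bootstraps can resample genotypes and phenotypes jointly.
    """

    individual_ids: list[str]
    species: np.ndarray  # shape (n_individuals,), dtype str
    geno: np.ndarray  # shape (n_individuals, n_loci), int8
    locus_ids: list[str]
    accessions: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, dtype=object)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.accessions is None:
            self.accessions = list(self.individual_ids)

    # -- shape helpers -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.geno.shape[0]

    @property
    def n_loci(self) -> int:
        return self.geno.shape[1]

    @property
    def species_labels(self) -> tuple[str, str]:
        labels = sorted(set(self.species.tolist()))
        if len(labels) != 2:
            raise ValidationError(
                f"expected exactly 2 species labels, found {len(labels)}: {labels}"
            )
        return labels[0], labels[1]

    def species_mask(self, label: str) -> np.ndarray:
        return np.asarray(self.species == label)

    def validate(self) -> "GenotypeMatrix":
        if self.geno.ndim != 2:
            raise ValidationError("genotype array must be 2-dimensional")
        if self.geno.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise ValidationError(
                f"genotype shape {self.geno.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        if len(self.species) != len(self.individual_ids):
            raise ValidationError("species labels must align with individuals")
        self.species_labels  # raises unless exactly two
        bad = ~np.isin(self.geno, [0, 1, 2, MISSING])
        if bad.any():
            i, l = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype value {self.geno[i, l]} at individual "
                f"{self.individual_ids[i]}, locus {self.locus_ids[l]} is not in "
                "{0, 1, 2, missing}"
            )
        return self

    # -- subsetting ----------------------------------------------------
    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            geno=self.geno[:, idx],
            locus_ids=[self.locus_ids[int(i)] for i in idx],
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            individual_ids=[self.individual_ids[int(i)] for i in idx],
            species=self.species[idx],
            geno=self.geno[idx, :],
            accessions=[self.accessions[int(i)] for i in idx],
        )


@dataclass
class PhenotypeTable:
    """Long-form phenotype records in the nested greenhouse design.

    One row per (individual, trait, measurement). Accessions are nested in
    sites, sites in species; non-flowering plants simply lack floral rows
    (absence, never zero). ``validate`` enforces the nesting plus the two
    bounded scores: herkogamy (integer count of anthers below the stigma,
    0-5) and leaf dissection (5-point scale {0, 0.25, 0.5, 0.75, 1}).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"phenotype table lacks columns: {missing}")
        self.data = self.data[PHENO_COLUMNS].reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique().tolist())

    @property
    def species_labels(self) -> tuple[str, str]:
        labels = sorted(self.data["species"].unique().tolist())
        if len(labels) != 2:
            raise ValidationError(
                f"expected exactly 2 species labels, found {len(labels)}: {labels}"
            )
        return labels[0], labels[1]

    def validate(self) -> "PhenotypeTable":
        df = self.data
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            bad = df.index[~np.isfinite(df["value"].astype(float))][0]
            raise ValidationError(f"non-finite trait value at row {bad}")
        # nesting: an accession may not appear under two sites, a site not
        # under two species
        acc_sites = df.groupby("accession")["site"].nunique()
        if (acc_sites > 1).any():
            acc = acc_sites.index[acc_sites > 1][0]
            raise ValidationError(f"accession {acc!r} appears under multiple sites")
        site_sp = df.groupby("site")["species"].nunique()
        if (site_sp > 1).any():
            site = site_sp.index[site_sp > 1][0]
            raise ValidationError(f"site {site!r} appears under multiple species")
        ind_acc = df.groupby("individual")["accession"].nunique()
        if (ind_acc > 1).any():
            ind = ind_acc.index[ind_acc > 1][0]
            raise ValidationError(f"individual {ind!r} appears under multiple accessions")
        herk = df.loc[df["trait"] == "herkogamy", "value"]
        if len(herk) and (
            (herk < 0).any() or (herk > 5).any() or (herk != herk.round()).any()
        ):
            raise ValidationError("herkogamy values must be integers in [0, 5]")
        diss = df.loc[df["trait"] == "leaf_dissection", "value"]
        if len(diss) and not diss.isin(sorted(DISSECTION_LEVELS)).all():
            raise ValidationError(
                "leaf_dissection values must lie in {0, 0.25, 0.5, 0.75, 1}"
            )
        return self

    def for_trait(self, trait: str) -> pd.DataFrame:
        out = self.data[self.data["trait"] == trait]
        if out.empty:
            raise KeyError(f"trait {trait!r} not present in phenotype table")
        return out


@dataclass(frozen=True)
class AnalysisConfig:
    """Run-level knobs shared across pipeline stages."""

    n_boot: int = 1000
    seed: int = 0
    ascertainment: str = "all"  # {"all", "shared"}
    mating_system: str = "selfing"  # {"selfing", "outcrossing"}
    eigenvalue_floor: float = 1e-10
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.eigenvalue_floor <= 0:
            raise ValueError("eigenvalue_floor must be positive")
        if self.ascertainment not in ("all", "shared"):
            raise ValueError("ascertainment must be 'all' or 'shared'")
        if self.mating_system not in ("selfing", "outcrossing"):
            raise ValueError("mating_system must be 'selfing' or 'outcrossing'")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")


@dataclass(frozen=True)
class VarianceComponents:
    """Mean squares, df and moment variance components of one nested ANOVA.

    The two-level decomposition (species / accession-in-species / replicate)
    underlies Qst*; ``k_rep``, ``k_between`` and ``k_acc`` are the
    unbalanced-design coefficients relating expected mean squares to the
    variance components. Moment estimates can come out negative; the clamped
    (>= 0) values are reported with the raw estimates retained alongside.
    """

    ms_between_species: float
    ms_between_accessions: float
    ms_within: float
    df_b: int
    df_a: int
    df_w: int
    sigma2_betw_sp: float
    sigma2_betw_acc: float
    sigma2_err: float
    raw_sigma2_betw_sp: float
    raw_sigma2_betw_acc: float
    k_rep: float  # replicates-per-accession coefficient on MS_A
    k_between: float  # accession coefficient on MS_B
    k_acc: float  # effective accessions-per-species coefficient on MS_B


@dataclass(frozen=True)
class DivergenceResult:
    """Species-divergence test for one trait (nested ANOVA, species effect)."""

    trait: str
    mean_1: float
    mean_2: float
    sd_1: float
    sd_2: float
    n_1: int
    n_2: int
    f_ratio: float
    df_num: int
    df_den: int
    p_raw: float
    p_fdr: float
    relative_divergence: float


@dataclass(frozen=True)
class QstEstimate:
    """Conservative quantitative-trait differentiation Qst* for one trait."""

    trait: str
    qst_star: float
    components: VarianceComponents


@dataclass(frozen=True)
class FstEstimate:
    """Multi-locus Fst point estimate with optional percentile bootstrap CI."""

    estimator: str  # {"weir_cockerham", "hudson"}
    value: float
    ci_low: float
    ci_high: float
    n_loci: int
    ascertainment: str

    def __post_init__(self) -> None:
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")


@dataclass
class TestResult:
    """Observed statistic, resampled distribution and p-value of one test."""

    trait: str
    observed_qst: float
    observed_fst: float
    observed_d: float
    distribution: np.ndarray
    p_value: float
    method: str  # {"standard_bootstrap", "parametric_bootstrap"}
    n_iter: int
    seed: int
    ascertainment: str = "all"
    extras: dict = field(default_factory=dict)  # method-specific diagnostics


@dataclass
class GMatrixPair:
    """Accession-level (G_A) and species-level (G_S) trait covariance matrices.

    G_A is the within-species (residual) mean-square matrix of the accession
    means; the species-level mean-square matrix decomposes as
    E[MS_B] = G_A + n0 * Sigma_species, so G_S = (MS_B - G_A) / n0 where n0 is
    the effective accessions-per-species coefficient of the unbalanced
    two-group design.
    """

    g_a: np.ndarray
    g_s: np.ndarray
    df_a: int
    df_b: int
    n0: float
    trait_names: list[str]

    @property
    def ms_b(self) -> np.ndarray:
        """Species-level mean-square matrix implied by (g_a, g_s, n0)."""
        return self.g_a + self.n0 * self.g_s


@dataclass
class ProportionalityResult:
    """Outcome of the multivariate proportionality (rho) test."""

    rho_obs: float
    rho_ci: tuple[float, float]
    rho_exp: float
    rho_exp_ci: tuple[float, float]
    mating_system: str
    verdict: str  # {"neutral", "nonneutral"}
    trait_names: list[str] = field(default_factory=list)

    @staticmethod
    def decide(obs_ci: Sequence[float], exp_ci: Sequence[float]) -> str:
        """CI non-overlap rule: call selection only if the open intervals
        (rho_Obs CI, rho_Exp CI) are disjoint."""
        disjoint = obs_ci[1] < exp_ci[0] or exp_ci[1] < obs_ci[0]
        return "nonneutral" if disjoint else "neutral"
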