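"""Synthetic genotype and phenotype generation for the two-species design.

Genotypes follow the Balding-Nichols model: each locus draws an ancestral
frequency p from a Beta distribution, each species then draws its own
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) with F the target Fst, so
differentiation is a direct input rather than an emergent property.
Individual genotypes allow for inbreeding: heterozygote probability is
2 p_s (1 - p_s) (1 - f_is) with a per-species inbreeding coefficient f_is,
capturing the high homozygosity of selfed offspring. Loci that come out
monomorphic in both species are redrawn, so every simulated locus passes the
"all" ascertainment filter.

Phenotypes follow the nested design species -> site -> accession ->
replicate: value = species mean + accession effect ~ N(0, s2_acc) +
residual ~ N(0, s2_err). Site effects default to zero (the design detects
little within-species structure) with an optional variance knob. Because the
species means are set directly, the implied Qst* is known in closed form:

    Qst* = s2_sp / (s2_sp + 2 s2_acc),   s2_sp = (mean_a - mean_b)^2 / 2

which makes exact parameter-recovery tests possible.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    PHENO_COLUMNS,
)

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: per-species means plus the two variance knobs."""

    name: str
    mean_a: float  # species with the alphabetically first label
    mean_b: float
    var_accession: float
    var_error: float
    integer_round: bool = False  # round to integers in [0, 5] (herkogamy mode)
    min_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.var_accession < 0 or self.var_error < 0:
            raise ValueError("trait variances must be >= 0")

    @property
    def implied_qst_star(self) -> float:
        s2_sp = (self.mean_a - self.mean_b) ** 2 / 2.0
        return s2_sp / (s2_sp + 2.0 * self.var_accession)


@dataclass(frozen=True)
class DesignSpec:
    """Sampling layout: sites and accessions per species, replication."""

    species: tuple[str, str] = ("cordatotriloba", "lacunosa")
    sites: tuple[int, int] = (13, 12)
    accessions: tuple[int, int] = (33, 31)
    replicates: int = 2
    genotyped_per_accession: int = 1
    ungenotyped_accessions: int = 3
    f_is: tuple[float, float] = (0.7, 0.95)
    site_variance: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sites) < 1 or min(self.accessions) < 2 or self.replicates < 1:
            raise ValueError("design counts must be >= 1 (>= 2 accessions/species)")
        if not all(0.0 <= f <= 1.0 for f in self.f_is):
            raise ValueError("f_is must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    n_loci: int = 5000
    target_fst: float = 0.44
    ancestral_beta: tuple[float, float] = (1.0, 1.0)
    design: DesignSpec = field(default_factory=DesignSpec)
    traits: tuple[TraitSpec, ...] = ()
    seed: int = 0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fst < 1.0:
            raise ValueError("target_fst must lie strictly in (0, 1)")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


def var_accession_for_qst(qst: float, mean_a: float, mean_b: float) -> float:
    """Between-accession variance that yields a given true Qst* for the
    stated species means."""
    if not 0.0 < qst <= 1.0:
        raise ValueError("qst must lie in (0, 1]")
    s2_sp = (mean_a - mean_b) ** 2 / 2.0
    return s2_sp * (1.0 - qst) / (2.0 * qst)


def delta_for_qst(qst: float, var_accession: float) -> float:
    """Species-mean difference that yields a given true Qst* for a stated
    between-accession variance (used to build drift-calibrated null traits)."""
    if not 0.0 <= qst < 1.0:
        raise ValueError("qst must lie in [0, 1)")
    return float(2.0 * np.sqrt(qst * var_accession / (1.0 - qst)))


# ----------------------------------------------------------------------
# design table
# ----------------------------------------------------------------------
def build_design(design: DesignSpec) -> pd.DataFrame:
    """One row per accession: species, site, accession id, genotyped flag.

    Accessions are distributed round-robin over sites (so site loads differ
    by at most one); the final ``ungenotyped_accessions`` accessions carry no
    genotyped offspring, emulating phenotyped-but-not-genotyped families.
    """
    rows = []
    for k, sp in enumerate(design.species):
        n_sites, n_acc = design.sites[k], design.accessions[k]
        for j in range(n_acc):
            site = j % n_sites
            rows.append(
                {
                    "species": sp,
                    "site": f"{sp}_site{site:02d}",
                    "accession": f"{sp}_acc{j:02d}",
                }
            )
    df = pd.DataFrame(rows)
    df["genotyped"] = True
    if design.ungenotyped_accessions > 0:
        df.loc[df.index[-design.ungenotyped_accessions:], "genotyped"] = False
    return df


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------
def _species_frequencies(
    cfg: SimulationConfig, n: int, rng: np.random.Generator,
    copy_frequencies: bool,
) -> np.ndarray:
    a, b = cfg.ancestral_beta
    p_anc = rng.beta(a, b, size=n)
    F = cfg.target_fst
    shape = (1.0 - F) / F
    alpha = np.clip(p_anc * shape, 1e-12, None)
    beta = np.clip((1.0 - p_anc) * shape, 1e-12, None)
    p1 = rng.beta(alpha, beta)
    p2 = p1.copy() if copy_frequencies else rng.beta(alpha, beta)
    return np.vstack([p1, p2])


def _draw_genotypes(
    p_s: np.ndarray, f: float, n_ind: int, rng: np.random.Generator
) -> np.ndarray:
    """Genotypes for n_ind individuals of one species; heterozygote
    probability is reduced by the inbreeding coefficient f."""
    p = p_s[np.newaxis, :]
    p_hom_alt = p**2 + f * p * (1.0 - p)
    p_het = 2.0 * p * (1.0 - p) * (1.0 - f)
    u = rng.random((n_ind, p_s.size))
    g = np.zeros((n_ind, p_s.size), dtype=np.int8)
    g[u < p_hom_alt] = 2
    g[(u >= p_hom_alt) & (u < p_hom_alt + p_het)] = 1
    return g


def simulate_genotypes(
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    design_table: Optional[pd.DataFrame] = None,
    copy_frequencies: bool = False,
) -> GenotypeMatrix:
    """Balding-Nichols genotypes for the genotyped offspring of the design.

    Monomorphic-in-both-species loci are redrawn until every locus is
    polymorphic in at least one species. ``copy_frequencies=True`` gives both
    species identical frequencies (a no-differentiation control) instead of
    degenerate F -> 0 parameters.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    design = cfg.design
    if design_table is None:
        design_table = build_design(design)
    gt = design_table[design_table["genotyped"]]

    ind_rows = []
    for _, row in gt.iterrows():
        for r in range(design.genotyped_per_accession):
            ind_rows.append(
                {
                    "individual": f"{row.accession}_g{r}",
                    "species": row.species,
                    "accession": row.accession,
                }
            )
    inds = pd.DataFrame(ind_rows)
    sp_labels = list(design.species)
    masks = [(inds["species"] == sp).to_numpy() for sp in sp_labels]
    n_by_sp = [int(m.sum()) for m in masks]

    geno = np.zeros((len(inds), cfg.n_loci), dtype=np.int8)
    todo = np.arange(cfg.n_loci)
    for attempt in range(200):
        freqs = _species_frequencies(cfg, todo.size, rng, copy_frequencies)
        for k in range(2):
            geno[np.ix_(masks[k], todo)] = _draw_genotypes(
                freqs[k], design.f_is[k], n_by_sp[k], rng
            )
        # redraw loci monomorphic in both species
        poly_any = np.zeros(todo.size, dtype=bool)
        for k in range(2):
            sub = geno[np.ix_(masks[k], todo)]
            alt = sub.sum(axis=0)
            poly_any |= (alt > 0) & (alt < 2 * n_by_sp[k])
        todo = todo[~poly_any]
        if todo.size == 0:
            break
    else:
        logger.warning("%d loci still monomorphic after redraws", todo.size)

    if cfg.missing_rate > 0:
        miss = rng.random(geno.shape) < cfg.missing_rate
        geno[miss] = MISSING

    return GenotypeMatrix(
        individual_ids=inds["individual"].tolist(),
        species=inds["species"].to_numpy(dtype=object),
        geno=geno,
        locus_ids=[f"locus{l}" for l in range(cfg.n_loci)],
        accessions=inds["accession"].tolist(),
    ).validate()


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------
def simulate_phenotypes(
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    design_table: Optional[pd.DataFrame] = None,
) -> PhenotypeTable:
    """Nested-design phenotypes: species mean + accession effect + residual."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    design = cfg.design
    if design_table is None:
        design_table = build_design(design)
    sp_order = {sp: k for k, sp in enumerate(design.species)}

    n_acc = len(design_table)
    n_rep = design.replicates
    site_codes, sites = pd.factorize(design_table["site"])
    records = []
    for trait in cfg.traits:
        # species means are keyed by sorted label order: mean_a belongs to
        # the alphabetically first species label
        means = np.array([trait.mean_a, trait.mean_b])
        sp_mean = means[
            design_table["species"].map(
                {sp: i for i, sp in enumerate(sorted(design.species))}
            ).to_numpy()
        ]
        acc_eff = rng.normal(0.0, np.sqrt(trait.var_accession), size=n_acc)
        site_eff = (
            rng.normal(0.0, np.sqrt(design.site_variance), size=len(sites))
            if design.site_variance > 0
            else np.zeros(len(sites))
        )
        resid = rng.normal(0.0, np.sqrt(trait.var_error), size=(n_acc, n_rep))
        values = (
            sp_mean[:, None] + site_eff[site_codes][:, None] + acc_eff[:, None] + resid
        )
        if trait.min_value is not None:
            values = np.maximum(values, trait.min_value)
        if trait.integer_round:
            values = np.clip(np.round(values), 0, 5)
        for i, row in enumerate(design_table.itertuples()):
            for r in range(n_rep):
                records.append(
                    (
                        f"{row.accession}_p{r}",
                        row.species,
                        row.site,
                        row.accession,
                        trait.name,
                        float(values[i, r]),
                    )
                )
    df = pd.DataFrame(records, columns=PHENO_COLUMNS)
    return PhenotypeTable(df).validate()


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Genotypes and phenotypes over one shared design and seed stream."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_g, rng_p = (np.random.default_rng(s) for s in ss.spawn(2))
    design_table = build_design(cfg.design)
    g = simulate_genotypes(cfg, rng=rng_g, design_table=design_table)
    p = simulate_phenotypes(cfg, rng=rng_p, design_table=design_table)
    return g, p


# ----------------------------------------------------------------------
# correlated multi-trait phenotypes (for the proportionality test)
# ----------------------------------------------------------------------
def simulate_multivariate_phenotypes(
    design: DesignSpec,
    trait_names: Sequence[str],
    base_means: np.ndarray,
    g_a: np.ndarray,
    rho_species: float,
    var_error: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    species_effects: Optional[np.ndarray] = None,
) -> PhenotypeTable:
    """Traits with accession effects ~ MVN(0, G_A) and species effects
    ~ MVN(0, rho_species * G_A), the generative model of the proportionality
    test (under neutral drift rho_species = Fst(1 - Fst) for a selfer).

    ``species_effects`` (2 x p) overrides the random species draw when a
    fixed divergence vector is wanted.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    g_a = np.asarray(g_a, dtype=float)
    p_dim = g_a.shape[0]
    if len(trait_names) != p_dim or len(base_means) != p_dim:
        raise ValueError("trait_names / base_means must match G_A dimension")
    design_table = build_design(design)
    n_acc = len(design_table)
    n_rep = design.replicates

    chol = np.linalg.cholesky(g_a + 1e-12 * np.eye(p_dim))
    if species_effects is None:
        species_effects = (
            np.sqrt(max(rho_species, 0.0))
            * rng.standard_normal((2, p_dim)) @ chol.T
        )
    acc_eff = rng.standard_normal((n_acc, p_dim)) @ chol.T
    sp_idx = design_table["species"].map(
        {sp: i for i, sp in enumerate(sorted(design.species))}
    ).to_numpy()
    base = np.asarray(base_means, dtype=float)

    records = []
    for i, row in enumerate(design_table.itertuples()):
        mu = base + species_effects[sp_idx[i]] + acc_eff[i]
        for r in range(n_rep):
            vals = mu + (
                rng.normal(0.0, np.sqrt(var_error), size=p_dim)
                if var_error > 0
                else 0.0
            )
            for t, name in enumerate(trait_names):
                records.append(
                    (
                        f"{row.accession}_p{r}",
                        row.species,
                        row.site,
                        row.accession,
                        name,
                        float(np.asarray(vals)[t]),
                    )
                )
    return PhenotypeTable(pd.DataFrame(records, columns=PHENO_COLUMNS)).validate()


# ----------------------------------------------------------------------
# named fixture configs
# ----------------------------------------------------------------------
def load_sim_config(source: str | Path | dict) -> SimulationConfig:
    """Load a SimulationConfig from YAML (path or parsed dict) or by fixture
    name (``paper_like``, ``tiny``).

    Trait entries may give ``qst`` instead of ``var_accession``; the
    between-accession variance is then derived so the implied Qst* equals the
    stated value, with ``var_error`` defaulting to the same magnitude.
    """
    if isinstance(source, dict):
        raw = source
    else:
        path = Path(str(source))
        if not path.exists() and not str(source).endswith(".yaml"):
            ref = importlib.resources.files("qstfstkit") / "configs" / f"{source}.yaml"
            raw = yaml.safe_load(ref.read_text())
        else:
            raw = yaml.safe_load(Path(source).read_text())

    d = raw.get("design", {})
    design = DesignSpec(
        species=tuple(d.get("species", ("cordatotriloba", "lacunosa"))),
        sites=tuple(d.get("sites", (13, 12))),
        accessions=tuple(d.get("accessions", (33, 31))),
        replicates=int(d.get("replicates", 2)),
        genotyped_per_accession=int(d.get("genotyped_per_accession", 1)),
        ungenotyped_accessions=int(d.get("ungenotyped_accessions", 3)),
        f_is=tuple(d.get("f_is", (0.7, 0.95))),
        site_variance=float(d.get("site_variance", 0.0)),
    )
    traits = []
    for t in raw.get("traits", []):
        mean_a, mean_b = (float(x) for x in t["mean"])
        if "var_accession" in t:
            var_acc = float(t["var_accession"])
        else:
            var_acc = var_accession_for_qst(float(t["qst"]), mean_a, mean_b)
        var_err = float(t.get("var_error", var_acc))
        traits.append(
            TraitSpec(
                name=str(t["name"]),
                mean_a=mean_a,
                mean_b=mean_b,
                var_accession=var_acc,
                var_error=var_err,
                integer_round=bool(t.get("integer_round", False)),
                min_value=t.get("min_value"),
            )
        )
    return SimulationConfig(
        n_loci=int(raw.get("n_loci", 5000)),
        target_fst=float(raw.get("target_fst", 0.44)),
        ancestral_beta=tuple(raw.get("ancestral_beta", (1.0, 1.0))),
        design=design,
        traits=tuple(traits),
        seed=int(raw.get("seed", 0)),
        missing_rate=float(raw.get("missing_rate", 0.0)),
    )


def paper_like_config(seed: int = 0, n_loci: int = 5000) -> SimulationConfig:
    cfg = load_sim_config("paper_like")
    return replace(cfg, seed=seed, n_loci=n_loci)


def tiny_config(seed: int = 0) -> SimulationConfig:
    cfg = load_sim_config("tiny")
    return replace(cfg, seed=seed)
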