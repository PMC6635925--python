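"""Multivariate Qst-Fst: proportionality of the between- and within-species
G-matrices.

Under neutral divergence the between-species covariance matrix G_S should be
proportional to the within-species (accession-level) matrix G_A, with
coefficient rho_Exp = Fst(1 - Fst) for a highly selfing species (twice that
for an outcrosser). The observed coefficient rho_Obs is estimated by
maximum likelihood from the two mean-square matrices of a one-factor MANOVA
on accession means: the species-level SSCP is modelled as Wishart with scale
G_A (1 + n0 rho), and the likelihood is profiled over the single unknown
rho. Because the two-species contrast leaves only one degree of freedom, no
analytic CI exists; instead accessions are resampled within species
(percentile bootstrap) and the verdict is CI non-overlap between rho_Obs and
rho_Exp.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import (
    AnalysisConfig,
    EstimationError,
    FstEstimate,
    GenotypeMatrix,
    GMatrixPair,
    PhenotypeTable,
    ProportionalityResult,
)
from .fst import ascertain_snps, fst_bootstrap_ci
from .qst import individual_means

logger = logging.getLogger(__name__)

#: default per-trait transforms toward normality (applied before
#: mean-standardisation); pollen counts are right-skewed
DEFAULT_TRANSFORMS: Mapping[str, Callable[[np.ndarray], np.ndarray]] = {
    "pollen_per_ovule": np.log,
}

#: the trait set of the proportionality analysis: early growth enters as the
#: internode sum, nectar and floral dimensions individually
MULTIVARIATE_TRAITS = (
    "internode_sum",
    "flowers_per_day",
    "inflorescence_length",
    "corolla_length",
    "corolla_width",
    "herkogamy",
    "nectar_volume",
    "nectar_sugar",
    "pollen_per_ovule",
)


# ----------------------------------------------------------------------
# accession-level trait matrix
# ----------------------------------------------------------------------
def accession_trait_matrix(
    p: PhenotypeTable,
    traits: Sequence[str],
    transforms: Optional[Mapping[str, Callable]] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Accessions x traits matrix of transformed, mean-standardised means.

    Each trait is averaged to the accession level, passed through its
    normality transform (default: log for pollen, identity otherwise) and
    divided by its grand mean so that traits on different scales contribute
    comparably. Accessions missing any requested trait are dropped with a
    log entry. Returns the matrix and the accession -> species labels.
    """
    if transforms is None:
        transforms = DEFAULT_TRANSFORMS
    im = individual_means(p)
    df = im.data[im.data["trait"].isin(traits)]
    wide = df.pivot_table(
        index="accession", columns="trait", values="value", aggfunc="mean"
    )
    missing_traits = [t for t in traits if t not in wide.columns]
    if missing_traits:
        raise KeyError(f"traits absent from phenotype table: {missing_traits}")
    wide = wide[list(traits)]
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        logger.info(
            "dropped %d accessions lacking >=1 trait: %s",
            len(incomplete),
            list(incomplete[:5]),
        )
        wide = wide.drop(index=incomplete)
    for t in traits:
        fn = transforms.get(t)
        if fn is not None:
            wide[t] = fn(wide[t].to_numpy())
    grand = wide.mean(axis=0)
    if (grand == 0).any():
        raise EstimationError("cannot mean-standardise a trait with zero grand mean")
    wide = wide / grand
    species = (
        df.drop_duplicates("accession").set_index("accession")["species"]
        .loc[wide.index]
    )
    return wide, species


# ----------------------------------------------------------------------
# G-matrix estimation (one-factor MANOVA on accession means)
# ----------------------------------------------------------------------
def estimate_g_matrices(
    m: pd.DataFrame | np.ndarray,
    species_labels: Sequence[str],
    eigenvalue_floor: float = 1e-10,
    condition: bool = True,
) -> GMatrixPair:
    """G_A (within-species mean-square matrix) and G_S ((MS_B - G_A)/n0).

    n0 is the effective accessions-per-species coefficient of the unbalanced
    two-group design, (N - sum n_i^2 / N) / (s - 1).
    """
    X = np.asarray(m, dtype=float)
    trait_names = (
        list(m.columns) if isinstance(m, pd.DataFrame) else [f"t{i}" for i in range(X.shape[1])]
    )
    sp = np.asarray(species_labels)
    labels = sorted(set(sp.tolist()))
    if len(labels) != 2:
        raise EstimationError("G-matrix estimation requires exactly two species")
    n_total, p_dim = X.shape
    counts = np.array([(sp == lab).sum() for lab in labels], dtype=float)
    if (counts < 2).any():
        raise EstimationError("need >= 2 accessions per species")
    df_a = int(n_total - 2)
    if df_a < p_dim:
        raise EstimationError(
            f"rank error: {p_dim} traits need > {p_dim + 2} accessions, have {n_total}"
        )

    grand = X.mean(axis=0)
    within = np.zeros((p_dim, p_dim))
    between = np.zeros((p_dim, p_dim))
    for lab, n_i in zip(labels, counts):
        sub = X[sp == lab]
        mu = sub.mean(axis=0)
        dev = sub - mu
        within += dev.T @ dev
        dmu = mu - grand
        between += n_i * np.outer(dmu, dmu)
    df_b = 1
    g_a = within / df_a
    ms_b = between / df_b
    n0 = (n_total - float(np.sum(counts**2)) / n_total) / (len(labels) - 1)
    g_s = (ms_b - g_a) / n0
    if condition:
        g_a = condition_matrix(g_a, eigenvalue_floor)
        g_s = condition_matrix(g_s, eigenvalue_floor)
    return GMatrixPair(
        g_a=g_a, g_s=g_s, df_a=df_a, df_b=df_b, n0=n0, trait_names=trait_names
    )


def condition_matrix(M: np.ndarray, floor: Optional[float] = None) -> np.ndarray:
    """Symmetrise, round to 12 decimals, and lift null/negative eigenvalues.

    Rounding guards against loss of symmetry through loss of significance;
    eigenvalues below ``floor`` (default 1e-10 x largest) are raised to the
    floor so the output is positive definite. Idempotent.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("condition_matrix requires a square matrix")
    M = np.round(0.5 * (M + M.T), 12)
    w, v = np.linalg.eigh(M)
    lam_max = float(np.max(np.abs(w))) if w.size else 0.0
    if floor is None:
        floor = 1e-10 * (lam_max if lam_max > 0 else 1.0)
    w = np.maximum(w, floor)
    out = (v * w) @ v.T
    return 0.5 * (out + out.T)


# ----------------------------------------------------------------------
# proportionality coefficient
# ----------------------------------------------------------------------
def estimate_rho(pair: GMatrixPair, rel_tol: float = 1e-8) -> float:
    """ML estimate of rho: the species-level SSCP B = df_b * MS_B is modelled
    as Wishart(df_b, G_A (1 + n0 rho)); the Wishart log-density is profiled
    over rho by bracketed one-dimensional search.

    For exactly proportional pairs (G_S = c G_A) the maximiser is c; for a
    single trait it reduces to the scalar ratio g_s / g_a.
    """
    g_a = np.asarray(pair.g_a, dtype=float)
    p_dim = g_a.shape[0]
    w = np.linalg.eigvalsh(0.5 * (g_a + g_a.T))
    if w.min() <= 0:
        raise EstimationError(
            "G_A is not positive definite; run condition_matrix first"
        )
    B = pair.df_b * pair.ms_b
    t = float(np.trace(np.linalg.solve(g_a, B)))
    if t <= 0:
        return 0.0
    n0, df_b = pair.n0, pair.df_b

    def nll(rho: float) -> float:
        c = 1.0 + n0 * rho
        if c <= 0:
            return np.inf
        return 0.5 * (df_b * p_dim * np.log(c) + t / c)

    # the profile is unimodal in c = 1 + n0 rho; bracket around the
    # stationary point and polish by Brent search
    c_star = t / (df_b * p_dim)
    rho_guess = max((c_star - 1.0) / n0, 0.0)
    upper = max(10.0 * (rho_guess + 1.0), 100.0)
    res = optimize.minimize_scalar(
        nll, bounds=(0.0, upper), method="bounded",
        options={"xatol": rel_tol * max(rho_guess, 1.0)},
    )
    return float(res.x)


def rho_bootstrap_ci(
    p: PhenotypeTable | pd.DataFrame,
    traits: Optional[Sequence[str]] = None,
    n_boot: int = 1000,
    seed: int = 0,
    species: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    eigenvalue_floor: float = 1e-10,
) -> tuple[float, float]:
    """Percentile CI of rho from resampling accessions within each species.

    Accepts either a PhenotypeTable plus trait list, or a prebuilt
    accession x trait matrix with its species labels. Rank-deficient
    resamples (conditioning cannot rescue them) are redrawn with a logged
    count; persistent degeneracy aborts.
    """
    if isinstance(p, PhenotypeTable):
        X, species = accession_trait_matrix(p, traits or MULTIVARIATE_TRAITS)
    else:
        X = p
        if species is None:
            raise ValueError("species labels required with a prebuilt matrix")
    rhos = _rho_bootstrap_distribution(
        np.asarray(X, float), np.asarray(species), n_boot, seed, eigenvalue_floor
    )
    lo, hi = np.percentile(rhos, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _rho_bootstrap_distribution(
    X: np.ndarray,
    sp: np.ndarray,
    n_boot: int,
    seed: int,
    eigenvalue_floor: float = 1e-10,
) -> np.ndarray:
    labels = sorted(set(sp.tolist()))
    idx_by_sp = [np.flatnonzero(sp == lab) for lab in labels]
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    n_redraws = 0
    for i in range(n_boot):
        for _attempt in range(50):
            rows = np.concatenate(
                [rng.choice(idx, size=idx.size, replace=True) for idx in idx_by_sp]
            )
            try:
                pair = estimate_g_matrices(
                    X[rows],
                    sp[rows],
                    eigenvalue_floor=eigenvalue_floor,
                )
                out[i] = estimate_rho(pair)
                break
            except (EstimationError, np.linalg.LinAlgError):
                n_redraws += 1
        else:
            raise EstimationError(
                "persistent degeneracy in accession resamples (>50 redraws)"
            )
    if n_redraws:
        logger.info("redrew %d degenerate accession resamples", n_redraws)
    if n_redraws > n_boot / 2:
        raise EstimationError("more than half of resamples were degenerate")
    return out


# ----------------------------------------------------------------------
# neutral expectation and the full test
# ----------------------------------------------------------------------
_MATING_MULTIPLIER = {"selfing": 1.0, "outcrossing": 2.0}


def expected_rho(
    fst: FstEstimate | float,
    mating: str = "selfing",
    ci: Optional[tuple[float, float]] = None,
) -> tuple[float, tuple[float, float]]:
    """Neutral proportionality rho_Exp = m Fst (1 - Fst), m = 1 for a selfer
    and 2 for an outcrosser; the CI endpoints are mapped through the same
    function (taking care of the maximum at Fst = 0.5)."""
    if mating not in _MATING_MULTIPLIER:
        raise ValueError(f"unknown mating system {mating!r}")
    m = _MATING_MULTIPLIER[mating]

    def f(x: float) -> float:
        return m * x * (1.0 - x)

    if isinstance(fst, FstEstimate):
        value = fst.value
        lo_in, hi_in = fst.ci_low, fst.ci_high
    else:
        value = float(fst)
        lo_in, hi_in = (ci if ci is not None else (np.nan, np.nan))
    point = f(value)
    if np.isnan(lo_in) or np.isnan(hi_in):
        return point, (np.nan, np.nan)
    ends = [f(lo_in), f(hi_in)]
    hi_out = max(ends)
    if lo_in < 0.5 < hi_in:  # the map peaks inside the interval
        hi_out = f(0.5)
    return point, (min(ends), hi_out)


def multivariate_test(
    p: PhenotypeTable,
    g: GenotypeMatrix,
    traits: Optional[Sequence[str]] = None,
    cfg: Optional[AnalysisConfig] = None,
    transforms: Optional[Mapping[str, Callable]] = None,
) -> ProportionalityResult:
    """Full proportionality test: rho_Obs with accession-bootstrap CI versus
    rho_Exp = m Fst (1 - Fst) with its locus-bootstrap CI; verdict is
    'nonneutral' iff the two open intervals are disjoint."""
    cfg = cfg or AnalysisConfig()
    traits = list(traits or MULTIVARIATE_TRAITS)
    X, species = accession_trait_matrix(p, traits, transforms)
    pair = estimate_g_matrices(
        X, species, eigenvalue_floor=cfg.eigenvalue_floor
    )
    rho_obs = estimate_rho(pair)
    obs_ci = rho_bootstrap_ci(
        X,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        species=species,
        eigenvalue_floor=cfg.eigenvalue_floor,
    )
    g_asc = ascertain_snps(g, cfg.ascertainment)
    fst = fst_bootstrap_ci(
        g_asc,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        ascertainment=cfg.ascertainment,
    )
    rho_exp, exp_ci = expected_rho(fst, cfg.mating_system)
    verdict = ProportionalityResult.decide(obs_ci, exp_ci)
    return ProportionalityResult(
        rho_obs=rho_obs,
        rho_ci=obs_ci,
        rho_exp=rho_exp,
        rho_exp_ci=exp_ci,
        mating_system=cfg.mating_system,
        verdict=verdict,
        trait_names=list(traits),
    )
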