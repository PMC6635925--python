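"""Phenotype derivation, nested-ANOVA divergence testing and Qst*.

Derivation formulas convert raw greenhouse measurements into trait values:
microcapillary nectar height to volume, refractometer Brix (w/w) readings to
mg/ml sugar via a sucrose calibration quadratic, a dilution correction for
low-volume nectar reads, and pollen counts per aliquot to pollen per ovule.

The divergence screen is a three-level nested ANOVA
(species / site-in-species / accession-in-site / residual) fitted by the
method of moments on mean squares; the species effect is tested against the
site-in-species stratum, and Benjamini-Hochberg FDR is applied across the
trait family.

Qst* uses a two-level decomposition (species / accession-in-species /
replicate), deliberately ignoring sites: with highly inbred accessions the
between-accession component estimates total genetic variance V_G >= V_A, so

    Qst* = sigma2_BetwSp / (sigma2_BetwSp + 2 * sigma2_BetwAcc)

is an underestimate of true Qst, making the Qst-Fst comparison conservative.
Unbalanced designs use the standard weighted (Sokal-Rohlf) coefficients
relating expected mean squares to variance components.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    DivergenceResult,
    EstimationError,
    PhenotypeTable,
    QstEstimate,
    VarianceComponents,
)

logger = logging.getLogger(__name__)

#: traits log-transformed before ANOVA by default (pollen counts are
#: right-skewed; everything else in the study is close enough to normal)
DEFAULT_LOG_TRAITS = frozenset({"pollen_per_ovule"})

INTERNODE_TRAITS = ("internode_1", "internode_2", "internode_3")


# ----------------------------------------------------------------------
# measurement-derivation formulas
# ----------------------------------------------------------------------
def capillary_volume(height_mm: float) -> float:
    """Nectar volume (ul) from the column height in a 32 mm / 2 ul
    microcapillary tube: V = 2 * height / 32."""
    if not 0.0 <= height_mm <= 32.0:
        raise ValueError(f"nectar height {height_mm} mm outside the 0-32 mm tube")
    return 2.0 * height_mm / 32.0


def brix_to_mgml(w_w: float) -> float:
    """Sugar concentration (mg/ml) from a refractometer w/w reading, via the
    sucrose calibration quadratic 0.0524 x^2 + 9.6554 x + 1.3904."""
    if w_w < 0:
        raise ValueError(f"negative refractometer reading {w_w}")
    return 0.0524 * w_w**2 + 9.6554 * w_w + 1.3904


def dilution_correct(mgml_diluted: float, nectar_ul: float) -> float:
    """Undo a 2.5 ul water dilution: multiply the diluted concentration by
    (nectar + 2.5) / nectar."""
    if nectar_ul <= 0:
        raise EstimationError(
            f"dilution correction undefined for nectar volume {nectar_ul} ul"
        )
    return mgml_diluted * (nectar_ul + 2.5) / nectar_ul


def nectar_concentration(
    mgml_undiluted: float, mgml_diluted: float, nectar_ul: float
) -> float:
    """Final sugar concentration: mean of the undiluted estimate and the
    dilution-corrected diluted estimate."""
    return 0.5 * (mgml_undiluted + dilution_correct(mgml_diluted, nectar_ul))


def pollen_per_ovule(count_in_100ul: float) -> float:
    """Pollen per ovule from a 100 ul aliquot count: x5 (500/100 ul),
    /4 ovules per flower."""
    if count_in_100ul < 0:
        raise ValueError("pollen count cannot be negative")
    return count_in_100ul * 5.0 / 4.0


# ----------------------------------------------------------------------
# per-individual averaging
# ----------------------------------------------------------------------
def individual_means(p: PhenotypeTable) -> PhenotypeTable:
    """Average repeated measurements (flowers, leaves) within individuals.

    Returns one row per individual per trait, plus the derived
    ``internode_sum`` (sum of the three internode means) used as the single
    early-growth measure in multivariate work. Individuals lacking a trait
    are simply absent for it.
    """
    df = p.data
    keys = ["individual", "species", "site", "accession", "trait"]
    means = df.groupby(keys, as_index=False, sort=False)["value"].mean()
    present = set(means["trait"])
    if all(t in present for t in INTERNODE_TRAITS):
        sub = means[means["trait"].isin(INTERNODE_TRAITS)]
        counts = sub.groupby("individual")["trait"].nunique()
        complete = counts.index[counts == 3]
        summed = (
            sub[sub["individual"].isin(complete)]
            .groupby(["individual", "species", "site", "accession"], as_index=False)[
                "value"
            ]
            .sum()
        )
        summed["trait"] = "internode_sum"
        means = pd.concat([means, summed[means.columns]], ignore_index=True)
    return PhenotypeTable(means)


# ----------------------------------------------------------------------
# nested ANOVA machinery
# ----------------------------------------------------------------------
def _group_stats(values: np.ndarray, codes: np.ndarray):
    """Per-group n, sum and mean via bincount (codes must be 0..k-1)."""
    n = np.bincount(codes).astype(float)
    s = np.bincount(codes, weights=values)
    return n, s, s / n


def divergence_anova(
    p: PhenotypeTable,
    trait: str,
    log_transform: Optional[bool] = None,
) -> DivergenceResult:
    """Species-divergence test for one trait via three-level nested ANOVA.

    Sums of squares are partitioned over species, sites within species and
    accessions within sites; the species mean square is tested against the
    site-in-species stratum (the accession stratum if the design has no site
    replication). ``p_fdr`` is NaN here; use :func:`divergence_scan` to apply
    the Benjamini-Hochberg correction across a trait family.
    """
    df = p.for_trait(trait)
    if log_transform is None:
        log_transform = trait in DEFAULT_LOG_TRAITS
    y = df["value"].to_numpy(dtype=float)
    if log_transform:
        y = np.log(y)
    if df["species"].nunique() != 2:
        raise EstimationError(f"trait {trait!r} observed in only one species")

    sp_codes, _ = pd.factorize(df["species"], sort=True)
    site_codes, _ = pd.factorize(df["site"], sort=True)
    acc_codes, _ = pd.factorize(df["accession"], sort=True)

    N = len(y)
    grand = y.mean()
    n_sp, _, m_sp = _group_stats(y, sp_codes)
    n_site, _, m_site = _group_stats(y, site_codes)
    n_acc, _, m_acc = _group_stats(y, acc_codes)
    sp_of_site = pd.Series(sp_codes).groupby(site_codes).first().to_numpy()
    site_of_acc = pd.Series(site_codes).groupby(acc_codes).first().to_numpy()

    ss_sp = float(np.sum(n_sp * (m_sp - grand) ** 2))
    ss_site = float(np.sum(n_site * (m_site - m_sp[sp_of_site]) ** 2))
    ss_acc = float(np.sum(n_acc * (m_acc - m_site[site_of_acc]) ** 2))
    ss_within = float(np.sum((y - m_acc[acc_codes]) ** 2))

    n_species, n_sites, n_accs = len(n_sp), len(n_site), len(n_acc)
    df_sp = n_species - 1
    df_site = n_sites - n_species
    df_acc = n_accs - n_sites
    df_w = N - n_accs

    ms_sp = ss_sp / df_sp
    if df_site > 0:
        ms_err, df_err = ss_site / df_site, df_site
    elif df_acc > 0:
        ms_err, df_err = ss_acc / df_acc, df_acc
    else:
        raise EstimationError(
            f"no site or accession replication to test species effect for {trait!r}"
        )
    if ms_err == 0:
        f_ratio = np.inf
        p_raw = 0.0
    else:
        f_ratio = ms_sp / ms_err
        p_raw = float(stats.f.sf(f_ratio, df_sp, df_err))

    # descriptive species summaries on the untransformed individual values
    raw = df["value"].to_numpy(dtype=float)
    groups = [raw[sp_codes == k] for k in (0, 1)]
    m1, m2 = float(groups[0].mean()), float(groups[1].mean())
    try:
        reldiv = relative_divergence(m1, m2)
    except EstimationError:
        reldiv = float("nan")  # descriptive only; undefined for <= 0 means
    return DivergenceResult(
        trait=trait,
        mean_1=m1,
        mean_2=m2,
        sd_1=float(groups[0].std(ddof=1)) if len(groups[0]) > 1 else float("nan"),
        sd_2=float(groups[1].std(ddof=1)) if len(groups[1]) > 1 else float("nan"),
        n_1=int(len(groups[0])),
        n_2=int(len(groups[1])),
        f_ratio=float(f_ratio),
        df_num=df_sp,
        df_den=df_err,
        p_raw=p_raw,
        p_fdr=float("nan"),
        relative_divergence=reldiv,
    )


def divergence_scan(
    p: PhenotypeTable,
    traits: Optional[Sequence[str]] = None,
    log_traits: Optional[Iterable[str]] = None,
    fdr_alpha: float = 0.05,
) -> list[DivergenceResult]:
    """Run the divergence ANOVA for every trait and apply Benjamini-Hochberg
    FDR across the family in one step."""
    if traits is None:
        traits = p.traits
    log_set = DEFAULT_LOG_TRAITS if log_traits is None else set(log_traits)
    results = [divergence_anova(p, t, log_transform=t in log_set) for t in traits]
    if not results:
        return []
    pvals = np.array([r.p_raw for r in results])
    _, p_adj, _, _ = multipletests(pvals, alpha=fdr_alpha, method="fdr_bh")
    return [
        DivergenceResult(**{**r.__dict__, "p_fdr": float(q)})
        for r, q in zip(results, p_adj)
    ]


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted p-values (thin wrapper, kept for the CLI/report)."""
    _, p_adj, _, _ = multipletests(np.asarray(pvals, float), method="fdr_bh")
    return p_adj


def relative_divergence(m1: float, m2: float) -> float:
    """|m1 - m2| / max(m1, m2): scale-free divergence of two species means."""
    bigger = max(m1, m2)
    if bigger <= 0:
        raise EstimationError("relative divergence undefined when both means <= 0")
    return abs(m1 - m2) / bigger


# ----------------------------------------------------------------------
# Qst* (two-level nested ANOVA, sites ignored)
# ----------------------------------------------------------------------
def variance_components_from_arrays(
    y: np.ndarray,
    acc_codes: np.ndarray,
    sp_of_acc: np.ndarray,
) -> VarianceComponents:
    """Moment variance components of the species/accession/replicate design.

    ``acc_codes`` assigns each observation to an accession (0..A-1);
    ``sp_of_acc`` assigns each accession to a species (0/1). Expected mean
    squares for the unbalanced design:

        E[MS_W] = s2_err
        E[MS_A] = s2_err + k_rep  * s2_acc
        E[MS_B] = s2_err + k_betw * s2_acc + k_acc * s2_sp

    with the weighted coefficients
        k_rep  = (N - sum_ij n_ij^2 / n_i.) / (A - s)
        k_betw = (sum_ij n_ij^2 / n_i. - sum_ij n_ij^2 / N) / (s - 1)
        k_acc  = (N - sum_i n_i.^2 / N) / (s - 1)
    which all reduce to the replicate count / accessions-per-species in the
    balanced case.
    """
    y = np.asarray(y, dtype=float)
    acc_codes = np.asarray(acc_codes)
    sp_of_acc = np.asarray(sp_of_acc)
    A = len(sp_of_acc)
    s = int(sp_of_acc.max()) + 1
    if s != 2:
        raise EstimationError("Qst components require exactly two species")
    for k in range(2):
        if (sp_of_acc == k).sum() < 2:
            raise EstimationError("need >= 2 accessions in each species")

    n_acc, _, m_acc = _group_stats(y, acc_codes)
    sp_codes = sp_of_acc[acc_codes]
    n_sp, _, m_sp = _group_stats(y, sp_codes)
    N = float(len(y))
    grand = y.mean()

    ss_b = float(np.sum(n_sp * (m_sp - grand) ** 2))
    ss_a = float(np.sum(n_acc * (m_acc - m_sp[sp_of_acc]) ** 2))
    ss_w = float(np.sum((y - m_acc[acc_codes]) ** 2))
    df_b, df_a, df_w = s - 1, A - s, int(N) - A

    if df_a <= 0:
        raise EstimationError("no accession replication within species")
    ms_b = ss_b / df_b
    ms_a = ss_a / df_a
    ms_w = ss_w / df_w if df_w > 0 else 0.0

    nij2_over_ni = float(np.sum(np.bincount(sp_of_acc, weights=n_acc**2) / n_sp))
    k_rep = (N - nij2_over_ni) / df_a
    k_betw = (nij2_over_ni - float(np.sum(n_acc**2)) / N) / df_b
    k_acc = (N - float(np.sum(n_sp**2)) / N) / df_b

    s2_err = ms_w
    raw_acc = (ms_a - ms_w) / k_rep
    raw_sp = (ms_b - s2_err - k_betw * raw_acc) / k_acc
    return VarianceComponents(
        ms_between_species=ms_b,
        ms_between_accessions=ms_a,
        ms_within=ms_w,
        df_b=df_b,
        df_a=df_a,
        df_w=df_w,
        sigma2_betw_sp=max(raw_sp, 0.0),
        sigma2_betw_acc=max(raw_acc, 0.0),
        sigma2_err=s2_err,
        raw_sigma2_betw_sp=raw_sp,
        raw_sigma2_betw_acc=raw_acc,
        k_rep=k_rep,
        k_between=k_betw,
        k_acc=k_acc,
    )


def qst_components(
    p: PhenotypeTable,
    trait: str,
    log_transform: Optional[bool] = None,
) -> VarianceComponents:
    """Two-level nested ANOVA (species / accession / replicate) for one trait.

    Sites are ignored, matching the finding of negligible within-species
    population structure in this design.
    """
    df = p.for_trait(trait)
    if log_transform is None:
        log_transform = trait in DEFAULT_LOG_TRAITS
    y = df["value"].to_numpy(dtype=float)
    if log_transform:
        y = np.log(y)
    acc_codes, acc_index = pd.factorize(df["accession"], sort=True)
    sp_of_acc_series = df.groupby("accession")["species"].first().loc[acc_index]
    sp_of_acc, _ = pd.factorize(sp_of_acc_series, sort=True)
    return variance_components_from_arrays(y, acc_codes, sp_of_acc)


def qst_star(vc: VarianceComponents, trait: str = "") -> QstEstimate:
    """Qst* = s2_BetwSp / (s2_BetwSp + 2 s2_BetwAcc) on clamped components."""
    num = vc.sigma2_betw_sp
    den = vc.sigma2_betw_sp + 2.0 * vc.sigma2_betw_acc
    if den == 0.0:
        raise EstimationError(
            "Qst* undefined: both variance components are zero"
        )
    return QstEstimate(trait=trait, qst_star=num / den, components=vc)


def qst_for_trait(
    p: PhenotypeTable, trait: str, log_transform: Optional[bool] = None
) -> QstEstimate:
    """Convenience: components + Qst* in one call."""
    return qst_star(qst_components(p, trait, log_transform), trait=trait)
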