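"""SNP ascertainment and multi-locus Fst estimation between two species.

Two moment estimators are provided, both in ratio-of-averages form (per-locus
components summed across loci before dividing, which is the standard way to
stabilise multi-locus Fst):

* Weir & Cockerham's theta, built from the per-locus variance components
  a (among species), b (among individuals within species) and c (within
  individuals), using observed per-species sample sizes and heterozygote
  counts at each locus;
* Hudson's estimator, built from allele-frequency differences corrected for
  within-species sampling.

Confidence intervals come from a percentile bootstrap over loci. Because the
two study species are highly inbred, per-locus heterozygosity is low and the
c component is nearly zero; the estimators handle that regime without special
casing.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .datatypes import MISSING, EstimationError, FstEstimate, GenotypeMatrix

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# ascertainment
# ----------------------------------------------------------------------
def ascertain_snps(g: GenotypeMatrix, mode: str = "all") -> GenotypeMatrix:
    """Filter loci by polymorphism: ``all`` keeps loci polymorphic in at
    least one species, ``shared`` only loci polymorphic in both.

    The shared set is a subset of the all set on every input, so estimates
    from the two modes bracket the ascertainment bias in opposite directions.
    """
    if mode not in ("all", "shared"):
        raise ValueError(f"unknown ascertainment mode {mode!r}")
    poly = _polymorphic_by_species(g)
    keep = poly.all(axis=0) if mode == "shared" else poly.any(axis=0)
    if not keep.any():
        logger.warning("ascertainment %r left zero loci", mode)
    return g.take_loci(np.flatnonzero(keep))


def _polymorphic_by_species(g: GenotypeMatrix) -> np.ndarray:
    """(2, n_loci) boolean: locus polymorphic within each species."""
    rows = []
    for label in g.species_labels:
        sub = g.geno[g.species_mask(label)]
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=0)
        n = called.sum(axis=0)
        rows.append((alt > 0) & (alt < 2 * n) & (n > 0))
    return np.vstack(rows)


def filter_call_rate(g: GenotypeMatrix, max_missing: int = 1) -> GenotypeMatrix:
    """Drop loci with more than ``max_missing`` uncalled individuals,
    mirroring a near-complete-call hard filter."""
    n_miss = (g.geno == MISSING).sum(axis=0)
    keep = np.flatnonzero(n_miss <= max_missing)
    n_dropped = g.n_loci - keep.size
    if n_dropped:
        logger.info("call-rate filter dropped %d loci", n_dropped)
    return g.take_loci(keep)


# ----------------------------------------------------------------------
# per-locus summaries
# ----------------------------------------------------------------------
def _per_species_counts(g: GenotypeMatrix):
    """Per-locus called sample size, alt-allele frequency and observed
    heterozygote frequency for each of the two species."""
    ns, ps, hs = [], [], []
    for label in g.species_labels:
        sub = g.geno[g.species_mask(label)]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        alt = np.where(called, sub, 0).sum(axis=0).astype(float)
        het = ((sub == 1) & called).sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, alt / (2.0 * n), np.nan)
            h = np.where(n > 0, het / n, np.nan)
        ns.append(n)
        ps.append(p)
        hs.append(h)
    return ns, ps, hs


def weir_cockerham_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
):
    """Vectorised per-locus (a, b, c) variance components for two populations.

    a: among populations; b: among individuals within populations; c: within
    individuals. Sample sizes are the observed per-locus counts of called
    individuals, so missing genotypes simply shrink n at that locus.
    """
    r = 2.0
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    nbar = (n1 + n2) / r
    # n_c: variance-of-sample-size correction
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    return a, b, c


def _wc_per_locus(g: GenotypeMatrix):
    (n1, n2), (p1, p2), (h1, h2) = _per_species_counts(g)
    usable = (n1 >= 1) & (n2 >= 1)
    if not usable.all():
        logger.info("%d loci uncallable in one species ignored", int((~usable).sum()))
    a, b, c = weir_cockerham_components(
        n1[usable], p1[usable], h1[usable],
        n2[usable], p2[usable], h2[usable],
    )
    return a, b, c


def _hudson_per_locus(g: GenotypeMatrix):
    """Per-locus Hudson numerator and denominator (allele counts as sample
    sizes, i.e. 2x called diploid individuals)."""
    (n1, n2), (p1, p2), _ = _per_species_counts(g)
    m1 = 2.0 * n1
    m2 = 2.0 * n2
    usable = (m1 >= 2) & (m2 >= 2)
    if not usable.any():
        raise EstimationError("Hudson Fst undefined: <2 allele copies per species")
    m1, m2, p1, p2 = m1[usable], m2[usable], p1[usable], p2[usable]
    num = (
        (p1 - p2) ** 2
        - p1 * (1.0 - p1) / (m1 - 1.0)
        - p2 * (1.0 - p2) / (m2 - 1.0)
    )
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return num, den


# ----------------------------------------------------------------------
# multi-locus estimators
# ----------------------------------------------------------------------
def _ratio_of_sums(num: np.ndarray, den: np.ndarray) -> float:
    total = float(np.nansum(den))
    if total == 0.0:
        raise EstimationError(
            "Fst undefined: no variation at any locus (all loci monomorphic)"
        )
    return float(np.nansum(num)) / total


def weir_cockerham_fst(
    g: GenotypeMatrix,
    ascertainment: str = "all",
    max_missing: Optional[int] = 1,
) -> FstEstimate:
    """Multi-locus Weir-Cockerham theta between the two species.

    theta = sum_l a_l / sum_l (a_l + b_l + c_l). Loci with zero total
    variance contribute nothing to either sum; negative multi-locus values
    (a small-sample artifact near zero differentiation) are reported as
    computed, never clamped.
    """
    if max_missing is not None:
        g = filter_call_rate(g, max_missing)
    a, b, c = _wc_per_locus(g)
    value = _ratio_of_sums(a, a + b + c)
    return FstEstimate(
        estimator="weir_cockerham",
        value=value,
        ci_low=float("nan"),
        ci_high=float("nan"),
        n_loci=g.n_loci,
        ascertainment=ascertainment,
    )


def hudson_fst(
    g: GenotypeMatrix,
    ascertainment: str = "all",
    max_missing: Optional[int] = 1,
) -> FstEstimate:
    """Multi-locus Hudson Fst between the two species (ratio of averages)."""
    if max_missing is not None:
        g = filter_call_rate(g, max_missing)
    num, den = _hudson_per_locus(g)
    value = _ratio_of_sums(num, den)
    return FstEstimate(
        estimator="hudson",
        value=value,
        ci_low=float("nan"),
        ci_high=float("nan"),
        n_loci=g.n_loci,
        ascertainment=ascertainment,
    )


_ESTIMATOR_FUNCS = {"weir_cockerham": weir_cockerham_fst, "hudson": hudson_fst}
_ESTIMATOR_ALIASES = {"wc": "weir_cockerham", "weir_cockerham": "weir_cockerham",
                      "hudson": "hudson"}


def fst_bootstrap_ci(
    g: GenotypeMatrix,
    estimator: str = "weir_cockerham",
    n_boot: int = 1000,
    seed: int = 0,
    ascertainment: str = "all",
    max_missing: Optional[int] = 1,
    alpha: float = 0.05,
) -> FstEstimate:
    """Point estimate plus percentile CI from resampling loci with replacement.

    Deterministic given ``seed``. A single-locus input yields a degenerate
    (zero-width) interval, with a warning.
    """
    estimator = _ESTIMATOR_ALIASES.get(estimator, estimator)
    if estimator not in _ESTIMATOR_FUNCS:
        raise ValueError(f"unknown Fst estimator {estimator!r}")
    if max_missing is not None:
        g = filter_call_rate(g, max_missing)
    if estimator == "weir_cockerham":
        a, b, c = _wc_per_locus(g)
        num, den = a, a + b + c
    else:
        num, den = _hudson_per_locus(g)
    value = _ratio_of_sums(num, den)
    if len(num) == 1:
        logger.warning("single locus: bootstrap CI is degenerate")
    rng = np.random.default_rng(seed)
    boots = bootstrap_ratio_of_sums(num, den, n_boot, rng)
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return FstEstimate(
        estimator=estimator,
        value=value,
        ci_low=float(lo),
        ci_high=float(hi),
        n_loci=g.n_loci,
        ascertainment=ascertainment,
    )


def bootstrap_ratio_of_sums(
    num: np.ndarray, den: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap replicates of sum(num)/sum(den) resampling loci jointly."""
    n = len(num)
    num = np.nan_to_num(np.asarray(num, dtype=float))
    den = np.nan_to_num(np.asarray(den, dtype=float))
    idx = rng.integers(0, n, size=(n_boot, n))
    num_s = num[idx].sum(axis=1)
    den_s = den[idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num_s / den_s
    return out
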