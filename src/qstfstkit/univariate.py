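"""Univariate Qst-Fst comparisons: standard and parametric bootstrap.

Both tests ask whether a trait's differentiation Qst* exceeds the neutral
marker differentiation Fst, i.e. whether D = Qst* - Fst is too large for
drift alone.

Standard bootstrap: accessions (maternal families) are resampled with
replacement within each species; every resample determines BOTH the
phenotype rows (all replicates of the chosen accessions, repeats kept as
distinct pseudo-accessions) and the genotype columns (the chosen accessions'
genotyped offspring), so Qst and Fst co-vary across iterations exactly as
the sampling design dictates. p = proportion of resampled D <= 0.

Parametric bootstrap: the neutral distribution of D is simulated from the
data's own variance scaffolding. Per iteration Fst is re-estimated from a
bootstrap over loci; the neutral between-species variance is set by the
drift expectation

    sigma2_BetwSp ~= 2 Fst V_A / (1 - Fst)

(with V_A taken from the between-accession component divided by the
sib-relatedness coefficient -- 1 for selfed offspring, keeping the test
conservative since that component estimates V_G >= V_A); species- and
accession-level mean squares are then drawn from chi-square distributions
scaled by their expectations (df 1 and A - 2), re-solved for the components,
and recombined into a simulated neutral D. p = proportion of neutral
D >= observed D. With only two "populations" the df-1 chi-square makes this
test deliberately wide, hence low-powered but safe.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    AnalysisConfig,
    EstimationError,
    GenotypeMatrix,
    PhenotypeTable,
    TestResult,
)
from .fst import (
    ascertain_snps,
    bootstrap_ratio_of_sums,
    filter_call_rate,
    hudson_fst,
    weir_cockerham_components,
    weir_cockerham_fst,
    _hudson_per_locus,
    _wc_per_locus,
)
from .qst import DEFAULT_LOG_TRAITS, qst_for_trait, variance_components_from_arrays

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# fast per-resample Fst machinery
# ----------------------------------------------------------------------
class _SpeciesGenoCache:
    """Per-species 0/1 summaries enabling Fst from a multiplicity vector."""

    def __init__(self, g: GenotypeMatrix, label: str):
        idx = np.flatnonzero(g.species_mask(label))
        sub = g.geno[idx]
        self.individual_idx = idx
        self.accessions = [g.accessions[int(i)] for i in idx]
        self.called = (sub != MISSING).astype(np.float64)
        self.alt = np.where(sub != MISSING, sub, 0).astype(np.float64)
        self.het = (sub == 1).astype(np.float64)
        self.n_ind = len(idx)
        # accession -> row positions of its genotyped offspring
        self.by_accession: dict[str, list[int]] = {}
        for pos, acc in enumerate(self.accessions):
            self.by_accession.setdefault(acc, []).append(pos)

    def counts(self, mult: np.ndarray):
        n = mult @ self.called
        alt = mult @ self.alt
        het = mult @ self.het
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, alt / (2.0 * n), np.nan)
            h = np.where(n > 0, het / n, np.nan)
        return n, p, h


def _theta_from_counts(n1, p1, h1, n2, p2, h2) -> float:
    ok = (n1 >= 1) & (n2 >= 1)
    a, b, c = weir_cockerham_components(
        n1[ok], p1[ok], h1[ok], n2[ok], p2[ok], h2[ok]
    )
    den = float(np.nansum(a + b + c))
    if den == 0.0:
        return float("nan")
    return float(np.nansum(a)) / den


# ----------------------------------------------------------------------
# standard (nonparametric) bootstrap
# ----------------------------------------------------------------------
def standard_bootstrap_test(
    p: PhenotypeTable,
    g: GenotypeMatrix,
    trait: str,
    n_boot: int = 1000,
    seed: int = 0,
    ascertainment: str = "all",
    log_transform: Optional[bool] = None,
    joint: bool = True,
    max_missing: Optional[int] = 1,
) -> TestResult:
    """Accession bootstrap of D = Qst* - Fst; p = proportion of D <= 0."""
    if log_transform is None:
        log_transform = trait in DEFAULT_LOG_TRAITS
    if max_missing is not None:
        g = filter_call_rate(g, max_missing)
    g = ascertain_snps(g, ascertainment)

    obs_qst = qst_for_trait(p, trait, log_transform).qst_star
    obs_fst = weir_cockerham_fst(g, ascertainment, max_missing=None).value
    d_obs = obs_qst - obs_fst

    df = p.for_trait(trait).reset_index(drop=True)
    y_all = df["value"].to_numpy(dtype=float)
    if log_transform:
        y_all = np.log(y_all)
    labels = sorted(df["species"].unique())
    caches = {lab: _SpeciesGenoCache(g, lab) for lab in g.species_labels}

    # per-species accession -> replicate values
    pheno_acc: dict[str, list[tuple[str, np.ndarray]]] = {}
    for lab in labels:
        sub = df[df["species"] == lab]
        groups = [
            (acc, y_all[sub.index[sub["accession"] == acc]])
            for acc in sub["accession"].unique()
        ]
        if len(groups) < 2:
            raise EstimationError(f"species {lab!r} has < 2 accessions for {trait!r}")
        pheno_acc[lab] = groups

    rng = np.random.default_rng(seed)
    dist = np.empty(n_boot)
    n_redrawn = 0
    for it in range(n_boot):
        for _attempt in range(1000):
            ys, codes, sp_of_acc = [], [], []
            mults = []
            next_code = 0
            ok = True
            for k, lab in enumerate(labels):
                groups = pheno_acc[lab]
                draw = rng.integers(0, len(groups), size=len(groups))
                if len(np.unique(draw)) < 2:
                    ok = False  # species collapsed to one distinct accession
                # phenotypes: repeats become distinct pseudo-accessions
                for j in draw:
                    acc, vals = groups[j]
                    ys.append(vals)
                    codes.append(np.full(vals.size, next_code))
                    sp_of_acc.append(k)
                    next_code += 1
                # genotypes follow the same accession draw (joint mode)
                cache = caches[lab]
                mult = np.zeros(cache.n_ind)
                if joint:
                    for j in draw:
                        acc = groups[j][0]
                        for pos in cache.by_accession.get(acc, ()):
                            mult[pos] += 1.0
                else:
                    own = rng.integers(0, cache.n_ind, size=cache.n_ind)
                    np.add.at(mult, own, 1.0)
                if mult.sum() < 1:
                    ok = False
                mults.append(mult)
                if not ok:
                    break
            if ok:
                break
            n_redrawn += 1
        else:
            raise EstimationError("bootstrap redraw limit exceeded")

        vc = variance_components_from_arrays(
            np.concatenate(ys), np.concatenate(codes), np.array(sp_of_acc)
        )
        num = vc.sigma2_betw_sp
        den = num + 2.0 * vc.sigma2_betw_acc
        qst_b = num / den if den > 0 else 0.0
        c1, c2 = caches[labels[0]], caches[labels[1]]
        fst_b = _theta_from_counts(*c1.counts(mults[0]), *c2.counts(mults[1]))
        dist[it] = qst_b - fst_b
    if n_redrawn:
        logger.info("redrew %d degenerate accession resamples", n_redrawn)

    p_value = float(np.mean(dist <= 0.0))
    return TestResult(
        trait=trait,
        observed_qst=obs_qst,
        observed_fst=obs_fst,
        observed_d=d_obs,
        distribution=dist,
        p_value=p_value,
        method="standard_bootstrap",
        n_iter=n_boot,
        seed=seed,
        ascertainment=ascertainment,
    )


# ----------------------------------------------------------------------
# parametric bootstrap
# ----------------------------------------------------------------------
def parametric_bootstrap_test(
    p: PhenotypeTable,
    g: GenotypeMatrix,
    trait: str,
    n_sim: int = 1000,
    seed: int = 0,
    relatedness: float = 1.0,
    ascertainment: str = "all",
    estimator: str = "weir_cockerham",
    log_transform: Optional[bool] = None,
    max_missing: Optional[int] = 1,
) -> TestResult:
    """Simulate the neutral distribution of D from the drift expectation.

    ``relatedness`` is the within-family sib relatedness (1 for selfed
    offspring); the between-accession component divided by it estimates V_A.
    """
    if not 0.0 < relatedness <= 1.0:
        raise ValueError("relatedness must lie in (0, 1]")
    if log_transform is None:
        log_transform = trait in DEFAULT_LOG_TRAITS
    if max_missing is not None:
        g = filter_call_rate(g, max_missing)
    g = ascertain_snps(g, ascertainment)

    est = qst_for_trait(p, trait, log_transform)
    vc = est.components
    v_a = vc.sigma2_betw_acc / relatedness
    if v_a <= 0.0:
        raise EstimationError(
            f"parametric test undefined for {trait!r}: estimated V_A <= 0"
        )

    if estimator == "weir_cockerham":
        a, b, c = _wc_per_locus(g)
        num, den = a, a + b + c
        obs_fst = weir_cockerham_fst(g, ascertainment, max_missing=None).value
    else:
        num, den = _hudson_per_locus(g)
        obs_fst = hudson_fst(g, ascertainment, max_missing=None).value
    d_obs = est.qst_star - obs_fst

    rng = np.random.default_rng(seed)
    fst_sim = bootstrap_ratio_of_sums(num, den, n_sim, rng)
    fst_sim = np.clip(fst_sim, 0.0, 0.999999)

    # neutral drift expectation for the between-species component
    s2_sp_neutral = 2.0 * fst_sim * v_a / (1.0 - fst_sim)
    ems_b = vc.sigma2_err + vc.k_between * vc.sigma2_betw_acc + vc.k_acc * s2_sp_neutral
    ems_a = vc.sigma2_err + vc.k_rep * vc.sigma2_betw_acc
    ms_b_sim = ems_b * rng.chisquare(vc.df_b, size=n_sim) / vc.df_b
    ms_a_sim = ems_a * rng.chisquare(vc.df_a, size=n_sim) / vc.df_a

    s2_acc_sim = np.maximum((ms_a_sim - vc.ms_within) / vc.k_rep, 0.0)
    s2_sp_sim = np.maximum(
        (ms_b_sim - vc.ms_within - vc.k_between * s2_acc_sim) / vc.k_acc, 0.0
    )
    tot = s2_sp_sim + 2.0 * s2_acc_sim
    qst_sim = np.divide(s2_sp_sim, tot, out=np.zeros_like(tot), where=tot > 0)
    dist = qst_sim - fst_sim
    p_value = float(np.mean(dist >= d_obs))
    extras = {
        "s2_sp_neutral": s2_sp_neutral,
        "s2_sp_sim": s2_sp_sim,
        "fst_sim": fst_sim,
        "v_a": v_a,
    }
    return TestResult(
        trait=trait,
        observed_qst=est.qst_star,
        observed_fst=obs_fst,
        observed_d=d_obs,
        distribution=dist,
        p_value=p_value,
        method="parametric_bootstrap",
        n_iter=n_sim,
        seed=seed,
        ascertainment=ascertainment,
        extras=extras,
    )


# ----------------------------------------------------------------------
# orchestration over a trait family
# ----------------------------------------------------------------------
def run_trait_family(
    p: PhenotypeTable,
    g: GenotypeMatrix,
    traits: Sequence[str],
    cfg: Optional[AnalysisConfig] = None,
    ascertainments: Sequence[str] = ("all", "shared"),
    methods: Sequence[str] = ("standard_bootstrap", "parametric_bootstrap"),
) -> list[TestResult]:
    """Both tests per trait under each ascertainment mode, with seeds split
    deterministically from the run seed."""
    cfg = cfg or AnalysisConfig()
    results: list[TestResult] = []
    ss = np.random.SeedSequence(cfg.seed)
    children = iter(ss.generate_state(len(traits) * len(ascertainments) * len(methods)))
    for trait in traits:
        for asc in ascertainments:
            for method in methods:
                child_seed = int(next(children)) % (2**31)
                try:
                    if method == "standard_bootstrap":
                        res = standard_bootstrap_test(
                            p, g, trait, cfg.n_boot, child_seed, asc
                        )
                    else:
                        res = parametric_bootstrap_test(
                            p, g, trait, cfg.n_boot, child_seed, ascertainment=asc
                        )
                except EstimationError as exc:
                    logger.warning("%s on %s (%s): %s", method, trait, asc, exc)
                    continue
                results.append(res)
    return results


def family_report(results: Sequence[TestResult]) -> pd.DataFrame:
    """Tidy per-trait table of p-values, one row per trait, one column per
    (method, ascertainment) pair."""
    if not results:
        return pd.DataFrame(columns=["trait"])
    rows = {}
    for r in results:
        row = rows.setdefault(
            r.trait,
            {"trait": r.trait, "qst": r.observed_qst},
        )
        short = "standard" if r.method == "standard_bootstrap" else "parametric"
        row[f"fst_{r.ascertainment}"] = r.observed_fst
        row[f"p_{short}_{r.ascertainment}"] = r.p_value
    return pd.DataFrame(list(rows.values()))
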