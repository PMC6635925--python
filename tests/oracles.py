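"""Independent brute-force oracles used to cross-check the package.

Everything here is written as plain per-locus / per-observation Python loops
with scalar arithmetic, deliberately sharing no code with the vectorised
implementations under test.
"""

from __future__ import annotations

import numpy as np

MISSING = -1


def brute_force_weir_cockerham(geno: np.ndarray, species: np.ndarray) -> float:
    """Two-population Weir-Cockerham theta, one locus at a time.

    Per-locus variance components (r = 2 populations):
        nbar = mean sample size, nc = size-variance correction,
        pbar = weighted mean frequency, s2 = weighted frequency variance,
        hbar = weighted heterozygote frequency,
        a = nbar/nc [s2 - (pbar(1-pbar) - s2/2 - hbar/4)/(nbar-1)]
        b = nbar/(nbar-1) [pbar(1-pbar) - s2/2 - (2 nbar - 1)/(4 nbar) hbar]
        c = hbar/2
    multi-locus estimate: sum(a) / sum(a + b + c).
    """
    labels = sorted(set(species.tolist()))
    assert len(labels) == 2
    sum_a = 0.0
    sum_abc = 0.0
    for l in range(geno.shape[1]):
        ns, ps, hs = [], [], []
        for lab in labels:
            calls = [
                int(geno[i, l])
                for i in range(geno.shape[0])
                if species[i] == lab and geno[i, l] != MISSING
            ]
            n = len(calls)
            if n == 0:
                break
            ns.append(float(n))
            ps.append(sum(calls) / (2.0 * n))
            hs.append(sum(1 for x in calls if x == 1) / n)
        else:
            n1, n2 = ns
            p1, p2 = ps
            h1, h2 = hs
            r = 2.0
            nbar = (n1 + n2) / r
            if nbar <= 1:
                continue
            nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (
                s2
                - 1.0
                / (nbar - 1.0)
                * (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
            )
            b = (nbar / (nbar - 1.0)) * (
                pbar * (1.0 - pbar)
                - (r - 1.0) / r * s2
                - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
            )
            c = hbar / 2.0
            sum_a += a
            sum_abc += a + b + c
    return sum_a / sum_abc


def brute_force_hudson(geno: np.ndarray, species: np.ndarray) -> float:
    """Hudson Fst, explicit per-locus sums; sample sizes in allele copies."""
    labels = sorted(set(species.tolist()))
    num_sum = 0.0
    den_sum = 0.0
    for l in range(geno.shape[1]):
        stats = []
        for lab in labels:
            calls = [
                int(geno[i, l])
                for i in range(geno.shape[0])
                if species[i] == lab and geno[i, l] != MISSING
            ]
            m = 2 * len(calls)
            if m < 2:
                break
            stats.append((m, sum(calls) / m))
        else:
            (m1, p1), (m2, p2) = stats
            num_sum += (
                (p1 - p2) ** 2
                - p1 * (1 - p1) / (m1 - 1)
                - p2 * (1 - p2) / (m2 - 1)
            )
            den_sum += p1 * (1 - p2) + p2 * (1 - p1)
    return num_sum / den_sum


def balanced_nested_components(values: np.ndarray):
    """Variance components of a balanced species/accession/replicate design.

    ``values`` has shape (2, a, r). Classic balanced EMS solution:
        s2_err = MS_W
        s2_acc = (MS_A - MS_W) / r
        s2_sp  = (MS_B - MS_A) / (a r)
    computed here with explicit loops.
    """
    s, a, r = values.shape
    assert s == 2
    grand = values.mean()
    sp_means = [values[i].mean() for i in range(s)]
    acc_means = [[values[i, j].mean() for j in range(a)] for i in range(s)]

    ss_b = sum(a * r * (sp_means[i] - grand) ** 2 for i in range(s))
    ss_a = sum(
        r * (acc_means[i][j] - sp_means[i]) ** 2 for i in range(s) for j in range(a)
    )
    ss_w = sum(
        (values[i, j, k] - acc_means[i][j]) ** 2
        for i in range(s)
        for j in range(a)
        for k in range(r)
    )
    ms_b = ss_b / (s - 1)
    ms_a = ss_a / (s * (a - 1))
    ms_w = ss_w / (s * a * (r - 1)) if r > 1 else 0.0
    return {
        "ms_b": ms_b,
        "ms_a": ms_a,
        "ms_w": ms_w,
        "s2_err": ms_w,
        "s2_acc": (ms_a - ms_w) / r,
        "s2_sp": (ms_b - ms_a) / (a * r),
    }


def random_genotype_matrix(rng: np.random.Generator, n_per_species=10, n_loci=20):
    """A random two-species genotype matrix with occasional missing calls."""
    geno = rng.integers(0, 3, size=(2 * n_per_species, n_loci)).astype(np.int8)
    miss = rng.random(geno.shape) < 0.03
    geno[miss] = MISSING
    species = np.array(["A"] * n_per_species + ["B"] * n_per_species, dtype=object)
    return geno, species
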