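"""G-matrix estimation, conditioning, the proportionality coefficient and
its neutral expectation."""

import numpy as np
import pandas as pd
import pytest

from qstfstkit import (
    accession_trait_matrix,
    condition_matrix,
    estimate_g_matrices,
    estimate_rho,
    expected_rho,
    multivariate_test,
    rho_bootstrap_ci,
)
from qstfstkit.datatypes import (
    AnalysisConfig,
    EstimationError,
    FstEstimate,
    GMatrixPair,
    ProportionalityResult,
)
from qstfstkit.qst import individual_means, qst_components
from qstfstkit.simulate import (
    DesignSpec,
    SimulationConfig,
    TraitSpec,
    simulate_dataset,
    simulate_multivariate_phenotypes,
    simulate_phenotypes,
)


def random_spd(rng, p, scale=1.0):
    A = rng.standard_normal((p, p + 3))
    return scale * (A @ A.T) / (p + 3)


def proportional_pair(rng, p, c, n0=30.0):
    g_a = condition_matrix(random_spd(rng, p))
    return GMatrixPair(
        g_a=g_a, g_s=c * g_a, df_a=60, df_b=1, n0=n0,
        trait_names=[f"t{i}" for i in range(p)],
    )


class TestConditionMatrix:
    def test_identity_unchanged(self):
        assert np.allclose(condition_matrix(np.eye(3)), np.eye(3))

    def test_null_eigenvalue_lifted_to_floor(self):
        out = condition_matrix(np.diag([1.0, 0.0]), floor=1e-10)
        assert np.allclose(out, np.diag([1.0, 1e-10]))

    def test_tiny_asymmetry_removed(self):
        M = np.array([[1.0, 0.5 + 1e-14], [0.5, 2.0]])
        out = condition_matrix(M)
        assert np.array_equal(out, out.T)

    def test_idempotent_and_floor_monotone(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            M = random_spd(rng, 4)
            M[0, 0] = 0.0  # break positive-definiteness
            once = condition_matrix(M)
            twice = condition_matrix(once)
            assert np.allclose(once, twice, atol=1e-9)
            assert np.linalg.eigvalsh(once).min() >= np.linalg.eigvalsh(
                0.5 * (M + M.T)
            ).min()
            assert np.linalg.eigvalsh(once).min() > 0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            condition_matrix(np.zeros((2, 3)))


class TestAccessionTraitMatrix:
    def test_mean_standardised_columns_average_one(self, paper_like_data):
        _, _, p = paper_like_data
        means = individual_means(p)
        X, sp = accession_trait_matrix(means, ["corolla_width", "nectar_sugar"])
        assert np.allclose(X.mean(axis=0), 1.0)
        assert len(X) == len(sp)

    def test_incomplete_accessions_dropped(self):
        rows = [
            ("i1", "s1", "x", "a1", "t1", 1.0),
            ("i1", "s1", "x", "a1", "t2", 2.0),
            ("i2", "s1", "x", "a2", "t1", 1.5),  # a2 lacks t2
            ("i3", "s2", "y", "a3", "t1", 1.0),
            ("i3", "s2", "y", "a3", "t2", 3.0),
        ]
        from .conftest import make_phenotypes

        X, sp = accession_trait_matrix(make_phenotypes(rows), ["t1", "t2"])
        assert list(X.index) == ["a1", "a3"]


class TestGMatrixEstimation:
    def test_identical_species_clouds_give_null_gs(self):
        rng = np.random.default_rng(1)
        cloud = rng.standard_normal((30, 3)) + 5.0
        X = np.vstack([cloud, cloud])
        sp = np.array(["A"] * 30 + ["B"] * 30)
        pair = estimate_g_matrices(X, sp)
        # after conditioning G_S collapses to the eigenvalue floor
        assert np.abs(pair.g_s).max() < 1e-6

    def test_univariate_case_matches_nested_anova(self):
        # with one trait and one accession mean per accession, G_A equals the
        # accession-level mean square of the species/accession ANOVA
        tr = TraitSpec("t", 1.0, 3.0, 0.5, 0.0)
        design = DesignSpec(sites=(3, 3), accessions=(12, 12),
                            replicates=1, ungenotyped_accessions=0)
        cfg = SimulationConfig(n_loci=10, design=design, traits=(tr,), seed=2)
        p = simulate_phenotypes(cfg)
        df = p.for_trait("t")
        X = df.set_index("accession")[["value"]]
        sp = df.set_index("accession")["species"]
        pair = estimate_g_matrices(X, sp, condition=False)
        vc = qst_components(p, "t")
        assert pair.g_a[0, 0] == pytest.approx(vc.ms_between_accessions)
        # and (MS_B - MS_A)/n0 is the species-level component
        assert pair.g_s[0, 0] == pytest.approx(
            (vc.ms_between_species - vc.ms_between_accessions) / pair.n0
        )

    def test_rank_error_when_traits_exceed_accessions(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((6, 8))
        sp = np.array(["A"] * 3 + ["B"] * 3)
        with pytest.raises(EstimationError, match="rank"):
            estimate_g_matrices(X, sp)


class TestEstimateRho:
    def test_recovers_constant_on_proportional_pairs(self):
        rng = np.random.default_rng(4)
        for c in (0.5, 2.0, 3.0):
            for p_dim in range(2, 7):
                pair = proportional_pair(rng, p_dim, c)
                assert estimate_rho(pair) == pytest.approx(c, abs=1e-6)

    def test_null_gs_gives_near_zero(self):
        rng = np.random.default_rng(5)
        g_a = condition_matrix(random_spd(rng, 3))
        pair = GMatrixPair(
            g_a=g_a, g_s=condition_matrix(np.zeros((3, 3))), df_a=40, df_b=1,
            n0=25.0, trait_names=list("abc"),
        )
        assert estimate_rho(pair) < 1e-6

    def test_scalar_case_is_the_ratio(self):
        pair = GMatrixPair(
            g_a=np.array([[2.0]]), g_s=np.array([[5.0]]), df_a=40, df_b=1,
            n0=30.0, trait_names=["t"],
        )
        assert estimate_rho(pair) == pytest.approx(2.5, abs=1e-7)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        g_a = condition_matrix(random_spd(rng, 4))
        pair = GMatrixPair(g_a=g_a, g_s=1.7 * g_a, df_a=50, df_b=1, n0=20.0,
                           trait_names=list("abcd"))
        scaled = GMatrixPair(g_a=9.0 * g_a, g_s=9.0 * 1.7 * g_a, df_a=50,
                             df_b=1, n0=20.0, trait_names=list("abcd"))
        assert estimate_rho(pair) == pytest.approx(estimate_rho(scaled), abs=1e-6)

    def test_non_pd_input_rejected(self):
        pair = GMatrixPair(
            g_a=np.diag([1.0, 0.0]), g_s=np.eye(2), df_a=10, df_b=1, n0=5.0,
            trait_names=["a", "b"],
        )
        with pytest.raises(EstimationError, match="condition"):
            estimate_rho(pair)

    def test_simulated_proportional_divergence_recovers_rho(self):
        # species effects drawn with covariance 3 G_A: with df_b = 1 each
        # realisation is noisy (rho_hat ~ rho chi2_p / p), so check the mean
        # over seeds. Conditioning on the *estimated* within-species matrix
        # inflates the trace by the inverse-Wishart factor df/(df - p - 1),
        # so the expected mean is 3 * 62/52 ~ 3.58; se ~ 0.27 over 40 seeds.
        rng0 = np.random.default_rng(7)
        p_dim = 9
        g_a = condition_matrix(random_spd(rng0, p_dim, scale=0.01))
        base = np.linspace(5.0, 25.0, p_dim)
        names = [f"m{i}" for i in range(p_dim)]
        rhos = []
        for seed in range(40):
            p = simulate_multivariate_phenotypes(
                DesignSpec(), names, base, g_a, rho_species=3.0, seed=seed
            )
            X, sp = accession_trait_matrix(p, names)
            rhos.append(estimate_rho(estimate_g_matrices(X, sp)))
        df_a = 64 - 2
        adjusted = 3.0 * df_a / (df_a - p_dim - 1)
        assert np.mean(rhos) == pytest.approx(adjusted, abs=0.8)


class TestRhoBootstrap:
    def test_seed_determinism(self, paper_like_data):
        _, _, p = paper_like_data
        means = individual_means(p)
        traits = ["corolla_length", "corolla_width", "nectar_sugar"]
        a = rho_bootstrap_ci(means, traits, n_boot=100, seed=3)
        b = rho_bootstrap_ci(means, traits, n_boot=100, seed=3)
        assert a == b

    def test_null_data_ci_near_zero(self):
        rng0 = np.random.default_rng(8)
        g_a = condition_matrix(random_spd(rng0, 3, scale=0.01))
        names = ["a", "b", "c"]
        p = simulate_multivariate_phenotypes(
            DesignSpec(), names, np.array([10.0, 12.0, 8.0]), g_a,
            rho_species=0.0, seed=9,
        )
        lo, hi = rho_bootstrap_ci(p, names, n_boot=200, seed=10)
        assert hi < 0.5


class TestExpectedRho:
    @pytest.mark.parametrize("fst,expected", [(0.442, 0.2466), (0.390, 0.2379)])
    def test_published_neutral_expectations(self, fst, expected):
        value, _ = expected_rho(fst, "selfing")
        assert round(value, 4) == expected

    def test_outcrossing_multiplier(self):
        value, _ = expected_rho(0.5, "outcrossing")
        assert value == pytest.approx(0.5)

    def test_symmetric_with_maximum_at_half(self):
        v1, _ = expected_rho(0.3, "selfing")
        v2, _ = expected_rho(0.7, "selfing")
        vmax, _ = expected_rho(0.5, "selfing")
        assert v1 == pytest.approx(v2)
        assert vmax >= max(v1, v2)
        assert expected_rho(0.0, "selfing")[0] == 0.0
        assert expected_rho(1.0, "selfing")[0] == 0.0

    def test_ci_mapping_handles_interval_through_half(self):
        est = FstEstimate("weir_cockerham", 0.48, 0.45, 0.55, 100, "all")
        _, (lo, hi) = expected_rho(est, "selfing")
        assert hi == pytest.approx(0.25)  # peak inside the interval
        assert lo == pytest.approx(min(0.45 * 0.55, 0.55 * 0.45))


class TestFullTest:
    def test_verdict_rule_is_open_interval_disjointness(self):
        assert ProportionalityResult.decide((0.5, 1.0), (0.2, 0.3)) == "nonneutral"
        assert ProportionalityResult.decide((0.25, 1.0), (0.2, 0.3)) == "neutral"

    def test_single_selected_trait_agrees_with_univariate_direction(self):
        from qstfstkit.simulate import var_accession_for_qst
        from qstfstkit.univariate import standard_bootstrap_test

        va = var_accession_for_qst(0.9, 10.0, 11.0)
        tr = TraitSpec("sel", 10.0, 11.0, va, va)
        cfg = SimulationConfig(n_loci=600, design=DesignSpec(), traits=(tr,), seed=12)
        g, p = simulate_dataset(cfg)
        uni = standard_bootstrap_test(p, g, "sel", n_boot=100, seed=13)
        mv = multivariate_test(p, g, ["sel"], AnalysisConfig(n_boot=100, seed=13))
        assert uni.observed_d > 0
        assert mv.rho_obs > mv.rho_exp
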