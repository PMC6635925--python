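"""Trait-derivation formulas, nested ANOVA divergence testing and Qst*."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from qstfstkit import (
    brix_to_mgml,
    capillary_volume,
    dilution_correct,
    divergence_anova,
    divergence_scan,
    individual_means,
    nectar_concentration,
    pollen_per_ovule,
    qst_components,
    qst_for_trait,
    qst_star,
    relative_divergence,
)
from qstfstkit.datatypes import EstimationError, VarianceComponents
from qstfstkit.qst import benjamini_hochberg, variance_components_from_arrays
from qstfstkit.simulate import DesignSpec, SimulationConfig, TraitSpec, simulate_phenotypes

from .conftest import make_phenotypes
from .oracles import balanced_nested_components


class TestDerivationFormulas:
    @pytest.mark.parametrize(
        "height,volume", [(32.0, 2.0), (16.0, 1.0), (0.0, 0.0), (8.0, 0.5)]
    )
    def test_capillary_volume(self, height, volume):
        assert capillary_volume(height) == pytest.approx(volume)

    def test_capillary_range_enforced(self):
        with pytest.raises(ValueError):
            capillary_volume(33.0)
        with pytest.raises(ValueError):
            capillary_volume(-1.0)

    @pytest.mark.parametrize(
        "w,mgml", [(0.0, 1.3904), (10.0, 103.1844), (30.0, 338.2124)]
    )
    def test_brix_conversion_evaluates_calibration_quadratic(self, w, mgml):
        assert brix_to_mgml(w) == pytest.approx(mgml, abs=1e-10)

    @pytest.mark.parametrize("diluted,vol,expected", [(100.0, 2.5, 200.0), (100.0, 5.0, 150.0)])
    def test_dilution_correction(self, diluted, vol, expected):
        assert dilution_correct(diluted, vol) == pytest.approx(expected)

    def test_dilution_with_no_nectar_is_undefined(self):
        with pytest.raises(EstimationError):
            dilution_correct(100.0, 0.0)

    def test_final_concentration_averages_both_estimates(self):
        # undiluted 180; diluted 100 at 5 ul corrects to 150 -> mean 165
        assert nectar_concentration(180.0, 100.0, 5.0) == pytest.approx(165.0)

    @pytest.mark.parametrize("count,expected", [(0, 0.0), (100, 125.0), (126, 157.5)])
    def test_pollen_per_ovule(self, count, expected):
        assert pollen_per_ovule(count) == pytest.approx(expected)


class TestIndividualMeans:
    def test_flower_measurements_averaged(self):
        rows = [("i1", "s1", "x", "a1", "corolla_width", v) for v in (14.0, 15.0, 16.0)]
        rows += [("i2", "s2", "y", "a2", "corolla_width", 12.0)]
        means = individual_means(make_phenotypes(rows))
        df = means.data.set_index("individual")
        assert df.loc["i1", "value"] == pytest.approx(15.0)
        assert df.loc["i2", "value"] == pytest.approx(12.0)

    def test_internode_sum_derived(self):
        rows = [
            ("i1", "s1", "x", "a1", "internode_1", 13.37),
            ("i1", "s1", "x", "a1", "internode_2", 13.35),
            ("i1", "s1", "x", "a1", "internode_3", 52.20),
        ]
        means = individual_means(make_phenotypes(rows))
        s = means.data.set_index("trait").loc["internode_sum", "value"]
        assert s == pytest.approx(78.92)


class TestRelativeDivergence:
    @pytest.mark.parametrize(
        "m1,m2,expected",
        [(0.77, 3.33, 0.77), (0.28, 3.35, 0.92), (15.09, 34.44, 0.56), (13.37, 5.67, 0.58)],
    )
    def test_matches_published_trait_table_at_2dp(self, m1, m2, expected):
        assert round(relative_divergence(m1, m2), 2) == expected

    def test_equal_means_give_zero(self):
        assert relative_divergence(4.2, 4.2) == 0.0

    def test_both_zero_undefined(self):
        with pytest.raises(EstimationError):
            relative_divergence(0.0, 0.0)


class TestMultipleTesting:
    def test_bh_step_up_rule_by_hand(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.04, 0.90])
        assert adj == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.90])


class TestDivergenceAnova:
    def _sim(self, mean_b, seed, var_acc=1.0):
        tr = TraitSpec("t", 0.0, mean_b, var_acc, var_acc)
        design = DesignSpec(sites=(6, 6), accessions=(15, 15), ungenotyped_accessions=0)
        cfg = SimulationConfig(n_loci=10, design=design, traits=(tr,), seed=seed)
        return simulate_phenotypes(cfg)

    def test_clear_separation_is_significant(self):
        p = self._sim(mean_b=5.0, seed=0, var_acc=0.05)
        assert divergence_anova(p, "t").p_raw < 0.001

    def test_null_rejection_rate_controlled(self):
        hits = sum(
            divergence_anova(self._sim(0.0, seed), "t").p_raw < 0.1
            for seed in range(20)
        )
        assert hits <= 2

    def test_null_p_values_uniform(self):
        # KS test over 200 null simulations must not reject uniformity
        pvals = [
            divergence_anova(self._sim(0.0, 1000 + s), "t").p_raw
            for s in range(200)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_scan_applies_family_fdr(self):
        tr1 = TraitSpec("diverged", 0.0, 5.0, 0.2, 0.2)
        tr2 = TraitSpec("flat", 1.0, 1.0, 0.2, 0.2)
        cfg = SimulationConfig(n_loci=10, traits=(tr1, tr2), seed=3)
        p = simulate_phenotypes(cfg)
        res = {r.trait: r for r in divergence_scan(p, ["diverged", "flat"])}
        assert res["diverged"].p_fdr <= 0.05 < res["flat"].p_fdr
        for r in res.values():
            assert r.p_fdr >= r.p_raw


class TestQstComponents:
    def test_balanced_design_matches_hand_ems_solution(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(2, 3, 2)) + np.array([0.0, 2.0])[:, None, None]
        oracle = balanced_nested_components(vals)
        y = vals.reshape(-1)
        acc_codes = np.repeat(np.arange(6), 2)
        sp_of_acc = np.array([0, 0, 0, 1, 1, 1])
        vc = variance_components_from_arrays(y, acc_codes, sp_of_acc)
        assert vc.ms_between_species == pytest.approx(oracle["ms_b"])
        assert vc.ms_between_accessions == pytest.approx(oracle["ms_a"])
        assert vc.ms_within == pytest.approx(oracle["ms_w"])
        assert vc.raw_sigma2_betw_acc == pytest.approx(oracle["s2_acc"])
        assert vc.raw_sigma2_betw_sp == pytest.approx(oracle["s2_sp"])
        # balanced coefficients reduce to replicate / accession counts
        assert vc.k_rep == pytest.approx(2.0)
        assert vc.k_between == pytest.approx(2.0)
        assert vc.k_acc == pytest.approx(6.0)

    def test_degenerate_variances(self):
        rows = []
        for sp, site, mean in (("s1", "x", 1.0), ("s2", "y", 3.0)):
            for a in range(2):
                for r in range(2):
                    rows.append((f"{sp}a{a}r{r}", sp, site, f"{sp}a{a}", "t", mean))
        vc = qst_components(make_phenotypes(rows), "t")
        assert vc.sigma2_betw_acc == 0.0
        assert vc.sigma2_err == 0.0
        assert vc.sigma2_betw_sp > 0.0

    def test_pure_noise_recovery(self):
        tr = TraitSpec("t", 0.0, 0.0, 0.0, 1.0)
        design = DesignSpec(sites=(5, 5), accessions=(200, 200), ungenotyped_accessions=0)
        cfg = SimulationConfig(n_loci=10, design=design, traits=(tr,), seed=9)
        vc = qst_components(simulate_phenotypes(cfg), "t")
        assert vc.sigma2_betw_sp == pytest.approx(0.0, abs=0.05)
        assert vc.sigma2_err == pytest.approx(1.0, abs=0.15)

    def test_single_accession_species_rejected(self):
        rows = [
            ("i1", "s1", "x", "a1", "t", 1.0),
            ("i2", "s1", "x", "a1", "t", 2.0),
            ("i3", "s2", "y", "a2", "t", 1.0),
            ("i4", "s2", "y", "a3", "t", 2.0),
        ]
        with pytest.raises(EstimationError):
            qst_components(make_phenotypes(rows), "t")


def _vc(s2_sp, s2_acc, s2_err=1.0):
    return VarianceComponents(
        ms_between_species=0, ms_between_accessions=0, ms_within=s2_err,
        df_b=1, df_a=10, df_w=12,
        sigma2_betw_sp=s2_sp, sigma2_betw_acc=s2_acc, sigma2_err=s2_err,
        raw_sigma2_betw_sp=s2_sp, raw_sigma2_betw_acc=s2_acc,
        k_rep=2.0, k_between=2.0, k_acc=12.0,
    )


class TestQstStar:
    def test_equal_components_give_one_third(self):
        assert qst_star(_vc(1.5, 1.5)).qst_star == pytest.approx(1.0 / 3.0)

    def test_boundary_cases(self):
        assert qst_star(_vc(0.0, 2.0)).qst_star == 0.0
        assert qst_star(_vc(2.0, 0.0)).qst_star == 1.0
        with pytest.raises(EstimationError):
            qst_star(_vc(0.0, 0.0))

    @settings(derandomize=True, max_examples=50)
    @given(
        s_sp=st.floats(0.01, 100.0),
        s_acc=st.floats(0.01, 100.0),
        bump=st.floats(0.01, 10.0),
    )
    def test_monotone_in_both_components(self, s_sp, s_acc, bump):
        base = qst_star(_vc(s_sp, s_acc)).qst_star
        assert 0.0 <= base <= 1.0
        assert qst_star(_vc(s_sp + bump, s_acc)).qst_star > base
        assert qst_star(_vc(s_sp, s_acc + bump)).qst_star < base

    def test_log_transform_flag_respected(self, paper_like_data):
        _, _, p = paper_like_data
        logged = qst_for_trait(p, "pollen_per_ovule")  # log by default
        raw = qst_for_trait(p, "pollen_per_ovule", log_transform=False)
        assert logged.qst_star != pytest.approx(raw.qst_star, abs=1e-12)
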