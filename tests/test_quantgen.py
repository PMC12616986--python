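import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lactsel import founders, quantgen
from lactsel.quantgen import (GenomicAccuracyInputs, bend_correlation_matrix,
                              bulmer_update, estimate_variance_components,
                              genomic_accuracy, load_default_goals,
                              load_default_parameters, me_segments,
                              tmi_trait_correlations)


class TestVarianceComponents:
    def test_h2_recovery_from_half_sib_design(self):
        pop, ped = founders.sample_founders(200, 100, rng_seed=11)
        est = estimate_variance_components(pop.phenotype, ped)
        for t in founders.AA_TRAITS:
            assert est.h2[t] == pytest.approx(0.35, abs=0.08)

    def test_zero_residual_gives_h2_of_one(self):
        # the between-sire variance carries a relative sampling error of
        # about sqrt(2/n_sires), hence the 200-family design and the band
        pop, ped = founders.sample_founders(200, 100, rng_seed=1)
        est = estimate_variance_components(pop.tbv, ped)
        for t in founders.AA_TRAITS:
            assert est.h2[t] == pytest.approx(1.0, abs=0.15)

    def test_shared_tbv_gives_unit_genetic_correlation(self):
        pop, ped = founders.sample_founders(100, 50, rng_seed=2)
        rng = np.random.default_rng(3)
        tbv = pop.tbv["bas_acq"]
        ph = pd.DataFrame({
            "x": tbv + rng.normal(0, 0.5, len(tbv)),
            "y": tbv + rng.normal(0, 0.5, len(tbv)),
        }, index=pop.tbv.index)
        est = estimate_variance_components(ph, ped)
        assert est.genetic_corr.loc["x", "y"] == pytest.approx(1.0, abs=0.05)

    def test_missing_phenotypes_handled_pairwise(self):
        pop, ped = founders.sample_founders(100, 40, rng_seed=4)
        ph = pop.phenotype.copy()
        ph.loc[ph.index[::3], "lact_acq"] = np.nan
        est = estimate_variance_components(ph, ped)
        assert np.isfinite(est.h2["lact_acq"])
        assert est.h2["lact_acq"] == pytest.approx(0.35, abs=0.12)

    def test_requires_multiple_sires(self):
        pop, ped = founders.sample_founders(1, 10, rng_seed=0)
        with pytest.raises(quantgen.ContractViolation):
            estimate_variance_components(pop.phenotype, ped)


class TestBending:
    def test_identity_unchanged(self):
        np.testing.assert_array_equal(bend_correlation_matrix(np.eye(4)),
                                      np.eye(4))

    def test_overcorrelated_pair_is_repaired(self):
        r = np.array([[1.0, 1.02], [1.02, 1.0]])
        out = bend_correlation_matrix(r)
        assert abs(out[0, 1]) <= 1.0
        assert np.linalg.eigvalsh(out).min() > 0

    def test_idempotent_and_leaves_pd_untouched(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 6))
        r = np.corrcoef(a @ a.T + 6 * np.eye(6))
        once = bend_correlation_matrix(r)
        twice = bend_correlation_matrix(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_reference_panel_matrix_is_positive_definite(self, ref_params):
        g = ref_params.genetic_corr
        bent = bend_correlation_matrix(g)
        assert np.linalg.eigvalsh(bent.to_numpy()).min() > 0
        # the reference panel is already PD, so bending must not change it
        np.testing.assert_allclose(bent.to_numpy(), g.to_numpy(), atol=1e-12)

    def test_non_symmetric_rejected(self):
        bad = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(quantgen.ContractViolation):
            bend_correlation_matrix(bad)


class TestIndexMath:
    def test_single_weight_gives_unit_correlation(self, ref_params, goals):
        g5 = ref_params.goal_genetic_corr()
        goal = quantgen.BreedingGoal("only_milk", pd.Series({"Milk": 10.0}))
        cors = tmi_trait_correlations(goal, g5)
        assert cors["Milk"] == pytest.approx(1.0)

    def test_invariant_to_weight_rescaling(self, ref_params, goals):
        g5 = ref_params.goal_genetic_corr()
        a = tmi_trait_correlations(goals["Base"], g5)
        scaled = quantgen.BreedingGoal("scaled", goals["Base"].weights * 7.5)
        b = tmi_trait_correlations(scaled, g5)
        pd.testing.assert_series_equal(a, b)

    def test_output_within_unit_interval(self, ref_params, goals):
        g5 = ref_params.goal_genetic_corr()
        for goal in goals.values():
            cors = tmi_trait_correlations(goal, g5)
            assert cors.abs().max() <= 1.0 + 1e-12

    def test_matches_monte_carlo_oracle(self, ref_params, goals):
        """Formula vs correlation of sampled multivariate-normal TBVs."""
        g5 = ref_params.goal_genetic_corr().to_numpy()
        w = goals["Base"].weights.to_numpy(float)
        rng = np.random.default_rng(12345)
        bvs = rng.standard_normal((1_000_000, 5)) @ np.linalg.cholesky(g5).T
        tmi = bvs @ w
        mc = np.array([np.corrcoef(tmi, bvs[:, i])[0, 1] for i in range(5)])
        formula = tmi_trait_correlations(
            goals["Base"], ref_params.goal_genetic_corr()).to_numpy()
        np.testing.assert_allclose(formula, mc, atol=3e-3)

    def test_zero_weights_rejected(self):
        with pytest.raises(quantgen.ContractViolation):
            quantgen.BreedingGoal("null", pd.Series({"Milk": 0.0}))


class TestGenomicAccuracy:
    def test_independent_segments_closed_form(self):
        assert me_segments(350, 30) == pytest.approx(1972.7, abs=0.1)
        assert round(me_segments(350, 30), -3) == 2000  # "about 2000"
        assert me_segments(1, 1) == pytest.approx(2 / np.log(4), rel=1e-12)

    def test_segments_sublinear_in_ne_and_length(self):
        assert me_segments(700, 60) < 4 * me_segments(350, 30)

    def test_zero_reference_gives_zero(self):
        inp = GenomicAccuracyInputs(n_bulls=0, n_cows=0)
        assert genomic_accuracy(inp) == 0.0

    def test_monotone_in_reference_size_and_bounded(self):
        accs = [genomic_accuracy(GenomicAccuracyInputs(n_bulls=0, n_cows=n))
                for n in (1_000, 10_000, 100_000, 10_000_000)]
        assert all(a < b for a, b in zip(accs, accs[1:]))
        # asymptote set by the marker-captured share of genetic variance
        q = 38_000 / (38_000 + me_segments(350, 30))
        assert accs[-1] <= np.sqrt(q) + 1e-9

    def test_goddard_variant_shrinks_harder(self):
        inp = GenomicAccuracyInputs(n_bulls=0, n_cows=5_000, h2=0.34)
        assert genomic_accuracy(inp, variant="goddard2009") \
            < genomic_accuracy(inp, variant="daetwyler")

    def test_unknown_variant_rejected(self):
        with pytest.raises(quantgen.ContractViolation):
            genomic_accuracy(GenomicAccuracyInputs(), variant="nope")


class TestBulmerUpdate:
    def test_reference_values(self):
        assert bulmer_update(0.35, 1.0) == pytest.approx(0.35, abs=1e-12)
        assert bulmer_update(0.35, 0.93) == pytest.approx(0.3337, abs=5e-5)

    @given(h2=st.floats(0.01, 0.99), alpha=st.floats(0.01, 1.0))
    @settings(derandomize=True, max_examples=200)
    def test_equivalent_to_variance_ratio_and_bounded(self, h2, alpha):
        got = bulmer_update(h2, alpha)
        sg2 = alpha * h2
        se2 = 1.0 - h2
        assert got == pytest.approx(sg2 / (sg2 + se2), rel=1e-12)
        assert got <= h2 + 1e-15

    @given(h2=st.floats(0.02, 0.98), alpha=st.floats(0.02, 0.99))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_both_arguments(self, h2, alpha):
        eps = 0.01
        assert bulmer_update(h2 + eps, alpha) > bulmer_update(h2, alpha)
        assert bulmer_update(h2, alpha + eps) > bulmer_update(h2, alpha)

    def test_out_of_range_rejected(self):
        for h2, alpha in ((0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.5)):
            with pytest.raises(quantgen.ContractViolation):
                bulmer_update(h2, alpha)


class TestParameterIO:
    def test_matrix_csv_round_trip(self, ref_params, tmp_path):
        p = tmp_path / "params.csv"
        ref_params.to_csv(p)
        back = quantgen.GeneticParameters.from_csv(p)
        pd.testing.assert_frame_equal(back.genetic_corr,
                                      ref_params.genetic_corr)
        pd.testing.assert_frame_equal(back.residual_corr,
                                      ref_params.residual_corr)
        pd.testing.assert_series_equal(back.h2, ref_params.h2)

    def test_goal_table_loads_all_goals(self, goals):
        assert set(goals) == {"Base", "LimitBW", "LimitDMI", "LimitBoth",
                              "ReduceBW", "EFF"}
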