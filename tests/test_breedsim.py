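import numpy as np
import pandas as pd
import pytest

from lactsel import breedsim, quantgen
from lactsel.breedsim import (SchemeConfig, SchemeError, a_inverse,
                              blup_evaluate, build_scheme_correlations,
                              inbreeding_coefficients, kinship_matrix,
                              run_scheme, sample_dgv, sample_offspring_tbv)


class TestOffspringSampling:
    def test_identical_parents_zero_variance(self):
        rng = np.random.default_rng(0)
        tbv = np.array([[1.0, -2.0, 0.5]])
        got = sample_offspring_tbv(tbv, tbv, np.zeros((3, 3)), rng)
        np.testing.assert_allclose(got, tbv)

    def test_mendelian_sampling_covariance_is_half_g(self, ref_params):
        g = ref_params.genetic_corr.to_numpy()
        rng = np.random.default_rng(1)
        n = 100_000
        zeros = np.zeros((n, g.shape[0]))
        off = sample_offspring_tbv(zeros, zeros, g, rng)
        emp = np.cov(off.T)
        np.testing.assert_allclose(emp, 0.5 * g, atol=0.02)

    def test_uncorrelated_traits_stay_uncorrelated(self):
        rng = np.random.default_rng(2)
        n = 100_000
        zeros = np.zeros((n, 4))
        off = sample_offspring_tbv(zeros, zeros, np.eye(4), rng)
        corr = np.corrcoef(off.T)
        assert np.abs(corr - np.eye(4)).max() < 0.02


class TestDGV:
    @pytest.mark.parametrize("acc", [0.0, 0.68, 1.0])
    def test_correlation_equals_accuracy(self, acc):
        rng = np.random.default_rng(3)
        tbv = rng.standard_normal(100_000)
        dgv = sample_dgv(tbv, acc, rng)
        got = np.corrcoef(tbv, dgv)[0, 1]
        assert got == pytest.approx(acc, abs=0.01)

    def test_invalid_accuracy_rejected(self):
        with pytest.raises(SchemeError):
            sample_dgv(np.zeros(3), 1.2, np.random.default_rng(0))

    def test_scheme_correlation_matrix_is_positive_definite(self, ref_params):
        names, g, h2 = build_scheme_correlations(ref_params)
        assert len(names) == 10 + len(breedsim.DGV_TRAITS)
        assert np.linalg.eigvalsh(g).min() > 0
        i = names.index("DGV_Milk_HS")
        j = names.index("Milk_HS")
        assert g[i, j] == pytest.approx(0.68)


class TestPedigreeAlgebra:
    def test_a_inverse_inverts_tabular_a(self):
        # founders 0-2; 3 = 0x1, 4 = 0x2, 5 with one unknown parent
        sire = np.array([-1, -1, -1, 0, 0, 3])
        dam = np.array([-1, -1, -1, 1, 2, -1])
        a = kinship_matrix(sire, dam)
        ainv = a_inverse(sire, dam).toarray()
        np.testing.assert_allclose(ainv @ a, np.eye(6), atol=1e-12)

    def test_gene_drop_inbreeding_matches_exact_kinship(self):
        # full sibs mated: offspring F = 0.25; half sibs: F = 0.125
        sire = np.array([-1, -1, 0, 0, 2, 2, -1, 0, 0, 8])
        dam = np.array([-1, -1, 1, 1, 3, 3, -1, 1, 6, 7])
        f_exact = np.array([0.5 * kinship_matrix(sire, dam)[sire[i], dam[i]]
                            if sire[i] >= 0 and dam[i] >= 0 else 0.0
                            for i in range(sire.size)])
        f_mc = inbreeding_coefficients(sire, dam,
                                       np.random.default_rng(0),
                                       n_drops=20_000)
        np.testing.assert_allclose(f_mc, f_exact, atol=0.01)


class TestBLUP:
    def _two_trait_cov(self):
        G = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"],
                         columns=["a", "b"])
        R = pd.DataFrame([[2.0, 0.3], [0.3, 1.5]], index=["a", "b"],
                         columns=["a", "b"])
        return G, R

    def test_single_animal_regression_limit(self):
        ped = pd.DataFrame({"animal_id": [1], "sire_id": [0], "dam_id": [0]})
        h2 = 0.35
        G = pd.DataFrame([[h2]], index=["t"], columns=["t"])
        R = pd.DataFrame([[1 - h2]], index=["t"], columns=["t"])
        y = pd.DataFrame({"t": [1.8]}, index=[1])
        ebv = blup_evaluate(ped, y, G, R,
                            known_means=pd.Series({"t": 0.5}))
        assert ebv.loc[1, "t"] == pytest.approx(h2 * (1.8 - 0.5), rel=1e-8)

    def test_matches_dense_gls_on_five_animal_pedigree(self):
        """Sparse MME solution equals the dense multivariate GLS oracle
        u_hat = Cov(u, y) V^-1 y."""
        from _oracles import dense_gls_check
        dense_gls_check()

    def test_progeny_information_accumulates(self):
        """With constant progeny records, the parent's EBV approaches the
        implied parent value monotonically as progeny are added."""
        G, R = self._two_trait_cov()
        ebvs = []
        for n in (1, 10, 100):
            rows = [{"animal_id": 1, "sire_id": 0, "dam_id": 0}]
            rows += [{"animal_id": 10 + i, "sire_id": 1, "dam_id": 0}
                     for i in range(n)]
            ped = pd.DataFrame(rows)
            y = pd.DataFrame({"a": [1.0] * n, "b": [np.nan] * n},
                             index=[10 + i for i in range(n)])
            ebv = blup_evaluate(ped, y, G, R,
                                known_means=pd.Series({"a": 0.0, "b": 0.0}))
            ebvs.append(ebv.loc[1, "a"])
        assert ebvs[0] < ebvs[1] < ebvs[2]


class TestScheme:
    NULL_CONFIG = SchemeConfig(
        n_cows=200, n_herds=2, n_sires_per_year=5, n_genotyped_per_sex=40,
        n_moet_heifers=4, horizon_years=10, burn_in_years=4, replicates=2,
        selection="random")

    def test_random_selection_gives_zero_trends(self, ref_params, goals):
        res = run_scheme(self.NULL_CONFIG, ref_params, goals["Base"],
                         rng_seed=2)
        # pure drift: cohort-mean SE ~ 1/sqrt(200); 5-sigma band on slopes
        assert res.annual_gain.abs().max() < 0.08

    def test_generation_interval_under_age_rules(self, scheme_run):
        res = scheme_run("Base")
        assert 2.3 <= res.generation_interval <= 2.5

    def test_selection_produces_gain_and_retains_variance(self, scheme_run):
        res = scheme_run("Base")
        assert res.annual_gain["Milk_HS"] > 0.15
        assert res.annual_gain["BasAcq"] > 0.05
        assert ((res.alpha > 0.6) & (res.alpha <= 1.2)).all()
        assert res.inbreeding_rate_pct > 0

    def test_aliased_traits_share_their_response(self, scheme_run):
        """BWcalv1/BasAcq and Lact_Eff/LactAll are single panel traits, so
        the conventional response table repeats them exactly."""
        res = scheme_run("Base")
        assert res.annual_gain["BasAcq"] == res.aa_response["BasAcq"]
        assert res.annual_gain["LactAll"] == res.aa_response["LactAll"]

    def test_determinism_across_calls(self, ref_params, goals):
        a = run_scheme(self.NULL_CONFIG, ref_params, goals["Base"], rng_seed=9)
        b = run_scheme(self.NULL_CONFIG, ref_params, goals["Base"], rng_seed=9)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_invalid_configs_rejected(self):
        with pytest.raises(SchemeError):
            SchemeConfig(horizon_years=10, burn_in_years=10)
        with pytest.raises(SchemeError):
            SchemeConfig(n_cows=1001, n_herds=10)
        with pytest.raises(SchemeError):
            SchemeConfig(n_sires_per_year=0)

    def test_insufficient_candidates_is_structured_error(self, ref_params,
                                                         goals):
        cfg = SchemeConfig(n_cows=200, n_herds=2, n_sires_per_year=150,
                           n_genotyped_per_sex=160, n_moet_heifers=4,
                           horizon_years=6, burn_in_years=2, replicates=1)
        with pytest.raises(SchemeError):
            run_scheme(cfg, ref_params, goals["Base"], rng_seed=0)
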