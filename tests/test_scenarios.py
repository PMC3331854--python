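"""Scenario catalogue and half-sib data generators."""

import numpy as np
import pytest

import penreml as pr
from penreml.exceptions import ConfigurationError, InvalidInputError
from penreml.likelihood import strata_covariances
from penreml.scenarios import (HERITABILITY_SETS_Q5, HERITABILITY_SETS_Q9,
                               correlation_matrix, phenotypic_variances)


class TestCorrelationScenarios:
    def test_scenario_I_identity(self):
        for q in (5, 9):
            np.testing.assert_array_equal(correlation_matrix("I", q, "genetic"),
                                          np.eye(q))
            np.testing.assert_array_equal(correlation_matrix("I", q, "residual"),
                                          np.eye(q))

    def test_scenario_II_constant_genetic(self):
        R = correlation_matrix("II", 5, "genetic")
        off = R[np.triu_indices(5, k=1)]
        np.testing.assert_allclose(off, 0.8)
        np.testing.assert_array_equal(correlation_matrix("II", 5, "residual"),
                                      np.eye(5))

    def test_scenario_III_power_law(self):
        R = correlation_matrix("III", 5, "genetic")
        assert R[0, 2] == pytest.approx(0.36)
        assert R[0, 1] == pytest.approx(0.6)
        RE = correlation_matrix("III", 5, "residual")
        assert RE[0, 1] == pytest.approx(-0.4 + 0.5)
        assert RE[0, 2] == pytest.approx(0.16 + 0.5)

    def test_scenario_VI(self):
        R = correlation_matrix("VI", 9, "genetic")
        assert R[7, 8] == pytest.approx(0.7)
        RE = correlation_matrix("VI", 9, "residual")
        # r_E(i,j) = (-1)^j 0.05 i + 0.2 with i < j, 1-based
        assert RE[0, 1] == pytest.approx(0.05 + 0.2)
        assert RE[0, 2] == pytest.approx(-0.05 + 0.2)

    def test_all_catalogued_matrices_positive_definite(self):
        for sid, q in [("I", 5), ("II", 5), ("III", 5), ("IV", 5), ("V", 5),
                       ("I", 9), ("VI", 9), ("VII", 9)]:
            for side in ("genetic", "residual"):
                R = correlation_matrix(sid, q, side)
                assert np.linalg.eigvalsh(R).min() > 0

    def test_wrong_dimension_rejected(self):
        with pytest.raises(ConfigurationError):
            correlation_matrix("II", 9, "genetic")
        with pytest.raises(ConfigurationError):
            correlation_matrix("VI", 5, "genetic")

    def test_variance_patterns(self):
        np.testing.assert_allclose(phenotypic_variances("II", 5),
                                   [1.0, 1.5, 2.25, 3.375, 5.0625])
        np.testing.assert_allclose(phenotypic_variances("IV", 5),
                                   [3.0, 2.0, 1.0, 2.0, 3.0])
        np.testing.assert_allclose(phenotypic_variances("VI", 9),
                                   [2, 1, 3, 2, 1, 2, 3, 1, 2])
        np.testing.assert_allclose(phenotypic_variances("I", 7), np.ones(7))


class TestCatalogue:
    def test_count_and_split(self):
        cat = pr.catalogue()
        assert len(cat) == 90
        assert sum(1 for c in cat if c.q == 5) == 60
        assert sum(1 for c in cat if c.q == 9) == 30

    def test_heritability_set_means(self):
        for name, h2 in HERITABILITY_SETS_Q5.items():
            expected = 0.3 if name == "H" else (0.4 if name <= "G" else 0.2)
            assert np.mean(h2) == pytest.approx(expected, abs=1e-9), name
        for name, h2 in HERITABILITY_SETS_Q9.items():
            if name == "R":
                continue  # level not pinned down; equal values only
            expected = 0.4 if name <= "Q" else 0.2
            assert np.mean(h2) == pytest.approx(expected, abs=1e-9), name

    def test_equal_value_sets(self):
        for name in ("A", "I"):
            assert len(set(HERITABILITY_SETS_Q5[name])) == 1
        for name in ("M", "R"):
            assert len(set(HERITABILITY_SETS_Q9[name])) == 1

    def test_declining_with_trait_number(self):
        for sets in (HERITABILITY_SETS_Q5, HERITABILITY_SETS_Q9):
            for name, h2 in sets.items():
                assert all(a >= b for a, b in zip(h2, h2[1:])), name

    def test_printed_T_set(self):
        np.testing.assert_allclose(
            HERITABILITY_SETS_Q9["T"],
            [0.5, 0.5, 0.2, 0.15, 0.15, 0.1, 0.1, 0.05, 0.05])

    def test_all_truths_valid(self):
        for scen in pr.catalogue():
            lam = scen.canonical_eigenvalues()
            assert lam.min() > 0 and lam.max() < 1, scen.name
            np.testing.assert_allclose(np.diag(scen.truth.sigma_P),
                                       scen.phen_var, atol=1e-12)

    def test_t_vi_truth(self):
        scen = pr.get_scenario("T-VI")
        np.testing.assert_allclose(scen.phen_var, [2, 1, 3, 2, 1, 2, 3, 1, 2])
        np.testing.assert_allclose(np.diag(scen.truth.sigma_G),
                                   scen.h2 * scen.phen_var)

    def test_equal_eigenvalue_scenario(self):
        scen = pr.get_scenario("A-I")
        lam = scen.canonical_eigenvalues()
        np.testing.assert_allclose(lam, 0.4, atol=1e-12)
        assert lam.std() / lam.mean() == pytest.approx(0.0, abs=1e-12)


class TestSimulation:
    def test_generator_moments(self, small_scenario):
        # E[M_B] = Sigma_B and E[M_W] = Sigma_W across replicates
        config = pr.SimConfig(s=40, n=10)
        truth = small_scenario.truth
        Sigma_W, Sigma_B = strata_covariances(truth.sigma_G, truth.sigma_E, 10)
        gen = np.random.default_rng(2024)
        R = 4000
        mb = np.zeros((2, 2))
        mw = np.zeros((2, 2))
        for _ in range(R):
            d = pr.simulate_dataset(small_scenario, config, rng=gen)
            mb += d.M_B
            mw += d.M_W
        mb /= R
        mw /= R
        # 3 Monte-Carlo standard errors: Var(M_B_ii) ~ 2 Sigma_B_ii^2/(s-1)
        tol_b = 3 * np.sqrt(2.0 / (config.s - 1) / R) * np.abs(Sigma_B).max()
        tol_w = 3 * np.sqrt(2.0 / (config.s * 9) / R) * np.abs(Sigma_W).max()
        assert np.abs(mb - Sigma_B).max() < tol_b * 1.5
        assert np.abs(mw - Sigma_W).max() < tol_w * 1.5

    def test_record_and_stats_generators_agree_in_distribution(self, small_scenario):
        # both generators reproduce E[M_B] = Sigma_B within Monte-Carlo error
        config = pr.SimConfig(s=60, n=10)
        truth = small_scenario.truth
        _, Sigma_B = strata_covariances(truth.sigma_G, truth.sigma_E, config.n)
        R = 400
        se = np.sqrt(2.0 / (config.s - 1) / R) * np.abs(Sigma_B).max()
        gen1 = np.random.default_rng(5)
        mb_fast = np.mean([pr.simulate_dataset(small_scenario, config, rng=gen1).M_B
                           for _ in range(R)], axis=0)
        gen2 = np.random.default_rng(6)
        mb_rec = np.mean([pr.records_to_stats(
            pr.simulate_records(small_scenario, config, rng=gen2)).M_B
            for _ in range(R)], axis=0)
        assert np.abs(mb_fast - Sigma_B).max() < 4 * se
        assert np.abs(mb_rec - Sigma_B).max() < 4 * se

    def test_seed_reproducibility(self, small_scenario):
        config = pr.SimConfig(s=10, n=5, seed=77)
        d1 = pr.simulate_dataset(small_scenario, config)
        d2 = pr.simulate_dataset(small_scenario, config)
        np.testing.assert_array_equal(d1.M_B, d2.M_B)
        np.testing.assert_array_equal(d1.M_W, d2.M_W)

    def test_n_one_rejected(self, small_scenario):
        with pytest.raises(InvalidInputError):
            pr.SimConfig(s=10, n=1)

    def test_validation_stats_q1(self):
        scen = pr.build_scenario("v", [0.4], "I")
        stats = pr.validation_stats(scen, pr.SimConfig(s=50, n=10))
        assert stats.M_W[0, 0] == pytest.approx(0.9)
        assert stats.M_B[0, 0] == pytest.approx(1.9)

    def test_unpenalized_fit_on_validation_stats_recovers_truth(self):
        scen = pr.get_scenario("C-I")
        stats = pr.validation_stats(scen, pr.SimConfig(s=200, n=10))
        res = pr.fit(stats)
        np.testing.assert_allclose(res.pair.sigma_G, scen.truth.sigma_G, atol=1e-5)
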