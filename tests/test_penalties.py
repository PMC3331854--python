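"""Penalty functions: hand-computed values, minima, invariances, gradients."""

import numpy as np
import pytest

import penreml as pr
from penreml import estimator as est
from penreml.exceptions import BoundaryError, ConfigurationError
from penreml.penalties import (PenaltyBaseline, p_beta_fixed, p_beta_mom,
                               p_beta_order, p_lambda, p_lambda_log,
                               p_lambda_log2, p_rho, p_sigma)
from .conftest import random_pair


def make_baseline(lambdas0, sigma_P0=None, with_mom=False):
    lambdas0 = np.asarray(lambdas0, dtype=float)
    q = lambdas0.size
    sigma_P0 = np.eye(q) if sigma_P0 is None else np.asarray(sigma_P0)
    a = b = None
    if with_mom:
        a, b = pr.estimate_beta_shapes(lambdas0)
    return PenaltyBaseline(
        lambdas0=lambdas0, sigma_P0=sigma_P0,
        R_P0=sigma_P0 / np.sqrt(np.outer(np.diag(sigma_P0), np.diag(sigma_P0))),
        alpha_mom=a, beta_mom=b)


class TestEigenvaluePenalties:
    def test_p_lambda_values(self):
        assert p_lambda([0.3, 0.3, 0.3]) == 0.0
        assert p_lambda([0.2, 0.4]) == pytest.approx(0.02)

    def test_p_lambda_reflection_symmetry(self, rng):
        lam = rng.uniform(0.05, 0.95, 6)
        assert p_lambda(lam) == pytest.approx(p_lambda(1 - lam))

    def test_p_lambda_log_values(self):
        lam = np.array([0.2 * np.e ** -1, 0.2 * np.e])
        assert p_lambda_log(lam) == pytest.approx(2.0)
        assert p_lambda_log([0.3, 0.3]) == 0.0

    def test_p_lambda_log2_decomposition(self, rng):
        lam = rng.uniform(0.05, 0.95, 5)
        assert p_lambda_log2(lam) == pytest.approx(
            p_lambda_log(lam) + p_lambda_log(1 - lam))

    def test_log_penalties_reject_boundary(self):
        with pytest.raises(BoundaryError):
            p_lambda_log([0.0, 0.5])
        with pytest.raises(BoundaryError):
            p_lambda_log2([0.5, 1.0])

    def test_beta_fixed_hand_values(self):
        spec = pr.PenaltySpec(kind="P_beta_fixed", alpha=2, beta=2,
                              baseline=make_baseline([0.8, 0.4, 0.0]))
        # lambda* = 0.25 for lambda = 0.2 on range [0, 0.8]
        val = p_beta_fixed(np.array([0.2]), spec)
        assert val == pytest.approx(-(np.log(0.25) + np.log(0.75)), rel=1e-6)
        assert val == pytest.approx(1.674, abs=1e-3)

    def test_beta_fixed_uniform_shapes_vanish(self, rng):
        spec = pr.PenaltySpec(kind="P_beta_fixed", alpha=1, beta=1,
                              baseline=make_baseline([0.9, 0.1]))
        assert p_beta_fixed(rng.uniform(0.15, 0.85, 4), spec) == 0.0

    def test_beta_fixed_minimum_at_midrange(self):
        spec = pr.PenaltySpec(kind="P_beta_fixed", alpha=2, beta=2,
                              baseline=make_baseline([0.9, 0.1]))
        mid = p_beta_fixed(np.array([0.5, 0.5]), spec)
        assert mid == pytest.approx(2 * 2 * np.log(2))
        for lam in ([0.3, 0.5], [0.5, 0.7], [0.2, 0.8]):
            assert p_beta_fixed(np.array(lam), spec) > mid

    def test_degenerate_baseline_range_rejected(self):
        spec = pr.PenaltySpec(kind="P_beta_fixed",
                              baseline=make_baseline([0.4, 0.4]))
        with pytest.raises(ConfigurationError):
            p_beta_fixed(np.array([0.4]), spec)

    def test_moment_shapes_hand_value(self):
        a, b = pr.estimate_beta_shapes([0.2, 0.4, 0.6])
        assert (a, b) == (pytest.approx(3.2), pytest.approx(4.8))

    def test_moment_shapes_symmetry_and_mean(self, rng):
        lam = 0.5 + np.array([-0.2, -0.1, 0.1, 0.2])
        a, b = pr.estimate_beta_shapes(lam)
        assert a == pytest.approx(b)
        lam2 = rng.uniform(0.2, 0.7, 6)
        a2, b2 = pr.estimate_beta_shapes(lam2)
        assert a2 / (a2 + b2) == pytest.approx(lam2.mean())

    def test_moment_shapes_zero_spread_rejected(self):
        with pytest.raises(ConfigurationError):
            pr.estimate_beta_shapes([0.4, 0.4, 0.4])

    def test_beta_mom_hand_value(self):
        base = make_baseline([0.2, 0.4, 0.6], with_mom=True)
        spec = pr.PenaltySpec(kind="P_beta_mom", z=1.0, baseline=base)
        val = p_beta_mom(np.array([0.4]), spec)
        assert val == pytest.approx(-(3.2 * np.log(0.4) + 4.8 * np.log(0.6)))
        assert val == pytest.approx(5.384, abs=1e-3)

    def test_beta_mom_minimized_at_mode(self):
        base = make_baseline([0.2, 0.4, 0.6], with_mom=True)
        spec = pr.PenaltySpec(kind="P_beta_mom", z=0.0, baseline=base)
        a, b = base.alpha_mom, base.beta_mom
        mode = (a - 1) / (a + b - 2)
        vals = {lam: p_beta_mom(np.array([lam]), spec)
                for lam in (mode - 0.05, mode, mode + 0.05)}
        assert vals[mode] == min(vals.values())

    def test_beta_order_hand_value(self):
        spec = pr.PenaltySpec(kind="P_beta_order", z=0.0,
                              baseline=make_baseline([1.0, 0.0]))
        val = p_beta_order(np.array([0.75, 0.25]), spec)
        assert val == pytest.approx(-2 * np.log(0.75), rel=1e-4)
        assert val == pytest.approx(0.575, abs=1e-3)

    def test_beta_order_single_trait_z0_vanishes(self):
        spec = pr.PenaltySpec(kind="P_beta_order", z=0.0,
                              baseline=make_baseline([0.9, 0.1]))
        assert p_beta_order(np.array([0.5]), spec) == pytest.approx(0.0)

    def test_beta_order_modes_flatten_as_z_grows(self):
        # implied component modes (z+i-1)/(2z+q-1) converge to 1/2
        q = 5
        for z_small, z_big in [(0.0, 10.0), (1.0, 100.0)]:
            i = np.arange(1, q + 1)
            modes_small = (z_small + i - 1) / (2 * z_small + q - 1)
            modes_big = (z_big + i - 1) / (2 * z_big + q - 1)
            assert np.ptp(modes_big) < np.ptp(modes_small)


class TestMatrixPenalties:
    def test_p_sigma_at_target_identity(self):
        pair = pr.CovariancePair(sigma_G=np.eye(2), sigma_E=np.eye(2))
        spec = pr.PenaltySpec(kind="P_Sigma", c_approx_one=True,
                              baseline=make_baseline([0.5, 0.5], np.eye(2)))
        assert p_sigma(pair, spec, 1.0) == pytest.approx(2.0)

    def test_p_sigma_hand_value_and_kl(self):
        pair = pr.CovariancePair(sigma_G=np.diag([0.5, 2.0]), sigma_E=np.eye(2))
        spec = pr.PenaltySpec(kind="P_Sigma", c_approx_one=True,
                              baseline=make_baseline([0.5, 0.5], np.eye(2)))
        val = p_sigma(pair, spec, 1.0)
        assert val == pytest.approx(np.log(1.0) + 2.0 + 0.5)
        # divergence from the target: P - min(P) equals the KL-type loss
        at_target = p_sigma(
            pr.CovariancePair(sigma_G=np.eye(2), sigma_E=np.eye(2)), spec, 1.0)
        kl = pr.entropy_loss(np.diag([0.5, 2.0]), np.eye(2))
        assert val - at_target == pytest.approx(kl)

    def test_p_sigma_minimized_at_target(self, rng):
        target = np.array([[1.0, 0.3], [0.3, 2.0]])
        base = make_baseline([0.5, 0.5], target)
        spec = pr.PenaltySpec(kind="P_Sigma", c_approx_one=True, baseline=base)
        at_target = spec.value(
            pair=pr.CovariancePair(sigma_G=target, sigma_E=np.eye(2)), psi=1.0)
        for _ in range(5):
            pair = random_pair(rng, 2, 0.2, 0.8)
            assert spec.value(pair=pair, psi=1.0) >= at_target - 1e-10

    def test_p_rho_at_target(self):
        R0 = np.array([[1.0, 0.5], [0.5, 1.0]])
        base = make_baseline([0.5, 0.5], R0)
        spec = pr.PenaltySpec(kind="P_rho", c_approx_one=True, baseline=base)
        pair = pr.CovariancePair(sigma_G=4 * R0, sigma_E=np.eye(2))
        sign, logdet = np.linalg.slogdet(R0)
        assert p_rho(pair, spec, 1.0) == pytest.approx(logdet + 2.0)

    def test_p_rho_identity_genetic_correlation(self):
        R0 = np.array([[1.0, 0.5], [0.5, 1.0]])
        spec = pr.PenaltySpec(kind="P_rho", c_approx_one=True,
                              baseline=make_baseline([0.5, 0.5], R0))
        # diagonal sigma_G: R_G = I, penalty = log 1 + tr(R_P0) = 2
        for scale in (0.5, 3.0):
            pair = pr.CovariancePair(sigma_G=np.diag([1.0, scale]),
                                     sigma_E=np.eye(2))
            assert p_rho(pair, spec, 1.0) == pytest.approx(2.0)

    def test_p_rho_scale_invariance_p_sigma_not(self, rng):
        pair = random_pair(rng, 3, 0.2, 0.8)
        scale = np.diag([1.0, 10.0, 0.3])
        scaled = pr.CovariancePair(sigma_G=scale @ pair.sigma_G @ scale,
                                   sigma_E=scale @ pair.sigma_E @ scale)
        base = make_baseline([0.5] * 3, pair.sigma_P)
        base_scaled = PenaltyBaseline(
            lambdas0=base.lambdas0, sigma_P0=scale @ pair.sigma_P @ scale,
            R_P0=base.R_P0)
        rho = pr.PenaltySpec(kind="P_rho", c_approx_one=True)
        sig = pr.PenaltySpec(kind="P_Sigma", c_approx_one=True)
        v_rho = [pr.penalties.p_rho(p, pr.PenaltySpec(kind="P_rho", c_approx_one=True, baseline=b), 1.0)
                 for p, b in [(pair, base), (scaled, base_scaled)]]
        v_sig = [pr.penalties.p_sigma(p, pr.PenaltySpec(kind="P_Sigma", c_approx_one=True, baseline=b), 1.0)
                 for p, b in [(pair, base), (scaled, base_scaled)]]
        assert v_rho[0] == pytest.approx(v_rho[1], rel=1e-10)
        assert abs(v_sig[0] - v_sig[1]) > 1e-6

    def test_exact_c_weight(self):
        pair = pr.CovariancePair(sigma_G=np.diag([0.5, 2.0]), sigma_E=np.eye(2))
        base = make_baseline([0.5, 0.5], np.eye(2))
        spec = pr.PenaltySpec(kind="P_Sigma", baseline=base)
        psi = 4.0
        C = (psi + 2 + 1) / psi
        expected = C * np.log(1.0) + 2.5
        assert spec.value(pair=pair, psi=psi) == pytest.approx(expected)
        # scaled form continuous formulation: psi*C = psi + q + 1
        assert spec.scaled_value(pair=pair, psi=psi) == pytest.approx(psi * expected)

    def test_psi_zero_exact_c_rejected(self):
        base = make_baseline([0.5, 0.5], np.eye(2))
        spec = pr.PenaltySpec(kind="P_Sigma", baseline=base)
        pair = pr.CovariancePair(sigma_G=np.eye(2), sigma_E=np.eye(2))
        with pytest.raises(ConfigurationError):
            spec.value(pair=pair, psi=0.0)


class TestPenaltySpec:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            pr.PenaltySpec(kind="P_bogus")

    def test_baseline_required(self, rng):
        spec = pr.PenaltySpec(kind="P_Sigma")
        with pytest.raises(ConfigurationError):
            spec.value(pair=random_pair(rng, 2), psi=1.0)

    def test_with_baseline_freezes_quantities(self, rng):
        pair = random_pair(rng, 3)
        spec = pr.PenaltySpec(kind="P_beta_mom").with_baseline(pair)
        form = pr.canonical_decompose(pair)
        np.testing.assert_allclose(spec.baseline.lambdas0, form.lambdas)
        assert spec.baseline.alpha_mom > 0 and spec.baseline.beta_mom > 0

    def test_t_invariance_of_eigen_penalties(self, rng):
        # eigenvalue penalties depend on lambda only, not on T
        lam = np.array([0.6, 0.35, 0.15])
        for _ in range(3):
            A = rng.standard_normal((3, 3))
            T = np.linalg.cholesky(A @ A.T + 3 * np.eye(3))
            pair = pr.canonical_compose(pr.CanonicalForm(lambdas=lam, T=T))
            spec = pr.PenaltySpec(kind="P_lambda_log")
            assert spec.value(pair=pair) == pytest.approx(
                p_lambda_log(lam), rel=1e-8)

    def test_separate_tuning_two_part(self, rng):
        pair = random_pair(rng, 3, 0.2, 0.8)
        lam = pr.canonical_decompose(pair).lambdas
        spec = pr.PenaltySpec(kind="P_lambda_log2", separate_tuning=True)
        joint = spec.scaled_value(lambdas=lam, psi=2.0)
        split = spec.scaled_value(lambdas=lam, psi=(2.0, 2.0))
        assert joint == pytest.approx(split)
        asym = spec.scaled_value(lambdas=lam, psi=(2.0, 0.5))
        assert asym == pytest.approx(2.0 * p_lambda_log(lam)
                                     + 0.5 * p_lambda_log(1 - lam))


class TestAnalyticGradients:
    @pytest.mark.parametrize("kind", pr.PENALTY_KINDS)
    def test_matches_finite_differences(self, kind):
        scen = pr.get_scenario("C-III")
        data = pr.simulate_dataset(scen, pr.SimConfig(s=60, n=10), rng=3)
        base = pr.fit(data)
        spec = pr.PenaltySpec(kind=kind)
        if spec.needs_baseline:
            spec = spec.with_baseline(base.pair)
        negobj = est._objective_factory(data, spec, 3.7)
        gen = np.random.default_rng(7)
        p = np.concatenate([
            est._u_from_lam(np.clip(base.form.lambdas + gen.normal(0, 0.15, 5),
                                    0.02, 0.95)),
            (base.form.T + 0.05 * gen.standard_normal((5, 5))).reshape(-1)])
        _, g = negobj(p)
        h = 1e-6
        for i in gen.choice(p.size, 8, replace=False):
            pp, pm = p.copy(), p.copy()
            pp[i] += h
            pm[i] -= h
            fd = (negobj(pp)[0] - negobj(pm)[0]) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=5e-4, abs=1e-6)
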