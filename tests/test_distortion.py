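"""Marker-SNP model distortion: exact identities, approximations, beta-prime."""

import math

import numpy as np
import pytest

import tagdistort as td
from tagdistort.distortion import marker_interaction_penetrances
from tagdistort.ld import hwe_genotype_freqs

from conftest import random_valid_ld


def random_small_model(rng) -> td.GeneralModel:
    beta = rng.uniform(-0.5, 0.5)
    gamma = rng.uniform(-0.5, 0.5)
    return td.GeneralModel(mu=math.log(0.005), beta=beta, gamma=gamma)


class TestMarkerPenetrances:
    def test_no_ld_flattens_to_mean_risk(self):
        m = td.GeneralModel.from_homozygous_rr("dominant", 1.96)
        f = 0.3
        p_B = td.marker_penetrances(m, td.TwoLocusLD(f, 0.4, 0.0)).values
        mean_risk = hwe_genotype_freqs(f) @ m.penetrances().values
        np.testing.assert_allclose(p_B, mean_risk, atol=1e-12)

    def test_perfect_ld_copies_penetrances(self):
        m = td.GeneralModel.from_homozygous_rr("recessive", 1.96)
        p_B = td.marker_penetrances(m, td.TwoLocusLD(0.3, 0.3, 1.0)).values
        np.testing.assert_allclose(p_B, m.penetrances().values, atol=1e-12)

    def test_second_difference_scales_by_c_squared(self, rng):
        """p_B2 - 2 p_B1 + p_B0 = (q1-q0)^2 (p_A2 - 2 p_A1 + p_A0), exactly.

        The exact distortion law behind the quadratic decay of dominance
        effects; checked to 1e-12 over 1,000 random scenarios.
        """
        for _ in range(1000):
            ld = random_valid_ld(rng)
            m = random_small_model(rng)
            p_A = m.penetrances().values
            p_B = td.marker_penetrances(m, ld).values
            q0, q1 = td.conditional_probs(ld)
            lhs = p_B[2] - 2 * p_B[1] + p_B[0]
            rhs = (q1 - q0) ** 2 * (p_A[2] - 2 * p_A[1] + p_A[0])
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_population_mean_risk_preserved(self, rng):
        for _ in range(300):
            ld = random_valid_ld(rng)
            m = random_small_model(rng)
            mean_A = hwe_genotype_freqs(ld.f_A) @ m.penetrances().values
            mean_B = hwe_genotype_freqs(ld.f_B) @ td.marker_penetrances(m, ld).values
            assert mean_B == pytest.approx(mean_A, abs=1e-12)


class TestMarkerParamsExact:
    def test_inverts_to_marker_penetrances(self, rng):
        for _ in range(100):
            ld = random_valid_ld(rng)
            m = random_small_model(rng)
            mk = td.marker_params_exact(m, ld)
            np.testing.assert_allclose(
                mk.as_general_model().penetrances().values,
                td.marker_penetrances(m, ld).values,
                rtol=1e-10,
            )

    def test_perfect_ld_recovers_causal_parameters(self):
        m = td.GeneralModel.from_homozygous_rr("dominant", 1.96)
        mk = td.marker_params_exact(m, td.TwoLocusLD(0.3, 0.3, 1.0))
        assert mk.beta_B == pytest.approx(m.beta, abs=1e-12)
        assert mk.gamma_B == pytest.approx(m.gamma, abs=1e-12)

    def test_multiplicative_truth_stays_nearly_multiplicative(self):
        """|gamma_B| stays below 1e-2 for per-allele effects up to log 1.4."""
        m = td.GeneralModel(beta=math.log(1.4))
        for r in np.linspace(0.05, 0.95, 10):
            for f in np.linspace(0.05, 0.95, 10):
                lo, hi = td.r_bounds(f, 0.3)
                if not lo < r < hi:
                    continue
                mk = td.marker_params_exact(m, td.TwoLocusLD(f, 0.3, float(r)))
                assert abs(mk.gamma_B) <= 1e-2

    def test_dominant_parameters_shrink_monotonically_with_r(self):
        m = td.GeneralModel.from_homozygous_rr("dominant", 1.4**2)
        rs = np.linspace(0.95, 0.05, 10)
        betas, gammas = [], []
        for r in rs:
            mk = td.marker_params_exact(m, td.TwoLocusLD(0.3, 0.3, float(r)))
            betas.append(mk.beta_B)
            gammas.append(mk.gamma_B)
        assert all(np.diff(betas) < 0) and all(np.diff(gammas) < 0)
        assert betas[-1] == pytest.approx(0.0, abs=0.05)
        assert gammas[-1] == pytest.approx(0.0, abs=0.02)


class TestApproximateParams:
    def test_zero_ld_gives_zero_effects(self):
        m = td.GeneralModel.from_homozygous_rr("dominant", 1.96)
        assert td.approx_marker_params(m, td.TwoLocusLD(0.3, 0.4, 0.0)) == (0.0, 0.0)

    def test_small_effect_accuracy(self):
        """c*beta for multiplicative truths, c^2*gamma for the dominance effect.

        The linear-in-r law is the multiplicative-model relation; under a
        dominant truth the additive marker effect also carries a dominance
        leakage term c(1-q0-q1)*gamma_A, so beta is checked on a
        multiplicative model and gamma on the dominant one.
        """
        ld = td.TwoLocusLD(0.3, 0.3, 0.8)
        mult = td.GeneralModel.from_homozygous_rr("multiplicative", 1.1**2)
        b_a, _ = td.approx_marker_params(mult, ld)
        assert b_a == pytest.approx(td.marker_params_exact(mult, ld).beta_B, rel=0.05)
        dom = td.GeneralModel.from_homozygous_rr("dominant", 1.1**2)
        _, g_a = td.approx_marker_params(dom, ld)
        assert g_a == pytest.approx(td.marker_params_exact(dom, ld).gamma_B, rel=0.05)

    def test_dominance_leakage_into_the_additive_effect(self):
        """beta_B -> c*beta_A + c(1-q0-q1)*gamma_A as effects shrink."""
        ld = td.TwoLocusLD(0.3, 0.3, 0.8)
        q0, q1 = td.conditional_probs(ld)
        c = q1 - q0
        m = td.GeneralModel.from_homozygous_rr("dominant", 1.01**2)
        mk = td.marker_params_exact(m, ld)
        predicted = c * m.beta + c * (1 - q0 - q1) * m.gamma
        assert mk.beta_B == pytest.approx(predicted, rel=0.01)

    def test_gamma_ratio_is_square_of_beta_ratio_at_equal_frequencies(self):
        m = td.GeneralModel.from_homozygous_rr("dominant", 1.1**2)
        ld = td.TwoLocusLD(0.25, 0.25, 0.7)
        b_a, g_a = td.approx_marker_params(m, ld)
        assert g_a / m.gamma == pytest.approx((b_a / m.beta) ** 2, abs=1e-12)

    def test_relative_error_shrinks_with_effect_size(self):
        """Approximation ladder: error -> 0 as hom RR -> 1."""
        ld = td.TwoLocusLD(0.3, 0.3, 0.7)
        errs = []
        for hom_rr in (1.4**2, 1.2**2, 1.1**2, 1.05**2):
            m = td.GeneralModel.from_homozygous_rr("dominant", hom_rr)
            _, g_approx = td.approx_marker_params(m, ld)
            g_exact = td.marker_params_exact(m, ld).gamma_B
            errs.append(abs(g_approx - g_exact) / abs(g_exact))
        assert all(np.diff(errs) < 0)
        assert errs[-1] < 0.02


class TestMarkerInteraction:
    def test_no_ld_kills_interaction(self):
        m = td.InteractionModel(beta1=0.2, beta2=0.2, tau=0.3)
        mk = td.marker_interaction(
            m, td.TwoLocusLD(0.3, 0.3, 0.0), td.TwoLocusLD(0.3, 0.3, 0.0)
        )
        assert mk.tau_B == pytest.approx(0.0, abs=1e-12)

    def test_multiplicative_model_stays_multiplicative(self, rng):
        m = td.InteractionModel(beta1=0.3, beta2=0.15, tau=0.0)
        for _ in range(50):
            mk = td.marker_interaction(m, random_valid_ld(rng), random_valid_ld(rng))
            assert mk.tau_B == pytest.approx(0.0, abs=1e-10)

    def test_small_tau_scales_by_product_of_correlations(self):
        tau = math.log(1.1)
        m = td.InteractionModel(tau=tau)
        ld1 = td.TwoLocusLD(0.3, 0.3, 0.8)
        ld2 = td.TwoLocusLD(0.2, 0.25, 0.6)
        q0a, q1a = td.conditional_probs(ld1)
        q0b, q1b = td.conditional_probs(ld2)
        mk = td.marker_interaction(m, ld1, ld2)
        assert mk.tau_B == pytest.approx((q1a - q0a) * (q1b - q0b) * tau, rel=0.05)

    def test_determinant_scales_by_both_correlations(self, rng):
        """det P_B = (q1-q0)(q1'-q0') det P_A to 1e-12, 1,000 random scenarios."""
        for _ in range(1000):
            ld1, ld2 = random_valid_ld(rng), random_valid_ld(rng)
            m = td.InteractionModel(
                mu=math.log(0.005),
                beta1=rng.uniform(-0.4, 0.4),
                beta2=rng.uniform(-0.4, 0.4),
                tau=rng.uniform(-0.4, 0.4),
            )
            P_A = m.penetrance_matrix().values
            P_B = marker_interaction_penetrances(m, ld1, ld2)
            q0a, q1a = td.conditional_probs(ld1)
            q0b, q1b = td.conditional_probs(ld2)
            assert np.linalg.det(P_B) == pytest.approx(
                (q1a - q0a) * (q1b - q0b) * np.linalg.det(P_A), abs=1e-12
            )


class TestEffectiveAdditive:
    def test_multiplicative_model_is_exact(self):
        """beta' = beta for the multiplicative model at every RAF."""
        m = td.GeneralModel.from_homozygous_rr("multiplicative", 1.4**2)
        for f in np.linspace(0.05, 0.95, 19):
            assert td.effective_additive(m, float(f)) == pytest.approx(
                math.log(1.4), abs=1e-8
            )

    def test_null_model_gives_zero(self):
        assert td.effective_additive(td.GeneralModel(), 0.3) == pytest.approx(
            0.0, abs=1e-10
        )

    @pytest.mark.parametrize("kind", ["dominant", "recessive"])
    def test_limiting_values_zero_and_twice_the_multiplicative_effect(self, kind):
        """At extreme RAFs the fit sees two genotypes: beta' -> 0 or log(hom RR)."""
        m = td.GeneralModel.from_homozygous_rr(kind, 1.96)
        lo = td.effective_additive(m, 1e-4)
        hi = td.effective_additive(m, 1 - 1e-4)
        zero_end, big_end = (lo, hi) if kind == "recessive" else (hi, lo)
        assert zero_end == pytest.approx(0.0, abs=0.01)
        assert big_end == pytest.approx(math.log(1.96), abs=0.01)

    def test_dominant_beta_prime_between_limits(self):
        m = td.GeneralModel.from_homozygous_rr("dominant", 1.96)
        vals = [td.effective_additive(m, f) for f in (0.1, 0.3, 0.5, 0.9)]
        assert all(0.0 < v < math.log(1.96) for v in vals)
        assert all(np.diff(vals) < 0)  # shrinks as the risk allele gets common


class TestModelSpaceTrajectory:
    def test_single_zero_r_point_is_origin(self):
        m = td.GeneralModel.from_homozygous_rr("dominant", 1.96)
        traj = td.model_space_trajectory(m, 0.3, 0.3, [0.0])
        np.testing.assert_allclose(traj, [[0.0, 0.0, 0.0]])

    def test_curves_bend_toward_the_multiplicative_line(self):
        """|gamma_B / beta_B| is non-increasing as |r| decreases."""
        m = td.GeneralModel.from_homozygous_rr("dominant", 1.4**2)
        traj = td.model_space_trajectory(m, 0.3, 0.3, np.linspace(0.95, 0.2, 12))
        ratio = np.abs(traj[:, 2] / traj[:, 1])
        assert all(np.diff(ratio) < 1e-9)

    def test_recessive_curve_stays_below_the_line(self):
        m = td.GeneralModel.from_homozygous_rr("recessive", 1.4**2)
        traj = td.model_space_trajectory(m, 0.3, 0.3, np.linspace(0.1, 0.95, 10))
        assert np.all(traj[:, 2] <= 1e-12)

    def test_endpoint_matches_causal_model_at_equal_frequencies(self):
        m = td.GeneralModel.from_homozygous_rr("dominant", 1.4**2)
        traj = td.model_space_trajectory(m, 0.3, 0.3, [1.0])
        assert traj[0, 1] == pytest.approx(m.beta, abs=1e-12)
        assert traj[0, 2] == pytest.approx(m.gamma, abs=1e-12)
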