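"""Paradox-risk measures: orthant probabilities, conditional risk, s-values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal, norm

from sprisk.measures import (
    bvn_cdf,
    marginal_psi,
    observed_surrogate_effect,
    prob_harm_given_s,
    psi_sp13,
    psi_sp123,
    psi_values,
    s_threshold,
    s_threshold_closed_form,
)
from sprisk.model import ModelParams, TreatmentEffectJoint, joint_effect_distribution
from sprisk.simulate import default_parameters


def _random_joint(rng):
    mean = rng.normal(0, 2, 2)
    a = rng.normal(0, 1, (2, 2))
    cov = a @ a.T + 0.05 * np.eye(2)
    return TreatmentEffectJoint(mean=mean, cov=cov)


class TestBvnCdf:
    def test_matches_scipy_quasi_mc_routine(self, rng):
        """Owen's-T route agrees with scipy's independent MVN CDF to 1e-7."""
        for _ in range(200):
            h, k = rng.normal(0, 2, 2)
            r = rng.uniform(-0.999, 0.999)
            ref = multivariate_normal(mean=[0, 0], cov=[[1, r], [r, 1]]).cdf([h, k])
            assert bvn_cdf(h, k, r) == pytest.approx(ref, abs=1e-7)

    @pytest.mark.parametrize(
        "h,k,rho,expected",
        [
            (0.0, 0.0, 0.0, 0.25),
            (0.0, 0.0, 0.5, 0.25 + np.arcsin(0.5) / (2 * np.pi)),
            (np.inf, 1.3, 0.2, norm.cdf(1.3)),
            (1.0, 1.0, 1.0, norm.cdf(1.0)),
            (1.0, -1.0, -1.0, 0.0),
        ],
    )
    def test_closed_form_edge_cases(self, h, k, rho, expected):
        assert bvn_cdf(h, k, rho) == pytest.approx(expected, abs=1e-9)


class TestPsiMeasures:
    def test_independent_symmetric_signs(self):
        j = TreatmentEffectJoint(mean=[0, 0], cov=np.eye(2))
        assert psi_sp13(j) == pytest.approx(0.5, abs=1e-9)

    def test_certain_benefit_avoids_paradox(self):
        j = TreatmentEffectJoint(mean=[0, 10], cov=np.eye(2))
        assert psi_sp123(j) == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_quadrant_frequencies(self, rng):
        """Both measures equal MC quadrant frequencies within 3 binomial SEs."""
        n = 200_000
        for _ in range(10):
            j = _random_joint(rng)
            L = np.linalg.cholesky(j.cov)
            draws = rng.standard_normal((n, 2)) @ L.T + j.mean
            agree = float(np.mean(draws[:, 0] * draws[:, 1] > 0))
            not_q4 = float(np.mean(~((draws[:, 0] > 0) & (draws[:, 1] < 0))))
            se = 1.0 / (2 * np.sqrt(n))  # p(1-p) <= 1/4
            assert psi_sp13(j) == pytest.approx(agree, abs=3 * se)
            assert psi_sp123(j) == pytest.approx(not_q4, abs=3 * se)

    @settings(derandomize=True, max_examples=100)
    @given(
        ms=st.floats(-4, 4), mt=st.floats(-4, 4),
        vs=st.floats(0.05, 5), vt=st.floats(0.05, 5),
        r=st.floats(-0.95, 0.95),
    )
    def test_psi123_dominates_psi13(self, ms, mt, vs, vt, r):
        cov = np.array([[vs, r * np.sqrt(vs * vt)], [r * np.sqrt(vs * vt), vt]])
        j = TreatmentEffectJoint(mean=[ms, mt], cov=cov)
        assert psi_sp123(j) >= psi_sp13(j) - 1e-12

    def test_endpoint_swap_symmetry(self, rng):
        for _ in range(20):
            j = _random_joint(rng)
            swapped = TreatmentEffectJoint(
                mean=j.mean[::-1].copy(), cov=j.cov[::-1, ::-1].copy()
            )
            assert psi_sp13(j) == pytest.approx(psi_sp13(swapped), abs=1e-12)

    def test_psi123_nondecreasing_in_true_effect(self):
        cov = np.array([[1.0, 0.3], [0.3, 1.0]])
        vals = [
            psi_sp123(TreatmentEffectJoint(mean=[0.5, mt], cov=cov))
            for mt in np.linspace(-3, 3, 13)
        ]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_psi13_tends_to_one_for_large_effects(self):
        cov = np.array([[1.0, 0.3], [0.3, 1.0]])
        j = TreatmentEffectJoint(mean=[8, 8], cov=cov)
        assert psi_sp13(j) > 0.999999

    def test_zero_variance_zero_mean_is_an_error(self):
        j = TreatmentEffectJoint(mean=[0, 1], cov=[[0, 0], [0, 1]])
        with pytest.raises(ValueError, match="undefined"):
            psi_sp13(j)

    def test_vectorised_matches_scalar(self, rng):
        joints = [_random_joint(rng) for _ in range(30)]
        means = np.array([j.mean for j in joints])
        covs = np.array([j.cov for j in joints])
        p13, p123 = psi_values(means, covs)
        for i, j in enumerate(joints):
            assert p13[i] == pytest.approx(psi_sp13(j), abs=1e-12)
            assert p123[i] == pytest.approx(psi_sp123(j), abs=1e-12)


class TestObservedSurrogateEffect:
    @staticmethod
    def _frame(z, x, s):
        return pd.DataFrame(
            {"trial": 1, "subject": range(len(z)), "z": z, "x": x, "s": s, "t": 0.0}
        )

    def test_constant_surrogate_gives_zero(self):
        df = self._frame([1, 1, 0, 0], [1, 1, 1, 1], [3.0, 3.0, 3.0, 3.0])
        assert observed_surrogate_effect(df, 1, 1).o_s == 0.0

    def test_arm_mean_difference(self, s1_params):
        df = self._frame([1, 1, 0, 0], [1, 1, 1, 1], [3.0, 5.0, 1.0, 1.0])
        eff = observed_surrogate_effect(df, 1, 1, params=s1_params)
        assert eff.o_s == 3.0
        assert (eff.n1x, eff.n0x) == (2, 2)
        daa_star = s1_params.D[2, 2]
        assert eff.d_aa_tilde == pytest.approx(daa_star + 1.0 * (0.5 + 0.5))
        assert eff.d_aa_tilde >= daa_star

    def test_empty_arm_error_names_trial_and_level(self):
        df = self._frame([1, 1, 0, 0], [1, 1, 0, 0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="x=1"):
            observed_surrogate_effect(df, 1, 1)

    def test_converges_to_fixed_effect_without_trial_heterogeneity(self, rng):
        """With near-zero D, O_S at x=0 estimates beta_S."""
        from sprisk.simulate import SimulationDesign, simulate_meta

        params = default_parameters("S1")
        tiny = ModelParams(**{**params.__dict__, "D": 1e-10 * np.eye(4)})
        design = SimulationDesign(scenario="S1", n_trials=1, n_per_trial=20_000,
                                  params=tiny, seed=99)
        data = simulate_meta(design)
        eff = observed_surrogate_effect(data, 1, 0.0)
        se = np.sqrt(1.0 / eff.n1x + 1.0 / eff.n0x)  # sigma_ss = 1
        assert eff.o_s == pytest.approx(2.0, abs=4 * se)


class TestConditionalHarm:
    def test_conditioning_at_the_mean_leaves_no_shift(self, s1_params):
        j = joint_effect_distribution(s1_params, [0.0])
        p = prob_harm_given_s(s1_params, [0.0], s=j.mean[0], n1x=25, n0x=25)
        daa_t = j.cov[0, 0] + 1.0 * (2 / 25)
        expected = norm.cdf(-j.mean[1] / np.sqrt(j.cov[1, 1] - j.cov[0, 1] ** 2 / daa_t))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_independent_surrogate_carries_no_information(self):
        params = default_parameters("S1")
        D = params.D.copy()
        D[2, 3] = D[3, 2] = 0.0  # d_ab = 0
        params = ModelParams(**{**params.__dict__, "D": D})
        probs = [
            prob_harm_given_s(params, [0.0], s, 25, 25) for s in (-5.0, 0.0, 5.0)
        ]
        assert probs[0] == pytest.approx(probs[1]) == pytest.approx(probs[2])
        assert probs[0] == pytest.approx(norm.cdf(-1.0 / np.sqrt(1.0)), abs=1e-12)

    def test_monte_carlo_conditional_density(self, s1_params, rng):
        """Matches the MC estimate of P(Delta_T<0 | O_S in s +- window)."""
        n = 1_000_000
        n1 = n0 = 25
        eff = rng.multivariate_normal([2.0, 1.0], s1_params.D[2:4, 2:4], size=n)
        os_noise = rng.normal(0, np.sqrt(1.0 * (1 / n1 + 1 / n0)), size=n)
        os = eff[:, 0] + os_noise
        s0 = 1.0
        sel = np.abs(os - s0) < 0.02
        mc = float(np.mean(eff[sel, 1] < 0))
        se = np.sqrt(mc * (1 - mc) / sel.sum())
        p = prob_harm_given_s(s1_params, [0.0], s0, n1, n0)
        assert p == pytest.approx(mc, abs=max(3 * se, 1e-3))


class TestSThreshold:
    def test_root_and_closed_form_agree(self, s1_params):
        for x in (0.0, 1.0):
            res = s_threshold(s1_params, [x], alpha=0.05, n1x=25, n0x=25)
            cf = s_threshold_closed_form(s1_params, [x], 0.05, 25, 25)
            assert res.s_threshold == pytest.approx(cf, abs=1e-8)
            assert res.prob_at_s(res.s_threshold) == pytest.approx(0.05, abs=1e-8)

    def test_monotone_in_alpha_and_true_effect(self, s1_params):
        svals = [
            s_threshold(s1_params, [0.0], a, 25, 25).s_threshold
            for a in (0.01, 0.05, 0.1, 0.2)
        ]
        assert np.all(np.diff(svals) <= 1e-10)  # nonincreasing in alpha
        params_hi = ModelParams(**{**s1_params.__dict__, "beta_t": 2.0})
        assert (
            s_threshold(params_hi, [0.0], 0.05, 25, 25).s_threshold
            <= s_threshold(s1_params, [0.0], 0.05, 25, 25).s_threshold
        )

    def test_continuity_toward_prob_at_the_mean(self, s1_params):
        """As alpha approaches P(harm | O_S = m_S), s approaches m_S."""
        j = joint_effect_distribution(s1_params, [0.0])
        p_mean = prob_harm_given_s(s1_params, [0.0], j.mean[0], 25, 25)
        res = s_threshold(s1_params, [0.0], p_mean, 25, 25)
        assert res.s_threshold == pytest.approx(j.mean[0], abs=1e-6)

    def test_negative_association_rejected(self, s1_params):
        D = s1_params.D.copy()
        D[2, 3] = D[3, 2] = -0.5
        params = ModelParams(**{**s1_params.__dict__, "D": D})
        with pytest.raises(ValueError, match="reversed"):
            s_threshold(params, [0.0], 0.05, 25, 25)


class TestMarginalPsi:
    def test_single_level_unchanged(self):
        assert marginal_psi([(0.0, 0.8)]) == 0.8

    def test_equal_weight_average(self):
        assert marginal_psi([(0, 0.8), (1, 0.9)]) == pytest.approx(0.85)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            marginal_psi([(0, 0.8), (1, 0.9)], weights=[0.2, 0.2])
        with pytest.raises(ValueError, match="nonnegative"):
            marginal_psi([(0, 0.8), (1, 0.9)], weights=[-0.5, 1.5])
        with pytest.raises(ValueError, match="empty"):
            marginal_psi([])

    def test_sample_average_approximates_exact_integral(self, s1_params, rng):
        """Empirical Bernoulli(0.5) weights approach the exact x-average."""
        psi = {
            x: psi_sp123(joint_effect_distribution(s1_params, [x]))
            for x in (0.0, 1.0)
        }
        exact = 0.5 * psi[0.0] + 0.5 * psi[1.0]
        n = 10_000
        xs = rng.integers(0, 2, size=n)
        w1 = xs.mean()
        approx = marginal_psi([(0.0, psi[0.0]), (1.0, psi[1.0])], weights=[1 - w1, w1])
        se = abs(psi[1.0] - psi[0.0]) * 0.5 / np.sqrt(n)
        assert approx == pytest.approx(exact, abs=3 * se)
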