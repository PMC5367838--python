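"""Robustness metrics: similarity, log gain, beta_max, linearized theory."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cascade_robustness import metrics, models, relaxation
from cascade_robustness.metrics import (
    DurationApproxInvalid,
    SimilarityConfig,
    beta_max,
    check_conditions,
    consecutive_similarity,
    duration_approx,
    gain_from_coefficients,
    is_activated,
    log_gain,
    robustness_interval,
)
from cascade_robustness.models import (
    CascadeParameters,
    EffectiveParameters,
    effective_alphas,
    linearized_solution,
    steady_state_gains,
)
from cascade_robustness.relaxation import TauGrid, Trajectory


def make_traj(tau, output):
    tau = np.asarray(tau, dtype=float)
    return Trajectory(tau_grid=tau, times=10.0 ** tau,
                      output=np.asarray(output, dtype=float))


TAU = np.linspace(-2.0, 4.0 + math.log10(6.0), 600)


class TestConsecutiveSimilarity:
    def test_identical_profiles(self):
        a = make_traj(TAU, np.exp(-(10.0 ** TAU)))
        assert consecutive_similarity(a, a, 0.2) == 0.0

    def test_constant_offset_closed_form(self):
        a = make_traj(TAU, np.full_like(TAU, 0.6))
        b = make_traj(TAU, np.full_like(TAU, 0.5))
        length = TAU[-1] - TAU[0]
        expected = 0.1 * math.sqrt(length) / 0.2
        assert consecutive_similarity(a, b, 0.2) == pytest.approx(expected, rel=1e-9)
        # the literally-displayed (un-rooted) variant
        raw = consecutive_similarity(a, b, 0.2, SimilarityConfig(use_sqrt=False))
        assert raw == pytest.approx(0.01 * length / 0.2, rel=1e-9)

    def test_grid_refinement_converges(self, small_cascade):
        vals = {}
        for n in (600, 1200):
            grid = TauGrid(n=n)
            a = relaxation.simulate_relaxation("heinrich", small_cascade, grid=grid)
            p2 = small_cascade.replace(beta=small_cascade.beta * [10 ** 0.2, 1, 1])
            b = relaxation.simulate_relaxation("heinrich", p2, grid=grid)
            vals[n] = consecutive_similarity(a, b, 0.2)
        assert vals[600] == pytest.approx(vals[1200], abs=1e-4)

    def test_symmetry_and_homogeneity(self):
        rng = np.random.default_rng(3)
        out_a = rng.uniform(0, 1, TAU.size)
        out_b = rng.uniform(0, 1, TAU.size)
        a, b = make_traj(TAU, out_a), make_traj(TAU, out_b)
        assert consecutive_similarity(a, b, 0.2) == consecutive_similarity(b, a, 0.2)
        a5, b5 = make_traj(TAU, 5 * out_a), make_traj(TAU, 5 * out_b)
        assert consecutive_similarity(a5, b5, 0.2) == pytest.approx(
            5 * consecutive_similarity(a, b, 0.2)
        )

    def test_mismatched_grids_rejected(self):
        a = make_traj(TAU, np.ones_like(TAU))
        b = make_traj(TAU + 0.01, np.ones_like(TAU))
        with pytest.raises(ValueError):
            consecutive_similarity(a, b, 0.2)
        with pytest.raises(ValueError):
            consecutive_similarity(a, a, 0.0)


class TestLogGain:
    def test_inverse_proportionality(self):
        assert log_gain(lambda x: 1.0 / x, 1.0) == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("k", [-2.0, 0.5, 3.0])
    def test_power_law_exact(self, k):
        assert log_gain(lambda x: 4.2 * x ** k, 0.7) == pytest.approx(k, abs=1e-10)

    def test_flat_function(self):
        assert log_gain(lambda x: 3.3, 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            log_gain(lambda x: x - 1.0, 1.0)


class TestIsActivated:
    @pytest.mark.parametrize("g2,expected", [(0.51, True), (0.5, False), (0.25, False)])
    def test_strict_threshold(self, g2, expected):
        assert is_activated(g2) is expected


class TestBetaMax:
    def test_top_layer_closed_form(self):
        """With saturated upstream layers, g2 = 1/(1 + b2/a2) = 1/2 at b2 = a2."""
        p = CascadeParameters(alpha_bar=[1.0, 7.0, 11.0], beta=[1e-9, 1e-9, 1.0],
                              m_tot=[1.0] * 3, e0_init=1e9)
        assert beta_max(p, 2) == pytest.approx(effective_alphas(p).alpha[2], rel=1e-6)

    def test_matches_log_bisection(self, random_sets):
        """Closed-form rearrangement equals a brute-force bisection on g2."""
        for p in random_sets[:5]:
            eff = effective_alphas(p)
            for i in range(3):
                closed = beta_max(p, i)

                def g2_at(b):
                    bb = p.beta.copy()
                    bb[i] = b
                    return steady_state_gains(eff, bb).g[-1]

                if closed is None:
                    assert g2_at(1e-12) <= 0.5
                    continue
                lo, hi = closed * 1e-3, closed * 1e3
                assert g2_at(lo) > 0.5 > g2_at(hi)
                for _ in range(80):
                    mid = math.sqrt(lo * hi)
                    if g2_at(mid) > 0.5:
                        lo = mid
                    else:
                        hi = mid
                assert closed == pytest.approx(math.sqrt(lo * hi), rel=1e-6)

    def test_upstream_kinase_proportionality(self):
        """Raising alpha_k scales beta_k_max exactly proportionally, scales
        beta_i_max for i < k proportionally in the dominant term, and has
        only a negligible (order beta_k/alpha_k) effect for i > k: upstream
        shielding by fast downstream kinases."""
        from cascade_robustness.pipeline import set_param
        p = CascadeParameters(alpha_bar=[1.0, 1000.0, 1000.0],
                              beta=[1.0, 0.01, 1.0], m_tot=[1.0] * 3,
                              e0_init=1000.0)
        base_bmax = [beta_max(p, i) for i in range(3)]
        alpha1 = effective_alphas(p).alpha[1]
        boosted = set_param(p, "alpha.1", 10.0 * alpha1)
        new_bmax = [beta_max(boosted, i) for i in range(3)]
        # i = k: exact proportionality (the closed form is linear in alpha_k;
        # tolerance covers cancellation in the affine solve)
        assert new_bmax[1] == pytest.approx(10.0 * base_bmax[1], rel=1e-8)
        # i < k: proportional up to the subdominant -1 term
        assert new_bmax[0] == pytest.approx(10.0 * base_bmax[0], rel=1e-2)
        # i > k: shielded; the relative shift is of order beta_1/alpha_1
        assert new_bmax[2] == pytest.approx(base_bmax[2], rel=2e-5)

    def test_never_activated_reports_absent(self):
        # the downstream layer is too weakly driven even with no
        # dephosphorylation in the queried module
        p = CascadeParameters(alpha_bar=[1.0, 1.0, 1.0], beta=[1.0, 1.0, 10.0],
                              m_tot=[1.0] * 3, e0_init=100.0)
        assert beta_max(p, 1) is None


class TestDurationApprox:
    def test_direct_formula(self):
        lin = models.LinearizedSolution(
            rates=np.array([0.01, 1.0, 2.0]),
            terms=((0.01, np.array([1.0])), (1.0, np.array([0.0])),
                   (2.0, np.array([0.0]))),
        )
        assert duration_approx(lin) == pytest.approx(math.log(2) / 0.01)

    def test_half_coefficient_gives_zero(self):
        lin = models.LinearizedSolution(
            rates=np.array([0.5, 3.0]),
            terms=((0.5, np.array([0.5])), (3.0, np.array([0.5]))),
        )
        with pytest.raises(DurationApproxInvalid):
            duration_approx(lin)
        ok = models.LinearizedSolution(
            rates=np.array([0.5, 3.0]),
            terms=((0.5, np.array([0.5000001])), (3.0, np.array([0.4999999]))),
        )
        assert duration_approx(ok) == pytest.approx(0.0, abs=1e-6)

    def test_agrees_with_root_found_half_life(self):
        """5% agreement when the slow rate is 100x below the others."""
        p = CascadeParameters(alpha_bar=[1.0, 100.0, 100.0],
                              beta=[0.01, 1.0, 3.0], m_tot=[1.0] * 3, e0_init=100.0)
        lin = linearized_solution(effective_alphas(p), p.beta)
        theta = relaxation.half_life("linearized", p)
        assert duration_approx(lin) == pytest.approx(theta, rel=0.05)


class TestGainFromCoefficients:
    def test_two_route_consistency(self, heinrich_base):
        """The coefficient formula equals the log gain of the approximated
        duration treated as a function of beta_i."""
        eff = effective_alphas(heinrich_base)
        beta = heinrich_base.beta
        k = int(np.argmin(beta))
        for i in range(3):
            if i == k:
                continue

            def theta_of(b):
                bb = beta.copy()
                bb[i] = b
                return duration_approx(linearized_solution(eff, bb))

            # at a small common step the two finite-difference routes agree
            # to well under their own O(h^2) discretization error
            via_coeff = gain_from_coefficients(eff, beta, i, step_log10=0.002)
            via_duration = log_gain(theta_of, float(beta[i]), step_log10=0.002)
            assert via_coeff == pytest.approx(via_duration, abs=1e-6)

    def test_shielding_limit(self):
        """Fast downstream kinases drive the gain magnitude to zero."""
        beta = np.array([1.0, 0.01, 2.0])
        mags = []
        for a in (10.0, 1e3, 1e5):
            eff = EffectiveParameters(alpha=np.array([a, a, a]))
            mags.append(abs(gain_from_coefficients(eff, beta, 0)))
        # the slow-mode coefficient grows with alpha, so the prefactor
        # 1/(log 2 + log c_k) shrinks: decay is logarithmic in alpha
        assert mags[0] > mags[1] > mags[2]
        assert mags[2] < 0.05

    def test_minimum_rate_rejected(self, heinrich_base):
        k = int(np.argmin(heinrich_base.beta))
        with pytest.raises(ValueError):
            gain_from_coefficients(effective_alphas(heinrich_base),
                                   heinrich_base.beta, k)


class TestCheckConditions:
    def test_rate_limiting_flag(self):
        eff = EffectiveParameters(alpha=np.array([1000.0, 1000.0, 1000.0]))
        beta = [1.0, 0.01, 1.0]
        assert check_conditions(eff, beta, 0).rate_limiting_ok
        assert not check_conditions(eff, beta, 1).rate_limiting_ok

    def test_initial_condition_product(self):
        eff = EffectiveParameters(alpha=np.array([1000.0, 1000.0, 1000.0]))
        beta = np.array([1.0, 0.01, 1.0])
        rep = check_conditions(eff, beta, 0)
        product = (1e-3) * (1 + 0.01 / 1000.0) * (1 + 1e-3)
        assert rep.initial_condition_ok
        assert rep.initial_condition_margin == pytest.approx(1 - product, rel=1e-9)

    def test_fast_downstream_factor(self):
        eff = EffectiveParameters(alpha=np.array([1.0, 1.0, 1.0]))
        beta = [0.5, 0.5, 0.5]
        assert not check_conditions(eff, beta, 0).fast_downstream_ok
        assert check_conditions(eff, beta, 0, fast_factor=0.6).fast_downstream_ok


class TestRobustnessInterval:
    def test_constant_duration_fully_robust(self):
        v = 10.0 ** np.arange(-2.0, 2.01, 0.2)
        gains = np.zeros_like(v)
        ivs = robustness_interval(v, gains, np.ones_like(v, dtype=bool))
        assert len(ivs) == 1
        assert (ivs[0].lower, ivs[0].upper) == (pytest.approx(v.min()),
                                                pytest.approx(v.max()))

    def test_inverse_duration_never_robust(self):
        v = 10.0 ** np.arange(-2.0, 2.01, 0.2)
        gains = np.full_like(v, -1.0)  # theta ~ 1/beta
        assert robustness_interval(v, gains, np.ones_like(v, dtype=bool)) == []

    def test_deactivated_points_excluded(self):
        v = np.array([1.0, 2.0, 4.0, 8.0])
        gains = np.zeros(4)
        act = np.array([True, True, False, True])
        ivs = robustness_interval(v, gains, act)
        assert [(iv.lower, iv.upper) for iv in ivs] == [(1.0, 2.0), (8.0, 8.0)]

    def test_min_rate_crossover(self):
        v = 10.0 ** np.arange(-3.0, 3.01, 0.5)
        cross = metrics.min_rate_crossover(v, [0.07, 22.0])
        assert cross == pytest.approx(10.0 ** -1.5)
        assert metrics.min_rate_crossover(v, [1e-6]) is None


class TestGainConvergesToMinusOne:
    def test_linearized_slow_rate_limit(self):
        """As the swept rate becomes rate limiting, the half-life gain
        approaches exact inverse proportionality."""
        base = CascadeParameters(alpha_bar=[1.0, 100.0, 100.0],
                                 beta=[1e-5, 1.0, 10.0], m_tot=[1.0] * 3,
                                 e0_init=100.0)

        def theta(b):
            return relaxation.half_life("linearized", base.replace(
                beta=np.array([b, 1.0, 10.0])))

        assert log_gain(theta, 1e-5) == pytest.approx(-1.0, abs=5e-3)
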