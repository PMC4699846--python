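"""Unit and property tests for the birth-death core: target distributions,
detailed-balance rate inversion, transition matrices and exact propagation."""

import math

import numpy as np
import pytest

from synturn import (
    DeletionProfile,
    ModelParams,
    StationaryDistribution,
    deletion_rates,
    gaussian_peak,
    interpeak_minimum,
    poisson_peak,
    propagate,
    stationary_of,
    total_variation,
    transition_matrix,
    wp_mixture,
)


def direct_gaussian(mu, sigma, N):
    """Independent oracle: plain-python summation of the exponential terms."""
    terms = [math.exp(-((s - mu) ** 2) / sigma**2) for s in range(N + 1)]
    Z = sum(terms)
    return [t / Z for t in terms]


def direct_poisson(lam, N):
    terms = [lam**s / math.factorial(s) for s in range(N + 1)]
    Z = sum(terms)
    return [t / Z for t in terms]


class TestPeakDistributions:
    def test_gaussian_symmetric_about_integer_mean(self):
        p = gaussian_peak(5, 1.2, 7).p
        assert p[4] == pytest.approx(p[6], rel=1e-14)
        assert p[3] == pytest.approx(p[7], rel=1e-14)

    def test_gaussian_matches_direct_summation(self):
        p = gaussian_peak(5, 1.2, 7).p
        oracle = direct_gaussian(5, 1.2, 7)
        assert p[5] == pytest.approx(0.4705877805, abs=1e-9)
        np.testing.assert_allclose(p, oracle, rtol=1e-13)

    def test_gaussian_single_state(self):
        assert gaussian_peak(0, 1, 0).p == pytest.approx([1.0])

    def test_gaussian_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            gaussian_peak(5, 0.0, 7)

    def test_poisson_matches_direct_summation(self):
        p = poisson_peak(0.05, 5).p
        assert p[0] == pytest.approx(0.95122942, abs=1e-7)
        np.testing.assert_allclose(p, direct_poisson(0.05, 5), rtol=1e-13)

    def test_poisson_successive_ratio_is_lambda_over_s(self):
        p = poisson_peak(0.05, 5).p
        assert p[1] / p[0] == pytest.approx(0.05, rel=1e-12)

    def test_poisson_two_equal_terms(self):
        assert poisson_peak(1.0, 1).p == pytest.approx([0.5, 0.5])

    def test_poisson_decreasing_for_small_lambda(self):
        p = poisson_peak(0.5, 6).p
        assert np.all(np.diff(p) < 0)

    def test_poisson_rejects_bad_lambda(self):
        with pytest.raises(ValueError):
            poisson_peak(-1.0, 5)

    @pytest.mark.parametrize("C,which", [(0.0, "low"), (1.0, "high")])
    def test_mixture_degenerate_weights(self, C, which):
        lo, hi = poisson_peak(0.05, 7), gaussian_peak(5, 1.2, 7)
        mixed = wp_mixture(lo, hi, C)
        ref = lo if which == "low" else hi
        np.testing.assert_allclose(mixed.p, ref.p, rtol=1e-14)

    def test_mixture_value_from_direct_evaluation(self):
        lo, hi = poisson_peak(0.05, 7), gaussian_peak(5, 1.2, 7)
        p = wp_mixture(lo, hi, 0.1).p
        expect = 0.9 * direct_poisson(0.05, 7)[2] + 0.1 * direct_gaussian(5, 1.2, 7)[2]
        assert p[2] == pytest.approx(expect, rel=1e-12)
        assert p[2] == pytest.approx(0.00116098, abs=1e-7)

    def test_mixture_rejects_mismatched_support(self):
        with pytest.raises(ValueError):
            wp_mixture(poisson_peak(0.05, 5), gaussian_peak(5, 1.2, 7), 0.1)


class TestDeletionRates:
    def test_uniform_target_gives_pure_combinatorial_rates(self):
        N, b = 5, 1e-4
        p = StationaryDistribution(np.full(N + 1, 1 / (N + 1)))
        d = deletion_rates(p, ModelParams(N=N, b=b)).d
        for S in range(1, N + 1):
            assert d[S] == pytest.approx((N - S + 1) / S * b, rel=1e-13)
        assert d[5] == pytest.approx(b / 5, rel=1e-13)

    def test_detailed_balance_identity_holds_by_construction(self, rng):
        N, b = 7, 1e-6
        for _ in range(20):
            p = StationaryDistribution(rng.dirichlet(np.full(N + 1, 2.0)) * 0.999 + 0.001 / (N + 1))
            d = deletion_rates(p, ModelParams(N=N, b=b)).d
            for S in range(1, N + 1):
                lhs = p.p[S] / p.p[S - 1] * S * d[S]
                assert lhs == pytest.approx((N - S + 1) * b, rel=1e-10)

    def test_poisson_target_rates_have_closed_form(self):
        # p[S-1]/p[S] = S/lam for a Poisson shape, so d[S] = (N-S+1) b / lam
        N, b, lam = 7, 1e-8, 0.05
        d = deletion_rates(poisson_peak(lam, N), ModelParams(N=N, b=b)).d
        assert d[5] == pytest.approx(3 * b / lam, rel=1e-12)
        assert d[5] == pytest.approx(6e-7, rel=1e-12)

    def test_validity_bound_violation_names_state(self):
        # steep target at large b forces S*d[S] above 1
        p = StationaryDistribution(np.array([0.9, 0.00025, 0.0995, 0.00025]))
        with pytest.raises(ValueError, match="S = "):
            deletion_rates(p, ModelParams(N=3, b=0.3))


class TestTransitionMatrix:
    def test_two_state_chain_layout(self):
        b, d1 = 0.2, 0.4
        M = transition_matrix(ModelParams(N=1, b=b), DeletionProfile([0.0, d1])).M
        np.testing.assert_allclose(M, [[1 - b, b], [d1, 1 - d1]], rtol=1e-14)

    def test_rows_sum_to_one(self, system7):
        for cond in ("low", "wp", "high"):
            np.testing.assert_allclose(system7.matrices[cond].M.sum(axis=1), 1.0, atol=1e-13)

    def test_roundtrip_recovers_wp_target(self, system7):
        pi = stationary_of(system7.matrices["wp"])
        assert total_variation(pi.p, system7.stationary["wp"].p) < 1e-10


class TestStationary:
    def test_two_state_closed_form(self):
        b, d1 = 1e-3, 4e-3
        M = transition_matrix(ModelParams(N=1, b=b), DeletionProfile([0.0, d1]))
        pi = stationary_of(M)
        assert pi.p[1] == pytest.approx(b / (b + d1), rel=1e-10)

    def test_reducible_chain_rejected(self):
        M = transition_matrix(ModelParams(N=2, b=1e-3), DeletionProfile([0.0, 1e-3, 1e-3]))
        broken = M.M.copy()
        broken[1, 0] = 0.0
        broken[1, 1] += 1e-3
        from synturn.model_core import TransitionMatrix

        with pytest.raises(ValueError, match="reducible"):
            stationary_of(TransitionMatrix(broken))

    def test_roundtrip_on_random_strictly_positive_targets(self, rng):
        # detailed balance is exact, not approximate
        N, b = 6, 1e-7
        for _ in range(30):
            raw = rng.dirichlet(np.full(N + 1, 0.8))
            p = StationaryDistribution((raw + 1e-4) / (raw + 1e-4).sum())
            mp = ModelParams(N=N, b=b)
            pi = stationary_of(transition_matrix(mp, deletion_rates(p, mp)))
            assert total_variation(pi.p, p.p) < 1e-10


class TestPropagate:
    def test_zero_steps_is_identity(self, system7):
        p0 = np.zeros(8)
        p0[3] = 1.0
        np.testing.assert_array_equal(propagate(p0, system7.matrices["wp"], 0), p0)

    def test_stationary_is_fixed_point_at_huge_t(self, system7):
        pw = system7.stationary["wp"].p
        for t in (1, 10**6, 10**10):
            assert total_variation(propagate(pw, system7.matrices["wp"], t), pw) < 1e-10

    def test_matches_repeated_multiplication(self, fast_system):
        M = fast_system.matrices["wp"]
        p0 = np.zeros(6)
        p0[5] = 1.0
        q = p0.copy()
        for _ in range(1000):
            q = q @ M.M
        assert np.abs(propagate(p0, M, 1000) - q).max() < 1e-10

    def test_rejects_negative_time(self, system7):
        with pytest.raises(ValueError):
            propagate(system7.stationary["wp"].p, system7.matrices["wp"], -1)

    def test_conserves_normalization_and_positivity(self, system7):
        p0 = np.zeros(8)
        p0[7] = 1.0
        for t in (1, 100, 10**4, 10**8, 10**12):
            pt = propagate(p0, system7.matrices["wp"], t)
            assert pt.sum() == pytest.approx(1.0, abs=1e-12)
            assert (pt >= 0).all()

    def test_total_variation_to_stationary_never_increases(self, system7):
        M = system7.matrices["wp"]
        pw = system7.stationary["wp"].p
        p0 = np.zeros(8)
        p0[7] = 1.0
        tv = [total_variation(propagate(p0, M, t), pw) for t in np.logspace(0, 11, 45)]
        assert all(b <= a + 1e-12 for a, b in zip(tv, tv[1:]))


class TestInterpeakMinimum:
    def test_default_working_point_barrier(self, system7):
        assert interpeak_minimum(system7.stationary["wp"]) == 2

    def test_unimodal_rejected(self):
        with pytest.raises(ValueError, match="interpeak"):
            interpeak_minimum(gaussian_peak(5, 1.2, 7))

    def test_two_delta_with_floor(self):
        p = np.full(8, 1e-6)
        p[0], p[7] = 0.9, 0.1 - 6e-6
        p[3] = 1e-7  # unique interior minimum
        s = interpeak_minimum(p / p.sum())
        assert s == 3

    def test_tie_breaks_to_smallest_count(self):
        p = np.array([0.5, 0.05, 0.05, 0.4])
        assert interpeak_minimum(p / p.sum()) == 1
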