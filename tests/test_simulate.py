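"""Simulator checks: closed-form inverse CDFs against quadrature of the stated
densities, support constraints, limit relationships between the three models,
and reproducibility."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from bdgrowth.simulate import (
    BDParams,
    delta_T,
    draw_birth_death_rates,
    sample_coal_times_exact,
    sample_coal_times_fixed_n,
    sample_coal_times_large_n,
    sample_Q,
    sample_U_trunc,
    sample_Y,
)
from bdgrowth.simulate import _depths_given_y

EULER_GAMMA = 0.5772156649015329


def quadrature_cdf(density, lo, hi, grid_points=4001):
    """Numeric CDF oracle: cumulative trapezoid of a density on [lo, hi]."""
    x = np.linspace(lo, hi, grid_points)
    cum = integrate.cumulative_trapezoid(density(x), x, initial=0.0)
    cum /= cum[-1]
    return lambda t: np.interp(t, x, cum)


class TestBDParams:
    def test_growth_rate_and_invariants(self):
        p = BDParams(birth_rate=1.5, death_rate=0.5)
        assert p.growth_rate == pytest.approx(1.0)
        q = BDParams.from_growth_rate(0.5, 1.2)
        assert q.death_rate == pytest.approx(0.7)

    @pytest.mark.parametrize(
        "lam,mu", [(0.0, 0.0), (1.0, 1.0), (1.0, 2.0), (1.0, -0.1)]
    )
    def test_invalid_rates_rejected(self, lam, mu):
        with pytest.raises(ValueError):
            BDParams(birth_rate=lam, death_rate=mu)


class TestDeltaT:
    def test_boundary_values(self):
        p = BDParams.from_growth_rate(1.0, 2.0)
        assert delta_T(p, 0.0) == pytest.approx(1.0)
        assert delta_T(p, 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_pure_birth_reduces_to_exponential(self):
        # with mu = 0 (lambda = r) the expression simplifies to e^{-rT}
        p = BDParams(birth_rate=0.7)
        for T in [0.5, 2.0, 10.0]:
            assert delta_T(p, T) == pytest.approx(math.exp(-0.7 * T), rel=1e-12)

    def test_strictly_decreasing_in_T(self):
        p = BDParams.from_growth_rate(0.5, 1.3)
        values = [delta_T(p, T) for T in np.linspace(0, 20, 50)]
        assert np.all(np.diff(values) < 0)

    def test_negative_T_rejected(self):
        with pytest.raises(ValueError):
            delta_T(BDParams(1.0), -1.0)


class TestInverseCdfSamplers:
    """Each closed-form inverse CDF is checked by KS against the numeric
    (quadrature) CDF of the printed density, at three parameter settings."""

    @pytest.mark.parametrize("n,delta", [(5, 0.1), (2, 0.9), (12, 0.4)])
    def test_sample_Y_matches_density(self, rng, n, delta):
        density = lambda y: n * delta * y ** (n - 1) / (y + delta - y * delta) ** (
            n + 1
        )
        cdf = quadrature_cdf(density, 0.0, 1.0)
        draws = sample_Y(n, delta, rng, size=10**5)
        assert np.all((draws > 0) & (draws < 1))
        assert stats.kstest(draws, cdf).statistic < 0.01

    def test_sample_Y_delta_one_is_nth_root_of_uniform(self, rng):
        n = 7
        draws = sample_Y(n, 1.0, rng, size=10**5)
        assert stats.kstest(draws, lambda y: y**n).statistic < 0.01

    @pytest.mark.parametrize("n", [2, 5, 30])
    def test_sample_Q_matches_density(self, rng, n):
        # Q has a 1/q tail, so quadrature is done in the compact coordinate
        # v = q/(1+q) with Jacobian 1/(1-v)^2 and draws mapped accordingly
        density_q = lambda q: n * q ** (n - 1) / (1 + q) ** (n + 1)
        density_v = lambda v: density_q(v / (1 - v)) / (1 - v) ** 2
        cdf = quadrature_cdf(density_v, 0.0, 1.0 - 1e-9, grid_points=40001)
        draws = sample_Q(n, rng, size=10**5)
        assert np.all(draws > 0)
        assert stats.kstest(draws / (1.0 + draws), cdf).statistic < 0.01

    def test_sample_Q_closed_form_cdf(self, rng):
        draws = sample_Q(5, rng, size=10**5)
        assert stats.kstest(draws, lambda q: (q / (1 + q)) ** 5).statistic < 0.01

    @pytest.mark.parametrize("q", [0.5, 2.0, 10.0])
    def test_sample_U_trunc_matches_density(self, rng, q):
        density = lambda u: (1 + q) / q * np.exp(u) / (1 + np.exp(u)) ** 2
        cdf = quadrature_cdf(density, -math.log(q), 40.0, grid_points=40001)
        draws = sample_U_trunc(q, rng, size=10**5)
        assert np.all(draws > -math.log(q))
        assert stats.kstest(draws, cdf).statistic < 0.01

    def test_sample_U_trunc_density_normalizes(self):
        from scipy.special import expit

        q = 0.5
        # e^u/(1+e^u)^2 written stably as sigma(u) sigma(-u)
        val, _ = integrate.quad(
            lambda u: (1 + q) / q * expit(u) * expit(-u), -math.log(q), 60.0
        )
        assert val == pytest.approx(1.0, rel=1e-9)

    def test_sample_U_trunc_large_q_is_standard_logistic(self, rng):
        draws = sample_U_trunc(1e6, rng, size=10**5)
        assert stats.kstest(draws, stats.logistic.cdf).statistic < 0.01

    @pytest.mark.parametrize(
        "y,lam,r,T", [(0.3, 1.5, 1.0, 10.0), (0.9, 2.0, 0.5, 40.0), (0.05, 1.1, 1.0, 6.0)]
    )
    def test_exact_depths_match_density_quadrature(self, rng, y, lam, r, T):
        params = BDParams.from_growth_rate(r, lam)

        def density(t):
            g = y * lam + (r - y * lam) * np.exp(-r * t)
            gT = y * lam + (r - y * lam) * np.exp(-r * T)
            lead = gT / (y * lam * (1 - np.exp(-r * T)))
            return lead * y * lam * r**2 * np.exp(-r * t) / g**2

        val, _ = integrate.quad(density, 0, T)
        assert val == pytest.approx(1.0, rel=1e-8)
        cdf = quadrature_cdf(density, 0.0, T)
        draws = _depths_given_y(10**5, y, params, T, rng)
        assert stats.kstest(draws, cdf).statistic < 0.01


class TestExactSampler:
    def test_depths_in_open_interval(self, rng):
        params = BDParams.from_growth_rate(1.0, 1.5)
        for _ in range(200):
            s = sample_coal_times_exact(6, params, 3.0, rng)
            assert np.all((s.depths > 0) & (s.depths < 3.0))
            assert s.n == 6 and s.ordered and s.model == "exact_finite_T"

    def test_converges_to_fixed_n_as_T_grows(self, rng):
        # two-sample KS between the exact and the T -> infinity law of the
        # first depth should shrink (within MC noise) along T = 10, 20, 40
        params = BDParams.from_growth_rate(1.0, 1.5)
        reps = 4000
        distances = []
        for T in [10.0, 20.0, 40.0]:
            exact = np.array(
                [sample_coal_times_exact(5, params, T, rng).depths[0] for _ in range(reps)]
            )
            approx = np.array(
                [sample_coal_times_fixed_n(5, 1.0, T, rng).depths[0] for _ in range(reps)]
            )
            distances.append(stats.ks_2samp(exact, approx).statistic)
        noise = 2.0 * math.sqrt(2.0 / reps)
        assert distances[2] < 0.03
        assert distances[1] <= distances[0] + noise
        assert distances[2] <= distances[1] + noise


class TestFixedNSampler:
    def test_depths_below_T_and_count(self, rng):
        for _ in range(200):
            s = sample_coal_times_fixed_n(5, 2.0, 7.0, rng)
            assert s.depths.size == 4
            assert np.all(s.depths < 7.0)
            assert s.model == "fixed_n_limit"

    def test_pivotality_in_r_and_T(self, rng):
        # the law of r (T - H) depends only on n
        a = np.array(
            [1.0 * (40.0 - sample_coal_times_fixed_n(5, 1.0, 40.0, rng).depths[0])
             for _ in range(8000)]
        )
        b = np.array(
            [2.0 * (100.0 - sample_coal_times_fixed_n(5, 2.0, 100.0, rng).depths[0])
             for _ in range(8000)]
        )
        assert stats.ks_2samp(a, b).statistic < 0.03


class TestLargeNSampler:
    def test_mean_depth_involves_log_n_and_euler_gamma(self, rng):
        # E[T - H] = (log n + gamma)/r: -log W has mean gamma, logistic mean 0
        n, r, reps = 100, 1.0, 3000
        per_rep = np.array(
            [np.mean(40.0 - sample_coal_times_large_n(n, r, 40.0, rng).depths)
             for _ in range(reps)]
        )
        target = (math.log(n) + EULER_GAMMA) / r
        se = per_rep.std(ddof=1) / math.sqrt(reps)
        assert abs(per_rep.mean() - target) < 3 * se

    def test_conditionally_logistic_given_W(self, rng):
        # given W, depths are i.i.d. logistic with scale 1/r, so the scaled
        # within-replicate difference r (H_1 - H_2) removes the shared W and
        # must follow the difference of two standard logistics
        n, r, T = 50, 2.0, 10.0
        pivots = np.array(
            [
                r * np.subtract(*sample_coal_times_large_n(n, r, T, rng).depths[:2])
                for _ in range(4000)
            ]
        )
        ref = stats.logistic.rvs(size=8000, random_state=1) - stats.logistic.rvs(
            size=8000, random_state=2
        )
        assert stats.ks_2samp(pivots, ref).statistic < 0.04

    def test_depths_may_exceed_T(self, rng):
        depths = np.concatenate(
            [sample_coal_times_large_n(4, 0.3, 1.0, rng).depths for _ in range(300)]
        )
        assert np.any(depths < 0) and np.any(depths > 1.0)


class TestRateDraw:
    def test_growth_rate_exact_and_mu_nonnegative(self, rng):
        for r in [0.3, 1.0]:
            for _ in range(100):
                p = draw_birth_death_rates(r, rng)
                assert p.growth_rate == pytest.approx(r)
                assert p.death_rate >= 0
                assert r <= p.birth_rate <= 1 + r

    def test_birth_rate_uniform_mean(self, rng):
        draws = np.array([draw_birth_death_rates(1.0, rng).birth_rate for _ in range(20000)])
        assert draws.mean() == pytest.approx(1.5, abs=3 * draws.std() / math.sqrt(draws.size))


class TestReproducibility:
    @pytest.mark.parametrize("which", ["exact", "fixed_n", "large_n"])
    def test_identical_seed_identical_output(self, which):
        def draw(seed):
            rng = np.random.default_rng(seed)
            if which == "exact":
                return sample_coal_times_exact(
                    8, BDParams.from_growth_rate(1.0, 1.4), 12.0, rng
                ).depths
            if which == "fixed_n":
                return sample_coal_times_fixed_n(8, 1.0, 12.0, rng).depths
            return sample_coal_times_large_n(8, 1.0, 12.0, rng).depths

        assert np.array_equal(draw(7), draw(7))
        assert not np.array_equal(draw(7), draw(8))
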