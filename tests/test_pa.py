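"""Polynomial-approximate estimator: quadratic fit, sufficient stats, MAP solve."""

import math

import numpy as np
import pytest

from ppglm.basis import BasisSet, pairwise_integrals, single_integrals
from ppglm.core import PPGLMParams, WindowedFeatures, _gauss_nodes, _segment_edges
from ppglm.io import SpikePopulation
from ppglm.pa import (PolyApprox, SufficientStats, fit_pa_c, fit_poly,
                      pa_objective, select_range, select_width_cv, solve_map,
                      sufficient_stats)


def _random_pop(seed, T=2.0, n_neurons=3, rate=8.0, H=0.005):
    """Small population with spikes kept clear of the right edge so the
    untruncated pairwise integrals agree exactly with [0, T] integration."""
    rng = np.random.default_rng(seed)
    trains = [np.unique(rng.uniform(0, T - 2 * H, rng.poisson(rate * T)))
              for _ in range(n_neurons)]
    return SpikePopulation(trains, T)


def _integrate_quadratic_cif(pop, b, pa, w_flat):
    """Direct numeric integration of a2 u(t)^2 + a1 u(t) + a0 over [0, T]."""
    p = PPGLMParams.from_flat(w_flat, pop.n_neurons, b.J)
    nodes, wts, _ = _gauss_nodes(_segment_edges(pop, b), 24)
    u = WindowedFeatures(pop, b, nodes).linear_predictor(p)
    return float(np.dot(wts, pa.a2 * u ** 2 + pa.a1 * u + pa.a0))


class TestFitPoly:
    def test_exactly_recovers_a_quadratic(self):
        stub = lambda x: 0.7 * x ** 2 - 1.2 * x + 0.3
        pa = fit_poly(stub, -2.0, 3.0)
        assert (pa.a2, pa.a1, pa.a0) == pytest.approx((0.7, -1.2, 0.3), abs=1e-10)
        assert pa.max_residual < 1e-10

    def test_exp_fit_is_convex_with_small_residual(self):
        pa = fit_poly("exp", -1.0, 1.0)
        assert pa.a2 > 0
        # frozen from the dense-grid least-squares oracle on [-1, 1]
        assert pa.max_residual == pytest.approx(0.081600, abs=1e-5)
        assert pa.max_residual < 0.04 * math.exp(1.0)

    def test_taylor_limit_on_shrinking_range(self):
        pa = fit_poly("exp", -1e-4, 1e-4)
        assert (pa.a0, pa.a1, pa.a2) == pytest.approx((1.0, 1.0, 0.5), abs=1e-4)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            fit_poly("exp", 1.0, 1.0)


class TestSelectRange:
    def test_mean_centered_arithmetic(self):
        # 3 Hz mean, 4 Hz width -> [log 1, log 5]
        pop = SpikePopulation([np.linspace(0.01, 0.99, 30)], 10.0)
        x0, x1 = select_range(pop, 0, width_hz=4.0)
        assert (x0, x1) == pytest.approx((math.log(1.0), math.log(5.0)), rel=1e-12)

    def test_degenerate_percentile_range_widened(self):
        x0, x1 = select_range(mode="percentile_sim", rates=np.full(1000, 3.0))
        assert x1 - x0 == pytest.approx(0.1, rel=1e-9)
        assert 0.5 * (x0 + x1) == pytest.approx(math.log(3.0), rel=1e-9)

    def test_wider_range_increases_poly_residual(self):
        resid = [fit_poly("exp", *select_range(mode="percentile_sim",
                                               rates=np.exp(np.linspace(0, s, 500)))
                          ).max_residual for s in (1.0, 2.0, 3.0)]
        assert resid[0] < resid[1] < resid[2]

    def test_empty_target_rejected(self):
        pop = SpikePopulation([[], [0.5]], 1.0)
        with pytest.raises(ValueError, match="no spikes"):
            select_range(pop, 0)


class TestSufficientStats:
    def test_single_spike_case(self, gl3):
        pop = SpikePopulation([[0.3]], 1.0)
        st = sufficient_stats(pop, 0, gl3)
        np.testing.assert_allclose(st.M[1:, 1:], pairwise_integrals(gl3, 0.0))
        np.testing.assert_allclose(st.m[1:], single_integrals(gl3))
        assert st.m[0] == 1.0 and st.k[0] == 1.0 == st.K

    def test_matches_brute_force_all_pairs(self, gl3):
        pop = _random_pop(1, T=3.0, rate=22.0)  # ~200 spikes
        st = sufficient_stats(pop, 0, gl3)
        N, J = pop.n_neurons, gl3.J
        times, ids = pop.merged()
        M = np.zeros((N * J + 1, N * J + 1))
        M[0, 0] = pop.duration
        M[0, 1:] = M[1:, 0] = st.m[1:]
        for a in range(times.size):
            for c in range(times.size):
                d = times[a] - times[c]
                if 0 <= d <= gl3.H and (a != c or a == c):
                    if a == c:
                        P = pairwise_integrals(gl3, 0.0)
                        blk = (ids[a], ids[a])
                        M[1 + blk[0] * J:1 + blk[0] * J + J,
                          1 + blk[1] * J:1 + blk[1] * J + J] += P
                    elif d > 0 or (d == 0 and a > c):
                        P = pairwise_integrals(gl3, d)
                        r, s = ids[c], ids[a]  # older row, newer column
                        M[1 + r * J:1 + r * J + J, 1 + s * J:1 + s * J + J] += P
                        M[1 + s * J:1 + s * J + J, 1 + r * J:1 + r * J + J] += P.T
        np.testing.assert_allclose(st.M, M, rtol=1e-10, atol=1e-14)

    def test_quadratic_form_matches_numeric_integration(self, gl3):
        rng = np.random.default_rng(2)
        pa = fit_poly("exp", -1.0, 1.5)
        for seed in range(5):
            pop = _random_pop(seed)
            st = sufficient_stats(pop, 0, gl3)
            for _ in range(10):
                w = rng.normal(0, 0.5, st.k.size)
                quad_form = pa.a2 * w @ st.M @ w + pa.a1 * st.m @ w + st.T * pa.a0
                direct = _integrate_quadratic_cif(pop, gl3, pa, w)
                assert quad_form == pytest.approx(direct, rel=1e-6)

    def test_matrix_is_positive_semidefinite(self, gl3):
        for seed in range(4):
            st = sufficient_stats(_random_pop(seed), 0, gl3)
            eigs = np.linalg.eigvalsh(st.M)
            assert eigs.min() >= -1e-8 * np.trace(st.M)

    def test_isolated_spikes_give_block_diagonal(self, gl3):
        # all spikes farther apart than H: M basis part = per-spike P(0) sums
        pop = SpikePopulation([[0.1, 0.3], [0.5, 0.9]], 1.2)
        st = sufficient_stats(pop, 0, gl3)
        P0 = pairwise_integrals(gl3, 0.0)
        expected = np.zeros((6, 6))
        expected[:3, :3] = 2 * P0
        expected[3:, 3:] = 2 * P0
        np.testing.assert_allclose(st.M[1:, 1:], expected, atol=1e-15)


class TestSolveMAP:
    def _stub_stats(self, dim=5):
        rng = np.random.default_rng(0)
        k = rng.normal(size=dim)
        m = rng.normal(size=dim)
        return SufficientStats(k=k, m=m, M=np.eye(dim), K=3, T=1.0,
                               N=dim - 1, J=1)

    def test_identity_stub_elementwise(self):
        st = self._stub_stats()
        pa = PolyApprox(a0=1.0, a1=1.0, a2=0.5, x0=-1, x1=1, max_residual=0.0)
        sol = solve_map(st, pa, ridge=0.0)
        np.testing.assert_allclose(sol.flat(), (st.k - pa.a1 * st.m) / (2 * pa.a2))

    def test_gradient_vanishes_at_solution(self, gl3):
        pop = _random_pop(3)
        st = sufficient_stats(pop, 0, gl3)
        pa = fit_poly("exp", -1.0, 1.5)
        sol = solve_map(st, pa, ridge=0.0)
        g = st.k - pa.a1 * st.m - 2 * pa.a2 * (st.M @ sol.flat())
        assert np.abs(g).max() <= 1e-8 * np.linalg.norm(st.k)

    def test_concavity_guard(self):
        st = self._stub_stats()
        pa = PolyApprox(a0=1.0, a1=1.0, a2=0.0, x0=-1, x1=1, max_residual=0.0)
        with pytest.raises(ValueError):
            solve_map(st, pa, ridge=0.0)


class TestFitPAC:
    def test_cached_stats_resolve_bit_exactly(self, gl3):
        pop = _random_pop(5)
        m1 = fit_pa_c(pop, 0, gl3, ridge=0.0)
        m2 = fit_pa_c(pop, 0, gl3, ridge=100.0, stats=m1.stats)
        m3 = fit_pa_c(pop, 0, gl3, ridge=100.0, stats=m1.stats)
        np.testing.assert_array_equal(m2.params.w, m3.params.w)
        assert m2.stats is m1.stats

    def test_large_ridge_shrinks_weights_to_zero(self, gl3):
        pop = _random_pop(6)
        m1 = fit_pa_c(pop, 0, gl3, ridge=0.0)
        m2 = fit_pa_c(pop, 0, gl3, ridge=1e9, stats=m1.stats)
        assert np.abs(m2.params.w).max() < 1e-5
        assert np.abs(m2.params.w).max() < np.abs(m1.params.w).max()

    def test_objective_value_is_consistent(self, gl3):
        pop = _random_pop(7)
        m = fit_pa_c(pop, 0, gl3, ridge=1.0)
        pa = PolyApprox(a0=m.metadata["poly"][0], a1=m.metadata["poly"][1],
                        a2=m.metadata["poly"][2], x0=0, x1=1, max_residual=0)
        assert m.final_objective == pytest.approx(
            pa_objective(m.stats, pa, m.params.flat(), ridge=1.0))

    def test_width_cv_returns_candidate(self, gl3):
        pop = _random_pop(8, T=6.0, rate=10.0)
        w = select_width_cv(pop, 0, gl3, widths=(3.0, 5.0), seed=0)
        assert w in (3.0, 5.0)
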