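"""Exact likelihood pieces: linear predictor, rate, spike term, CIF oracle."""

import math

import numpy as np
import pytest

from ppglm.basis import BasisSet
from ppglm.core import (PPGLMParams, WindowedFeatures, cif_quadrature_oracle,
                        exact_negloglik, get_link, linear_predictor, rate,
                        spike_term)
from ppglm.discrete import build_design, discrete_loglik
from ppglm.io import SpikePopulation


def _params(N, J, rng=None, scale=0.3, w0=0.0):
    rng = rng or np.random.default_rng(0)
    return PPGLMParams(rng.normal(0, scale, (N, J)), w0)


class TestLinearPredictor:
    def test_empty_window_returns_intercept(self, gl3):
        pop = SpikePopulation([[0.5]], 1.0)
        p = _params(1, 3, w0=1.7)
        assert linear_predictor(pop, p, gl3, 0.1) == 1.7

    def test_single_spike_unit_weight_gives_basis_value(self, gl3):
        pop = SpikePopulation([[0.5]], 1.0)
        for j in range(3):
            w = np.zeros((1, 3))
            w[0, j] = 1.0
            p = PPGLMParams(w, 0.25)
            tau = 1.3e-3
            expected = 0.25 + gl3.evaluate([tau])[0, j]
            assert linear_predictor(pop, p, gl3, 0.5 + tau) == pytest.approx(
                expected, rel=1e-12)

    def test_window_is_half_open(self, gl3):
        # a spike exactly at t does not drive the rate at t; one just inside
        # the trailing edge of the window still does
        pop = SpikePopulation([[0.5]], 1.0)
        p = PPGLMParams(np.ones((1, 3)), 0.0)
        assert linear_predictor(pop, p, gl3, 0.5) == 0.0
        lag = gl3.H - 1e-7
        assert linear_predictor(pop, p, gl3, 0.5 + lag) == pytest.approx(
            gl3.evaluate([lag])[0].sum(), rel=1e-9)

    def test_matches_brute_force_sum(self, small_pop, gl3):
        rng = np.random.default_rng(3)
        p = _params(small_pop.n_neurons, 3, rng)
        ts = rng.uniform(0, small_pop.duration, 100)
        u = linear_predictor(small_pop, p, gl3, ts)
        for t, u_t in zip(ts, u):
            acc = p.w0
            for n, train in enumerate(small_pop.spike_times):
                for s in train:
                    if t - gl3.H <= s < t:
                        acc += p.w[n] @ gl3.evaluate([t - s])[0]
            assert u_t == pytest.approx(acc, rel=1e-10, abs=1e-12)


class TestRate:
    def test_exp_baseline(self, gl3):
        pop = SpikePopulation([[0.9]], 1.0)
        p = _params(1, 3, w0=math.log(3.0))
        assert rate(pop, p, gl3, 0.1) == pytest.approx(3.0, rel=1e-12)

    def test_softplus_at_zero(self, gl3):
        pop = SpikePopulation([[0.9]], 1.0)
        p = PPGLMParams(np.zeros((1, 3)), 0.0, link="softplus")
        assert rate(pop, p, gl3, 0.1) == pytest.approx(math.log(2.0), rel=1e-12)

    def test_is_link_of_linear_predictor(self, small_pop, gl3):
        rng = np.random.default_rng(4)
        p = _params(3, 3, rng)
        ts = rng.uniform(0, small_pop.duration, 20)
        lam = rate(small_pop, p, gl3, ts)
        u = linear_predictor(small_pop, p, gl3, ts)
        np.testing.assert_allclose(lam, np.exp(u), rtol=1e-12)

    def test_overflow_cap_warns(self, gl3):
        pop = SpikePopulation([[0.9]], 1.0)
        p = _params(1, 3, w0=50.0)
        with pytest.warns(UserWarning, match="capped"):
            assert rate(pop, p, gl3, 0.1) == pytest.approx(math.exp(30.0))


class TestSpikeTerm:
    def test_no_target_spikes(self, small_pop, gl3):
        assert spike_term(small_pop, [], _params(3, 3), gl3) == 0.0

    def test_single_spike_empty_history_zero_intercept(self, gl3):
        pop = SpikePopulation([[0.5]], 1.0)
        p = _params(1, 3, w0=0.0)
        assert spike_term(pop, [0.5], p, gl3) == 0.0  # log 1

    def test_matches_feature_inner_product(self, small_pop, gl3):
        # two independent code paths: summed u vs k-vector dot weights
        rng = np.random.default_rng(5)
        p = _params(3, 3, rng, w0=0.4)
        y = small_pop.spike_times[0]
        direct = spike_term(small_pop, y, p, gl3)
        kvec = WindowedFeatures(small_pop, gl3, y).weighted_feature_sum(
            np.ones(y.size))
        assert direct == pytest.approx(kvec @ p.flat(), abs=1e-10)


class TestCIFOracle:
    def test_constant_rate(self, gl3):
        pop = SpikePopulation([[0.5]], 2.0)
        p = PPGLMParams(np.zeros((1, 3)), math.log(4.0))
        assert cif_quadrature_oracle(pop, p, gl3) == pytest.approx(8.0, rel=1e-10)

    def test_single_spike_closed_form(self, gl3):
        # one presyn spike, w = e_j, w0 = 0: integral = (T - H) + int exp(phi_j)
        from scipy.integrate import quad

        pop = SpikePopulation([[0.5]], 2.0)
        for j in range(3):
            w = np.zeros((1, 3))
            w[0, j] = 1.0
            p = PPGLMParams(w, 0.0)
            bump, _ = quad(lambda tau: math.exp(gl3.evaluate([tau])[0, j]),
                           0, gl3.H, epsabs=1e-12)
            expected = (2.0 - gl3.H) + bump
            assert cif_quadrature_oracle(pop, p, gl3) == pytest.approx(
                expected, rel=1e-9)

    def test_gradient_matches_finite_differences(self, small_pop, gl3):
        rng = np.random.default_rng(6)
        p = _params(3, 3, rng, w0=0.5)
        _, g = exact_negloglik(small_pop, 0, p, gl3, grad=True)
        x = p.flat()
        eps = 1e-6
        for i in (0, 1, 5, 9):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            fd = (exact_negloglik(small_pop, 0,
                                  PPGLMParams.from_flat(xp, 3, 3), gl3)
                  - exact_negloglik(small_pop, 0,
                                    PPGLMParams.from_flat(xm, 3, 3), gl3)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestDiscreteContinuousConsistency:
    def test_binned_loglik_converges_to_continuous(self, gl3):
        """Eq.-by-eq consistency: the binned objective approaches the exact
        continuous log-likelihood monotonically as the bin size shrinks."""
        rng = np.random.default_rng(9)
        T = 5.0
        pop = SpikePopulation(
            [np.sort(rng.uniform(0.05, T - 0.05, rng.poisson(8 * T)))
             for _ in range(2)], T)
        p = _params(2, 3, rng, w0=math.log(6.0))
        target = 0
        y = pop.spike_times[target]
        cont = spike_term(pop, y, p, gl3) - cif_quadrature_oracle(pop, p, gl3)
        gaps = []
        for d_ms in (1.0, 0.5, 0.1, 0.05):
            delta = d_ms * 1e-3
            d = build_design(pop, target, gl3, delta)
            w = np.r_[p.w0 + math.log(delta), p.w.ravel()]
            # remove the K*log(delta) offset of the per-bin rate convention
            disc = discrete_loglik(d, w) - y.size * math.log(delta)
            gaps.append(abs(disc - cont))
        assert all(a > b for a, b in zip(gaps, gaps[1:]))


class TestParamsAndLinks:
    def test_flat_round_trip(self):
        p = _params(4, 3, w0=0.7)
        q = PPGLMParams.from_flat(p.flat(), 4, 3)
        np.testing.assert_array_equal(p.w, q.w)
        assert p.w0 == q.w0

    def test_unknown_link_rejected(self):
        with pytest.raises(ValueError):
            get_link("identity")

    def test_softplus_inverse(self):
        sp = get_link("softplus")
        for r in (0.1, 1.0, 40.0):
            assert sp.forward(sp.inverse(r)) == pytest.approx(r, rel=1e-9)
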