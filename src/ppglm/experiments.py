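"""Canonical validation experiments.

Each function runs one self-contained study — integral accuracy, Monte
Carlo calibration, polynomial-approximation algebra, discretization
consistency, filter recovery, stochastic-gradient variance, connectivity
screening — from scratch on simulated data and returns its summary metrics
as a plain dict.  They are used by the test suite and by the repository's
reproduction script; problem sizes are chosen so the full battery runs in
a few minutes on one CPU (the methods note records the sizes).
"""

from __future__ import annotations

import math

import numpy as np

from .basis import BasisSet, pairwise_integrals_batch, single_integrals, \
    _pairwise_quad_ms
from .core import PPGLMParams, cif_quadrature_oracle, fit_reference
from .discrete import (build_design, discrete_sufficient_stats,
                       fit_discrete_full, gradient_error_db)
from .evaluation import filter_grid, filters_from_model, screen_connections
from .io import SpikePopulation
from .mc import (MCFitConfig, cif_mc_estimate, draw_stratified, draw_uniform,
                 fit_hybrid, fit_mc, gradient_error)
from .pa import fit_poly, sufficient_stats, solve_map
from .simulate import make_filters, simulate_all_to_one

__all__ = [
    "basis_integral_accuracy",
    "mc_calibration",
    "pa_algebra",
    "discretization_consistency",
    "recovery_protocol",
    "gradient_variance",
    "screening_check",
]

MS = 1e3


def basis_integral_accuracy(J_max: int = 7, n_deltas: int = 50) -> dict:
    """Closed-form GL integrals vs adaptive quadrature, millisecond units.

    Covers single integrals for J <= J_max and the pairwise matrix on a
    grid of lag differences spanning [-H, H].
    """
    b = BasisSet(J=J_max, H=0.005)
    single_err = float(np.abs(single_integrals(b) - single_integrals(
        b, quadrature=True)).max() * MS)
    deltas = np.linspace(-b.H, b.H, n_deltas)
    P = pairwise_integrals_batch(b, deltas)
    pair_err = 0.0
    for i, d in enumerate(deltas):
        Q = _pairwise_quad_ms(b, abs(d) * MS) / MS
        if d < 0:
            Q = Q.T
        pair_err = max(pair_err, float(np.abs(P[i] - Q).max() * MS))
    return {"single_max_abs_err": single_err, "pairwise_max_abs_err": pair_err,
            "max_abs_err": max(single_err, pair_err)}


def _hundred_spike_instance():
    """~100 spikes concentrated in the first half: strong stratum-scale
    rate structure, the regime where stratification pays off."""
    T = 0.4
    train = np.arange(0.001, T / 2, 0.002)
    pop = SpikePopulation([train], T)
    params = PPGLMParams(np.full((1, 3), 0.4), math.log(3.0))
    return pop, params


def mc_calibration(seed: int = 0, n_resamples: int = 10_000, M: int = 16) -> dict:
    """Unbiasedness (z-score vs the quadrature oracle) and the
    stratified/uniform variance ratio at equal sample count."""
    b = BasisSet(J=3)
    pop, params = _hundred_spike_instance()
    oracle = cif_quadrature_oracle(pop, params, b)
    rng = np.random.default_rng(seed)
    strat = np.array([cif_mc_estimate(pop, params, b,
                                      draw_stratified(M, pop.duration, rng))
                      for _ in range(n_resamples)])
    unif = np.array([cif_mc_estimate(pop, params, b,
                                     draw_uniform(M, pop.duration, rng))
                     for _ in range(n_resamples)])
    se = strat.std(ddof=1) / math.sqrt(n_resamples)
    return {
        "n_spikes": pop.n_spikes,
        "oracle": oracle,
        "z": float((strat.mean() - oracle) / se),
        "var_stratified": float(strat.var(ddof=1)),
        "var_uniform": float(unif.var(ddof=1)),
        "var_ratio": float(strat.var(ddof=1) / unif.var(ddof=1)),
    }


def pa_algebra(seed: int = 0, n_pops: int = 5, n_draws: int = 10) -> dict:
    """Quadratic-form identity and closed-form-solve optimality.

    Checks that a2 w'Mw + a1 m'w + T a0 equals direct numeric integration
    of the quadratic surrogate CIF, and that the MAP solution zeroes the
    surrogate gradient.
    """
    from .core import WindowedFeatures, _gauss_nodes, _segment_edges

    b = BasisSet(J=3)
    pa = fit_poly("exp", -1.0, 1.5)
    rng = np.random.default_rng(seed)
    max_rel = 0.0
    max_grad_ratio = 0.0
    for p_seed in range(n_pops):
        prng = np.random.default_rng(seed * 1000 + p_seed)
        T = 2.0
        pop = SpikePopulation(
            [np.unique(prng.uniform(0, T - 2 * b.H, prng.poisson(8 * T)))
             for _ in range(3)], T)
        st = sufficient_stats(pop, 0, b)
        nodes, wts, _ = _gauss_nodes(_segment_edges(pop, b), 24)
        wf = WindowedFeatures(pop, b, nodes)
        for _ in range(n_draws):
            w = rng.normal(0, 0.5, st.k.size)
            qf = pa.a2 * w @ st.M @ w + pa.a1 * st.m @ w + st.T * pa.a0
            u = wf.linear_predictor(PPGLMParams.from_flat(w, 3, b.J))
            direct = float(np.dot(wts, pa.a2 * u ** 2 + pa.a1 * u + pa.a0))
            max_rel = max(max_rel, abs(qf - direct) / abs(direct))
        sol = solve_map(st, pa, ridge=0.0)
        g = st.k - pa.a1 * st.m - 2 * pa.a2 * (st.M @ sol.flat())
        max_grad_ratio = max(max_grad_ratio,
                             float(np.abs(g).max() / np.linalg.norm(st.k)))
    return {"quadform_max_rel_err": float(max_rel),
            "solve_grad_ratio": max_grad_ratio}


def discretization_consistency(seed: int = 0, T: float = 50.0) -> dict:
    """Binned fits approach the continuous fit as the bin shrinks; binned
    sufficient statistics at 0.01 ms match the continuous ones."""
    pop, _ = simulate_all_to_one(n_pre=2, T=T, seed=seed)
    b = BasisSet(J=3)
    tgt = 2
    ridge = 1.0  # keeps both MLEs well-posed on this small instance
    ref = fit_reference(pop, tgt, b, ridge=ridge)
    grid = filter_grid(b.H)
    fref = filters_from_model(ref, b, grid)
    gaps = {}
    for d_ms in (1.0, 0.5, 0.1):
        d = build_design(pop, tgt, b, d_ms * 1e-3)
        m = fit_discrete_full(d, ridge=ridge)
        gaps[d_ms] = float(np.abs(filters_from_model(m, b, grid) - fref).max())
    st = sufficient_stats(pop, tgt, b)
    dd = build_design(pop, tgt, b, 1e-5)
    Sx, _, Sxx = discrete_sufficient_stats(dd)
    rel_m = float(np.linalg.norm(dd.delta * Sx - st.m) / np.linalg.norm(st.m))
    rel_M = float(np.linalg.norm(dd.delta * Sxx - st.M) / np.linalg.norm(st.M))
    return {"filter_gap_1ms": gaps[1.0], "filter_gap_0p5ms": gaps[0.5],
            "filter_gap_0p1ms": gaps[0.1],
            "monotone": gaps[1.0] > gaps[0.5] > gaps[0.1],
            "pa_stats_rel_err_m": rel_m, "pa_stats_rel_err_M": rel_M}


def recovery_protocol(seed: int = 0, n_iter: int = 2000) -> dict:
    """Filter recovery on the 8-neuron all-to-one benchmark.

    Fits the stochastic MC estimator at T = 10 s and T = 1000 s (3 Hz
    target baseline, GL J=3) and measures filter MSE against the ground
    truth; also compares warm-started (hybrid) and cold-started
    convergence on the T = 1000 s instance via the iteration at which each
    validation trace first reaches the cold fit's final objective (within
    1% of its total descent).
    """
    from .benchmark import recovery_mse

    b = BasisSet(J=3)
    out = {}
    for T in (10.0, 1000.0):
        pop, truth = simulate_all_to_one(T=T, seed=seed)
        tgt = pop.n_neurons - 1
        cfg = MCFitConfig(seed=seed + 1, n_iter=n_iter)
        cold = fit_mc(pop, tgt, b, cfg)
        out[f"mse_T{int(T)}"] = recovery_mse(cold, truth, b, tgt)
        if T == 1000.0:
            rates = truth.rate_trace(pop, tgt)
            hyb = fit_hybrid(pop, tgt, b, cfg, range_mode="percentile_sim",
                             rates=rates, pa_ridge=0.0)
            ct, co = cold.metadata["trace_iter"], cold.metadata["trace_objective"]
            ht, ho = hyb.metadata["trace_iter"], hyb.metadata["trace_objective"]
            thresh = co[-1] + 0.01 * abs(co[-1] - co[0])
            out["cold_iters_to_converge"] = next(
                i for i, v in zip(ct, co) if v <= thresh)
            out["hybrid_iters_to_converge"] = next(
                (i for i, v in zip(ht, ho) if v <= thresh), n_iter)
            out["cold_final_objective"] = co[-1]
            out["hybrid_final_objective"] = ho[-1]
    return out


def gradient_variance(seed: int = 0, T: float = 100.0, budget: int = 10_000,
                      n_resamples: int = 100) -> dict:
    """Normalized gradient error of stratified MC vs the mini-batched
    discrete GLM at a matched stochasticity budget (sample points = batch
    bins), at an early and a late optimization checkpoint."""
    pop, _ = simulate_all_to_one(T=T, seed=seed)
    b = BasisSet(J=3)
    tgt = pop.n_neurons - 1
    N, J = pop.n_neurons, b.J
    fitted = fit_mc(pop, tgt, b, MCFitConfig(seed=seed + 2, n_iter=600))
    w_init = np.zeros(N * J + 1)
    w_init[0] = math.log(pop.spike_times[tgt].size / T)
    checkpoints = [PPGLMParams.from_flat(w_init, N, J), fitted.params]

    errs_mc = gradient_error(pop, tgt, b, checkpoints, M=budget,
                             n_resamples=n_resamples, seed=seed + 3)
    delta = 1e-4
    d = build_design(pop, tgt, b, delta)
    trace = [np.r_[p.w0 + math.log(delta), p.w.ravel()] for p in checkpoints]
    errs_db = gradient_error_db(d, trace, batch_bins=budget,
                                n_resamples=n_resamples, seed=seed + 4)
    return {"mc_err_early": float(errs_mc[0]), "mc_err_late": float(errs_mc[1]),
            "db_err_early": float(errs_db[0]), "db_err_late": float(errs_db[1]),
            "ratio_early": float(errs_db[0] / errs_mc[0]),
            "ratio_late": float(errs_db[1] / errs_mc[1])}


def screening_check(seed: int = 0) -> dict:
    """Screening-rule fidelity on planted filters plus the region-block
    pair-count arithmetic for a (62, 28, 16)-neuron CA1/CA3/DG layout."""
    rc, coef = make_filters(14, seed=seed, p_positive=1.0)
    grid = filter_grid(rc.H)
    vals = coef @ rc.evaluate(grid).T
    peaks_ms = grid[vals.argmax(axis=1)] * MS
    in_window = (peaks_ms >= 0.3) & (peaks_ms <= 2.5)
    N = 6
    filt = np.zeros((N, N, grid.size))
    planted, k = set(), 0
    for i in range(N):
        for j in range(N):
            if i != j and k < coef.shape[0]:
                filt[i, j] = vals[k]
                if in_window[k]:
                    planted.add((i, j))
                k += 1
    rep = screen_connections(filt, grid, ["A"] * N, amp_threshold=0.2)
    flagged = {(int(r.pre), int(r.post))
               for _, r in rep.pairs[rep.pairs.putative_e].iterrows()}
    recall = len(flagged & planted) / max(len(planted), 1)
    fp = len(flagged - planted)

    sizes = {"CA1": 62, "CA3": 28, "DG": 16}
    regions = sum(([r] * n for r, n in sizes.items()), [])
    n_tot = sum(sizes.values())
    rep2 = screen_connections(np.zeros((n_tot, n_tot, 11)),
                              np.linspace(0, rc.H, 11), regions,
                              amp_threshold=0.1)
    blocks = rep2.blocks.set_index("Block")["Pairs Total"].to_dict()
    return {"recall": recall, "false_positives": fp,
            "n_planted": len(planted), "pair_counts": blocks}
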