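"""Continuous-time polynomial-approximate estimator (PA-c).

The exponential nonlinearity is replaced over a working range
``[x0, x1]`` of the linear predictor by the least-squares quadratic
``a2 x^2 + a1 x + a0``, which turns the CIF into an exact quadratic form

    int_0^T lambda dt  ~=  a2 w^T M w + a1 m^T w + T a0

in the (intercept-augmented) weights.  The sufficient statistics are

* ``m`` — per-neuron spike counts times the single basis integrals
  (intercept slot: T),
* ``M`` — a symmetric block matrix accumulating pairwise basis-product
  integrals over all spike pairs closer than the history window H
  (intercept row/column: the cross terms and T in the corner),
* ``k`` — the exact spike-term features (intercept slot: the target
  spike count K).

Maximizing ``w^T k - a1 m^T w - a2 w^T M w - ridge ||w||^2`` is a single
symmetric positive-definite solve, so the whole fit costs one sweep over
the in-window spike pairs regardless of recording duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .basis import pairwise_integrals, pairwise_integrals_batch, single_integrals
from .core import PPGLMParams, WindowedFeatures, get_link
from .io import FittedModel

__all__ = [
    "PolyApprox",
    "SufficientStats",
    "fit_poly",
    "select_range",
    "sufficient_stats",
    "solve_map",
    "fit_pa_c",
    "select_width_cv",
]

MIN_RANGE_WIDTH = 0.1  # widen degenerate approximation ranges to this (log-rate units)


@dataclass
class PolyApprox:
    """Quadratic surrogate ``a2 x^2 + a1 x + a0`` for a nonlinearity on [x0, x1]."""

    a0: float
    a1: float
    a2: float
    x0: float
    x1: float
    max_residual: float
    link: str = "exp"

    def __call__(self, x):
        return self.a2 * np.square(x) + self.a1 * np.asarray(x) + self.a0


def fit_poly(link, x0: float, x1: float, n_grid: int = 10_000) -> PolyApprox:
    """Least-squares degree-2 fit of the nonlinearity on a dense uniform grid.

    ``link`` is a link name or a callable (test stubs).  For any
    nondegenerate range the exp fit has ``a2 > 0`` (convexity preserved).
    """
    if not x0 < x1:
        raise ValueError("require x0 < x1")
    if callable(link):
        fwd, name = link, getattr(link, "__name__", "custom")
    else:
        nl = get_link(link)
        fwd, name = nl.forward, nl.name
    xs = np.linspace(x0, x1, n_grid)
    ys = fwd(xs)
    a0, a1, a2 = np.polynomial.polynomial.polyfit(xs, ys, 2)
    resid = float(np.max(np.abs(a2 * xs ** 2 + a1 * xs + a0 - ys)))
    return PolyApprox(a0=float(a0), a1=float(a1), a2=float(a2),
                      x0=x0, x1=x1, max_residual=resid, link=name)


def select_range(pop=None, target: int | None = None, mode: str = "mean_centered",
                 width_hz: float = 5.0, rates=None, link: str = "exp",
                 eps_hz: float = 0.01):
    """Choose the approximation range on the linear-predictor scale.

    ``mean_centered`` (data mode) spans ``width_hz`` around the mean rate
    K/T, floored at ``eps_hz``; ``percentile_sim`` (simulation mode) takes
    the 2.5th-97.5th percentiles of a supplied rate trace, mapped through
    the inverse link.  Degenerate ranges are widened symmetrically to
    ``MIN_RANGE_WIDTH``.
    """
    inv = get_link(link).inverse
    if mode == "mean_centered":
        if pop is None or target is None:
            raise ValueError("mean_centered mode needs pop and target")
        K = pop.spike_times[target].size
        if K == 0:
            raise ValueError("target has no spikes: mean rate undefined")
        rbar = K / pop.duration
        x0 = float(inv(max(rbar - width_hz / 2.0, eps_hz)))
        x1 = float(inv(rbar + width_hz / 2.0))
    elif mode == "percentile_sim":
        if rates is None:
            raise ValueError("percentile_sim mode needs a rate trace")
        rates = np.clip(np.asarray(rates, dtype=float), eps_hz, None)
        lo, hi = np.percentile(rates, [2.5, 97.5])
        x0, x1 = float(inv(lo)), float(inv(hi))
    else:
        raise ValueError(f"unknown range mode {mode!r}")
    if x1 - x0 < MIN_RANGE_WIDTH:
        mid = 0.5 * (x0 + x1)
        x0, x1 = mid - MIN_RANGE_WIDTH / 2.0, mid + MIN_RANGE_WIDTH / 2.0
    return x0, x1


@dataclass
class SufficientStats:
    """The (k, m, M) summaries from which the closed-form solve proceeds.

    Flat layout matches :meth:`PPGLMParams.flat`: index 0 is the intercept,
    then N blocks of J basis weights.
    """

    k: np.ndarray
    m: np.ndarray
    M: np.ndarray
    K: int
    T: float
    N: int | None = None
    J: int | None = None

    def __post_init__(self):
        d = self.k.size
        if self.m.size != d or self.M.shape != (d, d):
            raise ValueError("inconsistent sufficient-statistic dimensions")
        if self.N is None:
            self.N, self.J = d - 1, 1


def sufficient_stats(pop, target: int, b) -> SufficientStats:
    """Accumulate k, m and M for one target by a sweep over in-window pairs.

    Pair enumeration is a two-pointer sweep over the globally time-sorted
    spikes: each unordered pair with time difference ``0 <= d <= H``
    contributes the pairwise integral ``P(d)`` to the (older, newer) block
    and its transpose to the mirrored block; same-spike pairs contribute
    the Gram matrix ``P(0)`` once.  Cost is linear in the number of
    in-window pairs, independent of duration.
    """
    N, J = pop.n_neurons, b.J
    T = float(pop.duration)
    y = pop.spike_times[target]
    K = int(y.size)
    dim = N * J + 1

    phibar = single_integrals(b)
    Sn = pop.counts().astype(float)

    m = np.empty(dim)
    m[0] = T
    m[1:] = (Sn[:, None] * phibar[None, :]).ravel()

    kvec = WindowedFeatures(pop, b, y).weighted_feature_sum(np.ones(K))
    # intercept slot of k is exactly K by construction of the feature vector

    times, ids = pop.merged()
    blocks = np.zeros((N, N, J, J))
    # same-spike diagonal pairs, once each
    P0 = pairwise_integrals(b, 0.0)
    for n in range(N):
        blocks[n, n] += Sn[n] * P0
    # distinct pairs with 0 <= d <= H
    lo = np.searchsorted(times, times - b.H, side="left")
    counts = np.arange(times.size) - lo
    newer = np.repeat(np.arange(times.size), counts)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    older = np.arange(int(counts.sum())) - np.repeat(offsets[:-1], counts) + np.repeat(lo, counts)
    if newer.size:
        deltas = times[newer] - times[older]
        P = pairwise_integrals_batch(b, deltas)
        n_old, n_new = ids[older], ids[newer]
        np.add.at(blocks, (n_old, n_new), P)
        np.add.at(blocks, (n_new, n_old), np.transpose(P, (0, 2, 1)))

    M = np.empty((dim, dim))
    M[0, 0] = T
    M[0, 1:] = M[1:, 0] = m[1:]
    M[1:, 1:] = blocks.transpose(0, 2, 1, 3).reshape(N * J, N * J)
    return SufficientStats(k=kvec, m=m, M=M, K=K, T=T, N=N, J=J)


def solve_map(stats: SufficientStats, pa: PolyApprox, ridge: float = 0.0) -> PPGLMParams:
    """Closed-form maximizer of the quadratic surrogate objective.

    Solves ``(2 a2 M + 2 ridge I_noint) w = k - a1 m`` by a symmetric
    positive-definite solve; the ridge identity has a zero in the intercept
    slot so the baseline rate is never shrunk.
    """
    if pa.a2 <= 0 and ridge <= 0:
        raise ValueError("need a2 > 0 or ridge > 0 for a strictly concave objective")
    dim = stats.k.size
    A = 2.0 * pa.a2 * stats.M
    if ridge:
        A = A + 2.0 * ridge * np.diag(np.r_[0.0, np.ones(dim - 1)])
    rhs = stats.k - pa.a1 * stats.m
    try:
        sol = linalg.solve(A, rhs, assume_a="pos")
    except linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular PA system (rank-deficient sufficient statistics); "
            "try ridge > 0"
        ) from e
    return PPGLMParams.from_flat(sol, stats.N, stats.J)


def pa_objective(stats: SufficientStats, pa: PolyApprox, w_flat, ridge: float = 0.0) -> float:
    """Negative quadratic surrogate loss: a2 wMw + a1 mw + T a0 - k.w (+ridge)."""
    w = np.asarray(w_flat, dtype=float)
    cif = pa.a2 * w @ stats.M @ w + pa.a1 * stats.m @ w + stats.T * pa.a0
    pen = ridge * float(np.sum(w[1:] ** 2))
    return float(cif - stats.k @ w + pen)


def fit_pa_c(pop, target: int, b, range_mode: str = "mean_centered",
             width_hz: float = 5.0, rates=None, ridge: float = 0.0,
             stats: SufficientStats | None = None) -> FittedModel:
    """Full PA-c pipeline: range selection, quadratic fit, stats, MAP solve.

    Pass a precomputed ``stats`` object to re-solve at a different ridge
    without recomputing the sweep; the stats used are attached to the
    returned model as ``model.stats``.
    """
    x0, x1 = select_range(pop, target, mode=range_mode, width_hz=width_hz, rates=rates)
    pa = fit_poly("exp", x0, x1)
    if stats is None:
        stats = sufficient_stats(pop, target, b)
    params = solve_map(stats, pa, ridge=ridge)
    model = FittedModel(
        params=params, estimator="pa-c", basis=b.descriptor(), target=target,
        final_objective=pa_objective(stats, pa, params.flat(), ridge=ridge),
        metadata={"range": [x0, x1], "poly": [pa.a0, pa.a1, pa.a2],
                  "poly_max_residual": pa.max_residual, "ridge": ridge,
                  "range_mode": range_mode, "width_hz": width_hz},
    )
    model.stats = stats
    return model


def select_width_cv(pop, target: int, b, widths=(3.0, 4.0, 5.0, 6.0, 7.0),
                    train_frac: float = 0.8, ridge: float = 0.0, seed: int = 0,
                    val_M: int | None = None) -> float:
    """Pick the approximation width by held-out likelihood on a time split.

    Fits PA-c on the first ``train_frac`` of the recording for each
    candidate width and scores the stratified-MC-estimated log-likelihood
    on the remainder (common random numbers across widths).
    """
    from .mc import draw_stratified, mc_objective

    t_split = train_frac * pop.duration
    train = pop.time_slice(0.0, t_split)
    test = pop.time_slice(t_split, pop.duration)
    rng = np.random.default_rng(seed)
    sample = draw_stratified(val_M or int(np.ceil(100 * test.duration)),
                             test.duration, rng)
    best_w, best_obj = None, np.inf
    stats = sufficient_stats(train, target, b)
    for w_hz in widths:
        model = fit_pa_c(train, target, b, width_hz=w_hz, ridge=ridge, stats=stats)
        obj = mc_objective(test, test.spike_times[target], model.params, b, sample)
        if obj < best_obj:
            best_w, best_obj = w_hz, obj
    return best_w
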