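"""Binned-GLM baselines: full-gradient fit, mini-batch SGD, and discrete PA.

These implement the conventional discrete-time Poisson GLM,

    log p(y | X, w) = sum_t [ y_t log Phi(x_t^T w) - Phi(x_t^T w) ],

on a design of basis-convolved spike counts at bin size ``Delta``.  Bins are
0-based and half-open ``[t*Delta, (t+1)*Delta)``; basis features are
evaluated at bin-center lags, which is exactly the discretization error the
continuous estimators avoid, so it is deliberately not corrected.

The rate per bin is ``exp(x_t^T w)`` with the ``Delta`` scaling absorbed by
the intercept; fitted models are returned with the intercept converted back
to the continuous convention (log events/second) so filters and baselines
are directly comparable across estimators.  The design is never fully
materialized: rows are stored only for "active" bins (those with at least
one presynaptic spike in the history window); the remaining bins are
intercept-only and handled in closed form.

``fit_discrete_batched`` is a plain mini-batch stochastic-gradient
comparator (not a variance-reduced optimizer): its purpose is to exhibit
the gradient-noise behaviour of batched discrete GLMs at submillisecond
resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import PPGLMParams, WindowedFeatures
from .io import FittedModel
from .pa import PolyApprox, fit_poly

__all__ = [
    "BinnedDesign",
    "build_design",
    "discrete_loglik",
    "discrete_gradient",
    "fit_discrete_full",
    "fit_discrete_batched",
    "fit_pa_d",
    "discrete_sufficient_stats",
    "gradient_error_db",
]


@dataclass
class BinnedDesign:
    """Sparse-row representation of the binned design for one target."""

    delta: float
    n_bins: int
    N: int
    J: int
    y_active: np.ndarray         # target counts at active bins
    active_bins: np.ndarray      # indices of bins with nonzero basis features
    X_active: np.ndarray         # (n_active, N*J+1) rows incl. intercept column
    n_inactive: int
    y_inactive_sum: int          # target spikes falling in intercept-only bins
    inactive_y_bins: np.ndarray  # sorted intercept-only bins with y > 0 (rare)
    inactive_y_counts: np.ndarray
    K: int
    T: float
    basis: dict = field(default_factory=dict)
    target: int | None = None

    @property
    def dim(self) -> int:
        return self.N * self.J + 1

    def memory_bytes(self) -> int:
        return self.X_active.nbytes


def build_design(pop, target: int, b, delta: float,
                 memory_cap_bytes: int = 2 * 1024 ** 3) -> BinnedDesign:
    """Bin the recording at ``delta`` seconds and build active design rows.

    Refuses (with the printed estimate) if the projected active-row storage
    exceeds ``memory_cap_bytes``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    T = pop.duration
    n_bins = int(math.ceil(T / delta))
    dim = pop.n_neurons * b.J + 1
    times, _ = pop.merged()
    est_active = min(n_bins, int(times.size * (b.H / delta + 2)))
    est_bytes = est_active * dim * 8
    if est_bytes > memory_cap_bytes:
        raise MemoryError(
            f"projected design storage {est_bytes / 1e9:.2f} GB for "
            f"{est_active} active bins x {dim} columns exceeds the cap "
            f"{memory_cap_bytes / 1e9:.2f} GB; increase delta or the cap"
        )

    y_bins = np.minimum((pop.spike_times[target] / delta).astype(np.int64), n_bins - 1)
    y = np.bincount(y_bins, minlength=n_bins)

    # active bins: center has >= 1 spike in [center-H, center)
    centers = (np.arange(n_bins) + 0.5) * delta
    lo = np.searchsorted(times, centers - b.H, side="left")
    hi = np.searchsorted(times, centers, side="left")
    active = np.flatnonzero(hi > lo)
    X_active = WindowedFeatures(pop, b, centers[active]).dense()
    y_active = y[active]
    K = int(pop.spike_times[target].size)
    active_mask = np.zeros(n_bins, dtype=bool)
    active_mask[active] = True
    inactive_y = np.flatnonzero(~active_mask & (y > 0))
    return BinnedDesign(
        delta=delta, n_bins=n_bins, N=pop.n_neurons, J=b.J,
        y_active=y_active.astype(float), active_bins=active, X_active=X_active,
        n_inactive=n_bins - active.size,
        y_inactive_sum=int(K - y_active.sum()),
        inactive_y_bins=inactive_y, inactive_y_counts=y[inactive_y].astype(float),
        K=K, T=T, basis=b.descriptor(), target=target,
    )


def discrete_loglik(d: BinnedDesign, w_flat) -> float:
    """Exact binned Poisson log-likelihood (exp link, per-bin rate exp(u))."""
    w = np.asarray(w_flat, dtype=float)
    u = d.X_active @ w
    ll = float(d.y_active @ u - np.exp(np.minimum(u, 30.0)).sum())
    w0 = w[0]
    ll += d.y_inactive_sum * w0 - d.n_inactive * math.exp(min(w0, 30.0))
    return ll


def discrete_gradient(d: BinnedDesign, w_flat) -> np.ndarray:
    """Full analytic gradient of the binned log-likelihood."""
    w = np.asarray(w_flat, dtype=float)
    u = d.X_active @ w
    resid = d.y_active - np.exp(np.minimum(u, 30.0))
    g = d.X_active.T @ resid
    g[0] += d.y_inactive_sum - d.n_inactive * math.exp(min(w[0], 30.0))
    return g


def _to_model(d: BinnedDesign, w, estimator, **kw) -> FittedModel:
    params = PPGLMParams.from_flat(
        np.r_[w[0] - math.log(d.delta), w[1:]], d.N, d.J
    )
    meta = kw.pop("metadata", {})
    meta.update({"delta": d.delta, "intercept_raw": float(w[0])})
    return FittedModel(params=params, estimator=estimator, basis=d.basis,
                       target=d.target, metadata=meta, **kw)


def fit_discrete_full(d: BinnedDesign, ridge: float = 0.0,
                      gtol: float = 1e-6, maxiter: int = 500) -> FittedModel:
    """Deterministic quasi-Newton maximization of the full binned likelihood."""
    x0 = np.zeros(d.dim)
    x0[0] = math.log(max(d.K, 1) / d.n_bins)
    noint = np.r_[0.0, np.ones(d.dim - 1)]

    def fg(w):
        val = -discrete_loglik(d, w) + ridge * float(np.sum((w * noint) ** 2))
        g = -discrete_gradient(d, w) + 2.0 * ridge * w * noint
        return val, g

    res = optimize.minimize(fg, x0, jac=True, method="L-BFGS-B",
                            options={"gtol": gtol, "maxiter": maxiter, "ftol": 1e-15})
    return _to_model(d, res.x, "db", n_iter=int(res.nit),
                     final_objective=float(res.fun),
                     metadata={"grad_norm": float(np.max(np.abs(res.jac))),
                               "mode": "full"})


def _batch_gradient(d: BinnedDesign, w, batch_idx) -> np.ndarray:
    """Unbiased estimate of the full gradient from a uniform bin sample."""
    pos = np.searchsorted(d.active_bins, batch_idx)
    pos = np.clip(pos, 0, max(d.active_bins.size - 1, 0))
    is_active = d.active_bins.size > 0
    hit = is_active & (d.active_bins[pos] == batch_idx) if is_active else np.zeros(len(batch_idx), bool)
    g = np.zeros(d.dim)
    if np.any(hit):
        rows = d.X_active[pos[hit]]
        u = rows @ w
        g += rows.T @ (d.y_active[pos[hit]] - np.exp(np.minimum(u, 30.0)))
    n_miss = int((~hit).sum())
    if n_miss:
        g[0] += -n_miss * math.exp(min(w[0], 30.0))
        if d.inactive_y_bins.size:
            # rare intercept-only bins that still contain target spikes
            miss = batch_idx[~hit]
            q = np.searchsorted(d.inactive_y_bins, miss)
            q = np.clip(q, 0, d.inactive_y_bins.size - 1)
            yhit = d.inactive_y_bins[q] == miss
            g[0] += float(d.inactive_y_counts[q[yhit]].sum())
    scale = d.n_bins / len(batch_idx)
    return g * scale


def fit_discrete_batched(d: BinnedDesign, batch_bins: int, n_iter: int = 2000,
                         lr: float = 1e-2, ridge: float = 0.0, seed: int = 0,
                         trace_every: int = 10) -> FittedModel:
    """Mini-batch stochastic-gradient fit of the binned GLM (DB comparator).

    Bins are sampled uniformly with replacement and the per-batch gradient
    is rescaled by ``n_bins / batch_bins``, so each step uses an unbiased
    but (for sparse spiking) very noisy gradient estimate.
    """
    if batch_bins > d.n_bins:
        raise ValueError("batch size exceeds number of bins")
    rng = np.random.default_rng(seed)
    x = np.zeros(d.dim)
    x[0] = math.log(max(d.K, 1) / d.n_bins)
    noint = np.r_[0.0, np.ones(d.dim - 1)]
    m_t = np.zeros_like(x)
    v_t = np.zeros_like(x)
    b1, b2, eps = 0.9, 0.999, 1e-8
    trace_it, trace_obj = [], []
    full_batch = batch_bins == d.n_bins
    for i in range(n_iter):
        if full_batch:
            # degenerate batching: exact full gradient, deterministic trajectory
            g = -discrete_gradient(d, x) + 2.0 * ridge * x * noint
        else:
            batch = rng.integers(0, d.n_bins, size=batch_bins)
            g = -_batch_gradient(d, x, batch) + 2.0 * ridge * x * noint
        m_t = b1 * m_t + (1 - b1) * g
        v_t = b2 * v_t + (1 - b2) * g * g
        x = x - lr * (m_t / (1 - b1 ** (i + 1))) / (np.sqrt(v_t / (1 - b2 ** (i + 1))) + eps)
        if (i % trace_every) == 0 or i == n_iter - 1:
            trace_it.append(i + 1)
            trace_obj.append(-discrete_loglik(d, x))
    return _to_model(d, x, "db", seed=seed, n_iter=n_iter,
                     final_objective=trace_obj[-1],
                     metadata={"mode": "batched", "batch_bins": batch_bins,
                               "trace_iter": trace_it, "trace_objective": trace_obj})


def discrete_sufficient_stats(d: BinnedDesign):
    """Streaming sufficient statistics (sum x, sum y x, sum x x^T).

    ``Delta * sum(x)`` and ``Delta * sum(x x^T)`` converge to the continuous
    m vector and M matrix as the bin size shrinks.
    """
    Sx = d.X_active.sum(axis=0)
    Sx[0] += d.n_inactive
    Syx = d.X_active.T @ d.y_active
    Syx[0] += d.y_inactive_sum
    Sxx = d.X_active.T @ d.X_active
    Sxx[0, 0] += d.n_inactive
    return Sx, Syx, Sxx


def fit_pa_d(d: BinnedDesign, x0: float, x1: float, ridge: float = 0.0) -> FittedModel:
    """Discrete polynomial-approximate MAP from streaming sufficient stats.

    The quadratic surrogate is fit to the raw exp nonlinearity on
    ``[x0, x1]`` and the explicit ``Delta`` factor multiplies the integral
    statistics, so the solved weights (including the intercept) are already
    on the continuous scale.
    """
    pa = fit_poly("exp", x0, x1)
    Sx, Syx, Sxx = discrete_sufficient_stats(d)
    A = 2.0 * pa.a2 * d.delta * Sxx
    if ridge:
        A = A + 2.0 * ridge * np.diag(np.r_[0.0, np.ones(d.dim - 1)])
    rhs = Syx - pa.a1 * d.delta * Sx
    sol = np.linalg.solve(A, rhs)
    params = PPGLMParams.from_flat(sol, d.N, d.J)
    return FittedModel(params=params, estimator="pa-d", basis=d.basis,
                       target=d.target,
                       metadata={"delta": d.delta, "range": [x0, x1],
                                 "poly": [pa.a0, pa.a1, pa.a2], "ridge": ridge})


def gradient_error_db(d: BinnedDesign, params_trace, batch_bins: int,
                      n_resamples: int = 100, seed: int = 0,
                      grad_norm_ref: float | None = None) -> np.ndarray:
    """Normalized mini-batch gradient error along a parameter trace.

    Mirrors :func:`ppglm.mc.gradient_error`: expected squared deviation of
    the stochastic gradient from the full-data gradient at each checkpoint,
    normalized by the squared norm of the full gradient at the first one.
    ``params_trace`` entries are flat vectors in the *discrete* intercept
    convention (use ``w0 + log Delta`` to convert continuous parameters).
    """
    rng = np.random.default_rng(seed)
    errs = []
    norm0 = grad_norm_ref
    for w in params_trace:
        w = np.asarray(w, dtype=float)
        exact = discrete_gradient(d, w)
        if norm0 is None:
            norm0 = float(np.sum(exact ** 2))
            if norm0 == 0:
                raise ValueError("zero initial gradient: normalization undefined")
        sq = 0.0
        for _ in range(n_resamples):
            batch = rng.integers(0, d.n_bins, size=batch_bins)
            g = _batch_gradient(d, w, batch)
            sq += float(np.sum((g - exact) ** 2))
        errs.append(sq / n_resamples / norm0)
    return np.asarray(errs)
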