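"""Temporal basis functions for coupling filters.

Two families are provided:

* Generalized Laguerre (GL) functions
  ``phi_n(tau) = L_n^{(alpha)}(c*tau) * (c*tau)^{alpha/2} * exp(-c*tau/2)``
  with ``tau`` measured in **milliseconds**.  They are orthogonal on
  ``[0, inf)`` and, for even integer ``alpha``, all single and pairwise
  integrals reduce to lower incomplete gamma functions, which is what makes
  the closed-form polynomial-approximate estimator fast.
* Log-stretched raised cosine (RC) bumps, the conventional basis for spike
  history filters, kept as a comparison baseline.  Its integrals always go
  through adaptive quadrature.

Public time arguments (lags, the history window ``H``) are in seconds;
the millisecond change of variables is internal, so the default scale
parameter ``c = 1.5`` (per ms) and shape ``alpha = 2`` act on the
millisecond axis where synaptic dynamics live.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate, special

__all__ = [
    "BasisSet",
    "lower_incomplete_gamma",
    "single_integrals",
    "pairwise_integrals",
    "pairwise_integrals_batch",
    "gl_orthogonality_check",
]

_MS = 1e3  # seconds -> milliseconds


def lower_incomplete_gamma(a, x):
    """Unregularized lower incomplete gamma ``gamma(a, x) = int_0^x t^{a-1} e^{-t} dt``.

    ``a`` must be positive, ``x`` nonnegative.  Monotone nondecreasing in ``x``.
    """
    a = np.asarray(a, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(a <= 0):
        raise ValueError("lower_incomplete_gamma requires a > 0")
    if np.any(x < 0):
        raise ValueError("lower_incomplete_gamma requires x >= 0")
    return special.gammainc(a, x) * special.gamma(a)


@dataclass(frozen=True)
class BasisSet:
    """A set of ``J`` temporal basis functions on the history window ``[0, H]``.

    Parameters
    ----------
    kind:
        ``"gl"`` (generalized Laguerre, default) or ``"rc"`` (raised cosine).
    J:
        Number of basis functions (>= 1).
    H:
        History window length in **seconds** (default 5 ms).
    alpha:
        GL shape parameter, must exceed -1.  With ``alpha > 0`` every GL
        function vanishes at lag 0, so filters start at zero gain.
    c:
        GL time-scale parameter applied to the lag in milliseconds.
    rc_stretch:
        RC log-time offset ``psi`` (ms) in ``g(tau) = log(tau + psi)``.
    """

    kind: str = "gl"
    J: int = 3
    H: float = 0.005
    alpha: float = 2.0
    c: float = 1.5
    rc_stretch: float = 0.5

    def __post_init__(self):
        if self.kind not in ("gl", "rc"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if self.H <= 0:
            raise ValueError("H must be positive")
        if self.alpha <= -1:
            raise ValueError("alpha must exceed -1")

    # -- evaluation -----------------------------------------------------

    def evaluate(self, taus):
        """Evaluate all basis functions at lags ``taus`` (seconds).

        Returns an array of shape ``(len(taus), J)``.  Lags outside
        ``[0, H]`` evaluate to 0 by contract.
        """
        taus = np.atleast_1d(np.asarray(taus, dtype=float))
        out = np.zeros((taus.size, self.J))
        inside = (taus >= 0) & (taus <= self.H)
        if np.any(inside):
            out[inside] = self._eval_ms(taus[inside] * _MS)
        return out

    def _eval_ms(self, t_ms):
        if self.kind == "gl":
            x = self.c * t_ms
            env = np.where(x > 0, np.power(x, self.alpha / 2.0), 0.0 if self.alpha > 0 else 1.0)
            env = env * np.exp(-x / 2.0)
            cols = [special.eval_genlaguerre(j, self.alpha, x) * env for j in range(self.J)]
            return np.stack(cols, axis=1)
        return self._eval_rc_ms(t_ms)

    def _eval_rc_ms(self, t_ms):
        g = np.log(t_ms + self.rc_stretch)
        g0 = math.log(self.rc_stretch)
        g1 = math.log(self.H * _MS + self.rc_stretch)
        if self.J > 1:
            centers = np.linspace(g0, g1, self.J)
            width = 2.0 * (g1 - g0) / (self.J - 1)
        else:
            centers = np.array([(g0 + g1) / 2.0])
            width = g1 - g0
        arg = (g[:, None] - centers[None, :]) * (np.pi / width)
        arg = np.clip(arg, -np.pi, np.pi)
        return 0.5 * (1.0 + np.cos(arg))

    # -- plumbing -------------------------------------------------------

    @property
    def _closed_form_ok(self) -> bool:
        """Closed-form integrals need alpha to be a nonnegative even integer."""
        a = self.alpha
        return self.kind == "gl" and a >= 0 and float(a).is_integer() and int(a) % 2 == 0

    def descriptor(self) -> dict:
        return {
            "kind": self.kind,
            "J": self.J,
            "H": self.H,
            "alpha": self.alpha,
            "c": self.c,
            "rc_stretch": self.rc_stretch,
        }

    @classmethod
    def from_descriptor(cls, d: dict) -> "BasisSet":
        required = {"kind", "J", "H"}
        missing = required - set(d)
        if missing:
            raise ValueError(f"basis descriptor missing keys: {sorted(missing)}")
        known = {"kind", "J", "H", "alpha", "c", "rc_stretch"}
        return cls(**{k: d[k] for k in d if k in known})


# ----------------------------------------------------------------------
# Monomial expansion of the GL functions (closed-form path)
# ----------------------------------------------------------------------

@lru_cache(maxsize=64)
def _gl_monomial_coeffs(J: int, alpha: float):
    """Coefficients a_{jk} with L_j^{(alpha)}(x) = sum_k a_{jk} x^k."""
    coeffs = []
    for j in range(J):
        a = np.array(
            [(-1.0) ** k * special.binom(j + alpha, j - k) / math.factorial(k) for k in range(j + 1)]
        )
        coeffs.append(a)
    return tuple(tuple(a) for a in coeffs)


@lru_cache(maxsize=64)
def _pairwise_terms(b: BasisSet):
    """Flattened term table for the closed-form pairwise integral.

    For even alpha write ``phi_j(tau) = sum_k a_{jk} (c tau)^{p} e^{-c tau/2}``
    with integer ``p = k + alpha/2``.  Then for ``0 <= d <= H`` (ms)

        P(d)_{jj'} = int_d^H phi_j(tau) phi_{j'}(tau - d) dtau
                   = e^{-c d/2} * sum_terms coef * d^{dpow} * gamma(aa, c (H - d))

    where the sum runs over (k, l, i) with ``i`` indexing the binomial
    expansion of ``(s + d)^p``.  Returns flat arrays (j, j', coef, dpow, aa).
    """
    m = int(b.alpha) // 2
    c = b.c
    A = _gl_monomial_coeffs(b.J, b.alpha)
    rows_j, rows_jp, coefs, dpows, aas = [], [], [], [], []
    for j in range(b.J):
        for jp in range(b.J):
            for k, ajk in enumerate(A[j]):
                p = k + m
                for l, ajpl in enumerate(A[jp]):
                    q = l + m
                    for i in range(p + 1):
                        coef = (
                            ajk
                            * ajpl
                            * c ** (p + q)
                            * special.binom(p, i)
                            / c ** (i + q + 1)
                        )
                        rows_j.append(j)
                        rows_jp.append(jp)
                        coefs.append(coef)
                        dpows.append(p - i)
                        aas.append(i + q + 1)
    return (
        np.array(rows_j),
        np.array(rows_jp),
        np.array(coefs),
        np.array(dpows, dtype=float),
        np.array(aas, dtype=float),
    )


# ----------------------------------------------------------------------
# Integrals
# ----------------------------------------------------------------------

def single_integrals(b: BasisSet, quadrature: bool = False) -> np.ndarray:
    """Integrals ``phibar_j = int_0^H phi_j(tau) dtau`` in **seconds**.

    GL bases with even integer ``alpha`` use the exact incomplete-gamma
    expansion; everything else (and ``quadrature=True``) uses adaptive
    quadrature with absolute tolerance 1e-10 on the millisecond axis.
    """
    H_ms = b.H * _MS
    if b._closed_form_ok and not quadrature:
        m = int(b.alpha) // 2
        A = _gl_monomial_coeffs(b.J, b.alpha)
        out = np.zeros(b.J)
        for j in range(b.J):
            for k, ajk in enumerate(A[j]):
                p = k + m
                out[j] += ajk * 2.0 ** (p + 1) / b.c * lower_incomplete_gamma(p + 1, b.c * H_ms / 2.0)
        return out / _MS
    out = np.zeros(b.J)
    for j in range(b.J):
        val, _ = integrate.quad(
            lambda t, j=j: b._eval_ms(np.array([t]))[0, j], 0.0, H_ms, epsabs=1e-12, limit=400
        )
        out[j] = val
    return out / _MS


def pairwise_integrals_batch(b: BasisSet, deltas) -> np.ndarray:
    """Pairwise product integrals ``P(delta)`` for many lag differences at once.

    ``deltas`` is in seconds; the result has shape ``(len(deltas), J, J)``
    in units of seconds, with ``P(-d) = P(d)^T`` and zeros for ``|d| > H``.
    """
    deltas = np.atleast_1d(np.asarray(deltas, dtype=float))
    out = np.zeros((deltas.size, b.J, b.J))
    pos = np.abs(deltas) <= b.H
    if not np.any(pos):
        return out
    d_ms = np.abs(deltas[pos]) * _MS
    if b._closed_form_ok:
        P = _pairwise_closed_ms(b, d_ms)
    else:
        P = np.stack([_pairwise_quad_ms(b, d) for d in d_ms])
    P = P / _MS
    neg = deltas[pos] < 0
    P[neg] = np.transpose(P[neg], (0, 2, 1))
    out[pos] = P
    return out


def pairwise_integrals(b: BasisSet, delta: float) -> np.ndarray:
    """``P(delta)_{jj'} = int_delta^H phi_j(tau) phi_{j'}(tau - delta) dtau`` (seconds).

    For ``delta < 0`` returns ``P(-delta)^T``; outside ``[-H, H]`` the
    interaction window is empty and an all-zeros matrix is returned.
    """
    return pairwise_integrals_batch(b, [delta])[0]


def _pairwise_closed_ms(b: BasisSet, d_ms: np.ndarray) -> np.ndarray:
    H_ms = b.H * _MS
    rows_j, rows_jp, coefs, dpows, aas = _pairwise_terms(b)
    x = b.c * (H_ms - d_ms)  # (n,)
    # gamma(aa, x): broadcast terms x deltas
    gam = special.gammainc(aas[:, None], x[None, :]) * special.gamma(aas)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        dp = np.where(
            dpows[:, None] == 0.0, 1.0, np.power(d_ms[None, :], dpows[:, None])
        )
    terms = coefs[:, None] * dp * gam  # (n_terms, n)
    env = np.exp(-b.c * d_ms / 2.0)
    out = np.zeros((d_ms.size, b.J, b.J))
    np.add.at(out, (slice(None), rows_j, rows_jp), (terms * env[None, :]).T)
    return out


def _pairwise_quad_ms(b: BasisSet, d_ms: float) -> np.ndarray:
    H_ms = b.H * _MS
    out = np.zeros((b.J, b.J))
    for j in range(b.J):
        for jp in range(b.J):
            val, _ = integrate.quad(
                lambda t, j=j, jp=jp: b._eval_ms(np.array([t]))[0, j]
                * b._eval_ms(np.array([t - d_ms]))[0, jp],
                d_ms,
                H_ms,
                epsabs=1e-12,
                limit=400,
            )
            out[j, jp] = val
    return out


def gl_orthogonality_check(b: BasisSet, upper_ms: float | None = None) -> np.ndarray:
    """Gram matrix of the GL functions on ``[0, inf)`` (millisecond axis).

    The functions are orthogonal under their own envelope: the exact Gram is
    diagonal with entries ``Gamma(j + alpha + 1) / (j! c)``.  Raised-cosine
    bases are not orthogonal and are rejected.
    """
    if b.kind != "gl":
        raise ValueError("orthogonality check is only defined for the GL basis")
    if upper_ms is None:
        upper_ms = (60.0 + 10.0 * b.J) / b.c
    gram = np.zeros((b.J, b.J))
    for j in range(b.J):
        for jp in range(j, b.J):
            val, _ = integrate.quad(
                lambda t, j=j, jp=jp: b._eval_ms(np.array([t]))[0, j]
                * b._eval_ms(np.array([t]))[0, jp],
                0.0,
                upper_ms,
                epsabs=1e-12,
                limit=400,
            )
            gram[j, jp] = gram[jp, j] = val
    return gram


def gl_gram_diagonal_exact(b: BasisSet) -> np.ndarray:
    """Analytic GL norms ``Gamma(j + alpha + 1) / (j! c)`` on the ms axis."""
    j = np.arange(b.J)
    return special.gamma(j + b.alpha + 1) / (special.factorial(j) * b.c)
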