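# Methods

## Model

A target neuron's spikes are modeled as an inhomogeneous Poisson process
whose conditional intensity depends on recent population spiking:

    λ(t) = Φ( u(t) ),    u(t) = w₀ + Σ_{s: t−H ≤ t_s < t} w_{n_s}ᵀ φ(t − t_s)

- `H` — history window, seconds. Default **5 ms**: long enough for
  monosynaptic rise and decay (1–5 ms), short enough that window occupancy
  stays small. Configurable.
- `φ` — `J` temporal basis functions on `[0, H]`.
- `w_n ∈ R^J` — coupling weights from neuron `n` onto the target. The
  target's own history is a legitimate predictor and is included.
- `w₀` — intercept, log baseline rate (exp link). The model includes an
  explicit intercept so a nonzero baseline does not have to be absorbed by
  the coupling weights; all sufficient statistics are intercept-augmented
  accordingly.
- `Φ` — exp (canonical; all closed forms assume it) or softplus
  (Monte Carlo path only).

The window is half-open: a spike at exactly `t` does not drive the rate at
`t`, so self-history is causal and the basis is never evaluated at lag 0
for the spike itself.

The log-likelihood `Σ_k log λ(y_k) − ∫₀ᵀ λ dt` has an exact spike term;
the integral (CIF) is the only quantity approximated, by one of:

### Stratified Monte Carlo (MC)

`[0, T]` is divided into `M` equal strata with one uniform draw each;
`(T/M) Σ λ(τ_m)` is unbiased for the CIF and removes the between-strata
component of the sampling variance. Default `M = ⌈100 T⌉` (one point per
10 ms), resolving rate fluctuations at the history-window scale at modest
cost. Optimization is Adam (step 1e−2, 2000 iterations by default) with a
fresh sample per iteration; convergence is monitored on one fixed
validation sample (common random numbers) so traces are comparable across
iterations and across warm/cold starts. An optional ridge penalty excludes
the intercept — shrinking the baseline rate toward 0 Hz is not meaningful.

### Polynomial approximation (PA-c)

`Φ = exp` is replaced by its least-squares quadratic over a working range
`[x₀, x₁]` of the linear predictor (dense 10⁴-point grid; the fit residual
is recorded). The literature describes these coefficients as Chebyshev
coefficients minimizing mean squared error; plain least squares on a dense
grid implements exactly that criterion, and the difference from a
Chebyshev-weighted projection is negligible at these range widths. The CIF
becomes `a₂ wᵀMw + a₁ mᵀw + T a₀` with

- `m` — spike counts times single basis integrals (intercept slot `T`),
- `M` — pairwise basis-product integrals accumulated over all ordered
  spike pairs with time difference in `[0, H]` (same-spike pairs once;
  opposite orderings give transposed blocks, so `M` is symmetric),
- `k` — exact spike-term features (intercept slot `K`).

Maximizing `wᵀk − a₁mᵀw − a₂wᵀMw − β‖w‖²` is one symmetric
positive-definite solve. Sufficient statistics can be cached and re-solved
at any ridge without recomputation.

Range selection: on simulated data, the 2.5th–97.5th percentiles of the
true binned rate mapped through log (the generator exposes the exact rate
trace for this); on real data, a `width_hz` interval (default 5 Hz)
centered on the mean rate `K/T`, floored at 0.01 Hz. Degenerate ranges are
widened to 0.1 log-units. A cross-validated width search over
{3,4,5,6,7} Hz is provided (`select_width_cv`), scored by held-out
MC-estimated likelihood on a time split (first 80% train / last 20%
test) — the fold structure is this package's choice. Wider ranges admit
larger filter amplitudes but increase the quadratic's residual, which is
the PA family's intrinsic accuracy/stability trade-off.

Edge convention: the pairwise integrals run to lag `H` without truncation
at the recording boundary, so for a spike within `H` of `T` the statistics
count basis mass that extends past the recording. The relative effect is
O(H/T) (≤ 10⁻⁴ at the default scales) and is ignored.

The softplus link has no PA path here; configuration rejects that
combination.

### Hybrid

PA-c solved in closed form, then MC fine-tuning initialized at the PA
solution. The PA amplitudes are biased (quadratic surrogate), but the
shape information is enough to skip most of the stochastic optimization:
on the 8-neuron benchmark the warm-started trace reaches the cold fit's
converged objective in roughly half the iterations.

### Discrete baselines

The conventional binned GLM (`Σ y_t log Φ(x_tᵀw) − Φ(x_tᵀw)`) with
0-based, half-open bins and basis features evaluated at bin-center lags.
The O(Δ) bin-center error — including the same-bin self-history artifact,
where a target spike early in a bin appears in that bin's own features —
is deliberately left uncorrected: it is precisely the discretization error
the continuous estimators eliminate, and it vanishes as Δ → 0. The design
is stored sparsely (rows only for bins with in-window spikes; intercept-
only bins handled in closed form), with a memory-cap guard that reports
the projected allocation before refusing. Variants: full-gradient L-BFGS
(`fit_discrete_full`), unbiased mini-batch Adam (`fit_discrete_batched` —
a plain stochastic-gradient comparator for the gradient-noise experiment,
not a variance-reduced optimizer), and the discrete polynomial
approximation `fit_pa_d` from streaming sufficient statistics. Discrete
fits absorb `log Δ` into the intercept internally and are returned on the
continuous scale.

## Temporal bases

**Generalized Laguerre (GL), default.**
`φ_n(τ) = L_n^{(α)}(cτ_ms)·(cτ_ms)^{α/2}·e^{−cτ_ms/2}` with the lag in
milliseconds, `α = 2`, `c = 1.5` per ms, `J = 3` (configurable 1–7; three
functions capture typical synaptic rise–decay shapes). The functions are
orthogonal on `[0, ∞)` under their own envelope and vanish at lag 0 for
`α > 0`. For even integer `α` the Laguerre polynomial expands into
monomials and every single/pairwise integral reduces to lower incomplete
gamma functions; any other `α` (and the RC basis) falls back to adaptive
quadrature at 1e−10 absolute tolerance, which is the authoritative
definition of all integrals. Closed forms agree with the quadrature oracle
to better than 1e−8 (millisecond units) across `J ≤ 7` and a 50-point lag
grid. Internally the basis works in milliseconds so that `c` and `α` match
the natural scale of synaptic dynamics; all public interfaces are in
seconds.

**Raised cosine (RC).** Standard log-stretched cosine bumps tiling
`[0, H]` (stretch 0.5 ms), kept as the conventional comparison basis and
as the representation of simulated ground-truth filters.

## Synthetic data

`simulate_all_to_one(n_pre=7, T, post_baseline_hz=3, pre_rate_hz=5)` —
independent homogeneous Poisson inputs (5 Hz each; the input rate is this
package's choice, exposed in the signature) drive one target through known
filters. Ground-truth filters are differences of two gamma-shaped lobes —
fast lobe peaking at 0.8–2.2 ms, slower opposing lobe, peak magnitude
0.5–1.8 (capped at 3 to keep rates stable), 60% excitatory — projected
onto 100 RC bases, so they are smooth, vanish at lag 0, and are *not* in
the span of the GL fitting basis (recovery is a genuine approximation
task; the GL-projection floor is reported by the benchmark, not hidden).

Sampling is Ogata-style thinning of the exact process: per-chunk (5 ms)
piecewise-constant dominating rates built from interval suprema of the
filters (inflated 5% + 0.01 so the bound holds between grid points),
Poisson proposals per chunk, acceptance with probability `λ(t)/bound`. No
time grid enters the generator. A fine-grid Bernoulli simulator is kept
purely as a cross-check oracle; a time-rescaling test (rescaled ISIs
against Exp(1)) verifies exactness. A guard aborts only on genuinely
unstable filter sets (dominating rate above 10⁸ Hz or proposal budget
beyond 2×10⁷), not on the rare transient synchrony that legitimately
spikes the conservative bound.

`simulate_network(N, sparsity=0.1, T=100)` — directed Erdős–Rényi
connectivity, per-neuron baselines uniform in 2–6 Hz, sequential joint
thinning over the superposed process. Excitatory filter mass is rescaled
so the per-neuron branching proxy `Σ_pre baseline_pre·∫max(0,f)` stays
below 0.8, preventing runaway excitation.

What the generator does *not* emulate: refractoriness beyond what fitted
self-history absorbs, bursting, non-Poisson dispersion, common-input
latent states, and electrode artifacts. Passing recovery tests therefore
demonstrates correctness of the estimators under the model's own
assumptions, not robustness to real-data violations of them.

## Evaluation and screening

Filter accuracy is the mean squared pointwise difference on the
linear-predictor scale over a common 0.05 ms lag grid. CCGs are pair
histograms at 0.1 ms resolution over ±H (two-pointer sweep, zero-lag
self-pairs excluded for auto-CCGs). To compare CCGs with filters on one
scale, counts are converted to a log-rate modulation
`log(count/(S_pre·bin·r̄_post))` with empty bins floored at 0.5 counts —
the normalization is a package choice, config-exposed.

Screening flags an ordered pair as putative excitatory iff its filter's
global maximum is positive, exceeds an amplitude threshold (default:
twice the median absolute filter value across all pairs, a robust null
scale), and peaks at 0.3–2.5 ms lag — the monosynaptic latency window.
The onset-to-peak delay uses onset = first upward crossing of 10% of the
peak (threshold configurable; "onset" has no standard definition).
Region-block aggregates count ordered pairs including self-pairs on the
diagonal, so block pair counts are exactly products of region sizes.

## Numerical choices

- Exp-link linear predictor capped at 30 before exponentiation (warned
  when active) to prevent overflow during optimization.
- The CIF quadrature oracle is composite Gauss–Legendre with segment
  boundaries at every spike and spike + H (all kinks of the integrand);
  the order-24/32 discrepancy must stay below max(tol, 1e−9·value).
  Inside optimizer line searches the check is skipped (extreme trial
  weights make the integrand arbitrarily sharp) and re-applied at the
  solution.
- Unregularized continuous MLEs on short recordings can diverge in
  directions with no post-spike coincidences (the GLM analogue of
  separation); reference fits on small instances therefore use a small
  ridge, stated wherever used.
- `solve_map` uses a symmetric positive-definite solve and reports rank
  deficiency with a suggestion to add ridge rather than silently
  regularizing.
- Seeds: every stochastic routine takes an explicit seed or Generator;
  fits are bit-reproducible for identical config + data + seed.

## Validation battery problem sizes

The reproduction script (`scripts/acceptance.py`) and the end-to-end test
suite use: integral checks at `J = 7` over 50 lags; MC calibration with
10⁴ resamples at `M = 16` on a ~100-spike deterministic-rate instance
structured so stratification demonstrably reduces variance; PA algebra on
5 random 3-neuron populations × 10 weight draws; discretization
consistency on a 3-neuron, 50 s simulation (bins 1/0.5/0.1 ms, statistics
at 0.01 ms); recovery on the 8-neuron all-to-one benchmark at T = 10 and
1000 s (2000 Adam iterations); gradient-variance comparison at T = 100 s
with a 10⁴-point budget and 100 resamples per checkpoint; screening on 14
planted filters plus the 106-neuron (62/28/16) region layout. These sizes
are the package's chosen desk-scale defaults; all scale up linearly.

## Known limitations

- The PA path underestimates filter amplitudes whenever the true linear
  predictor leaves the approximation range; this is intrinsic to a global
  quadratic surrogate and is the reason the hybrid exists.
- Coupling filters measure statistical, not anatomical, connectivity;
  common input and indirect paths can mimic monosynaptic coupling, and the
  screening window is a heuristic.
- The mini-batch discrete baseline is a generic stochastic-gradient
  comparator; conclusions about it are qualitative orderings, not
  statements about any specific variance-reduced optimizer.
- Closed-form integrals require even integer `α`; other shapes silently
  use quadrature (correct but slower).
- The network simulator's sequential thinning is exact but scales poorly
  beyond a few hundred neurons at long durations.
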