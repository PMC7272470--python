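# Methods

## Model

The package models a transcription factor (TF) synthesized in instantaneous
bursts arriving as a Poisson process of rate `k_x` (hr⁻¹).  Each burst adds
`B_x` molecules, with `B_x` drawn i.i.d. from a burst-size distribution
`α_x` on the non-negative integers.  Free TFs bind reversibly to `N`
identical decoy sites (rate `k_b` per free-TF/site pair; unbinding `k_u`
per bound TF; dissociation constant `k_d = k_u/k_b`, in molecules).  Free
and bound TF degrade at `γ_f` and `γ_b = β γ_f`.  Up to two decoy species
with a shared `γ_b` are supported, as is a downstream target protein `y`
produced in bursts at frequency `k_y x_f` (linear dose-response) and
degraded at `γ_y`.  Cell division is not modelled explicitly; dilution is
folded into the degradation rates.  Rates are time-invariant.

Burst distributions come in three kinds.  `degenerate` places all mass on
one size (size 1 reproduces the non-bursty/Poisson limit).  `geometric` has
support {1, 2, …} with `P(B=i) = (1 − 1/⟨B⟩)^(i−1)/⟨B⟩`; its moments use
the closed forms `⟨B²⟩ = 2⟨B⟩² − ⟨B⟩`, and the tabulated pmf (used for
sampling and the CME oracle) is truncated at cumulative mass `1 − 1e−12`
and renormalized.  `explicit` accepts any finite pmf, may include size 0,
and must carry total mass within `1e−9` of 1.  Bursts of size 0 count as
events with no state change.

## Closed forms (fast-binding limit)

With `k_b, k_u → ∞` at fixed `k_d`, binding equilibrates instantly and the
stationary mean free TF is the positive root of a quadratic in
`(⟨x_f⟩₀, Nβ, k_d)`; the bound mean is `N x̄_f/(k_d + x̄_f)`.  The free-TF
Fano factor, its `β = 0` simplification, the critical affinity
`k_d^th = F₀ β ⟨x_f⟩₀/(F₀ − 1)`, the occupancy condition `f > 1/(1+β)`,
and the target-protein Fano factor are implemented as pure functions of
`(⟨x_f⟩₀, F₀, N, k_d, β, …)` rather than raw rate constants, so that
constant-mean sweeps can retune `k_x` (via `required_kx_for_mean`) without
rebuilding distributions.  `N` is accepted as a real number for smooth
sweeps; only the simulator requires integer `N`.

`k_d = 0` (irreversible binding) is rejected in the closed forms: with
`f → 1` the Fano denominator degenerates.  The SSA handles `k_u = 0`
directly.  The small-`N` expansion is accurate to 1% for
`N ≲ 0.02 ⟨x_f⟩₀/β`; the large-`N` form `k_d ⟨x_f⟩₀/(Nβ)` has relative
error ≈ `⟨x_f⟩₀/(Nβ)` and reaches 1% around `N ≈ 100 ⟨x_f⟩₀/β`.

## Linear noise approximation

At finite binding rates the bilinear binding propensity is linearized about
the deterministic fixed point.  The fixed point solves the scalar flux
balance `k_x⟨B_x⟩ = γ_f x̄_f + γ_b Σᵢ x̄_bᵢ` with
`x̄_bᵢ = Nᵢ x̄_f/(k_dᵢ + x̄_f + γ_b/k_bᵢ)`, bracketed on `[0, k_x⟨B_x⟩/γ_f]`
and solved by Brent's method (residual < 1e−10 of the production rate);
a monotone scalar solve was preferred to multidimensional Newton for
robustness.  The drift matrix `A` is the Jacobian of the rate equations;
the diffusion matrix is assembled channel by channel as
`D = Σ_c rate_c(x̄) v_c v_cᵀ`.  Burst channels contribute the *second
moment* of the jump size (`k_x⟨B_x²⟩` on the free-TF diagonal,
`k_y x̄_f⟨B_y²⟩` on the target diagonal) — using `⟨B⟩²` instead would fail
to reproduce the exact no-decoy Fano factor `(⟨B⟩+⟨B²⟩)/2⟨B⟩`.  The
stationary covariance solves `AΣ + ΣAᵀ + D = 0` (SciPy's Lyapunov solver);
instability of `A` raises an error rather than a warning, since every
open-loop degradation-stabilized model here is stable.  Lag covariances use
`exp(Aτ)Σ` via scaling-and-squaring `expm`, giving the model-based
autocorrelation `R(τ)` normalized to `R(0) = 1`; without decoys this is
exactly `exp(−γ_f τ)`.

Two-decoy mixtures use the same machinery; the Fano factor of the mixture
is obtained numerically from Σ, which is the route used for the mixture
heatmaps.  Note that for strong binding (small `k_d`) with `β > 0` the LNA
underestimates the actual fluctuations; the simulator is the reference
there (see Limitations).

## Exact simulation

The Gillespie direct method draws an exponential waiting time from the
total propensity and selects a channel by a second uniform; burst sizes are
drawn by inverse CDF from the tabulated pmf.  The inner loop is compiled
with numba (a pure-Python fallback keeps the package importable without
it).  The kernel accumulates *exact* time-weighted first and second moments
per species over `[burn-in, T]`, plus the time integral of every channel
propensity, so stationary statistics require no stored path.  Optional
sampling modes store uniform-grid snapshots (default `Δt = 0.02/γ_f`, for
autocorrelation work) or the full event sequence (guarded to
`T ≤ 10³/γ_f`; grid mode is the memory-safe choice for long runs).

Defaults: initial condition at the rounded deterministic fixed point
(configurable to zeros), burn-in `10/γ_f` excluded from all stationary
statistics, replicate seeds `seed + replicate index` recorded in the
trajectory.  Identical (model, T, seed, sampling) inputs reproduce the
event sequence bit for bit.

## Estimators

Moments are occupation-measure (time-weighted) averages — event-weighted
sampling would bias toward fast-switching states.  Standard errors come
from across-replicate scatter only (no within-trajectory batching), which
is simple and conservative; they require ≥ 2 replicates.  The
autocorrelation estimator mean-subtracts each replicate, computes the
biased (1/n) autocovariance by FFT, normalizes by the replicate's own lag-0
variance, then averages curves across replicates; the biased normalization
is stable at large lags, and lags are restricted to a fifth of the
post-burn-in window.  The estimator carries an `O(τ_c/T)` downward bias
from per-replicate mean subtraction, so comparisons against analytic curves
should use windows `T ≳ 10³` correlation times (the tests use 1500 hr).
The flux-balance diagnostic checks the exact stationary identity
`k_x⟨B_x⟩ = γ_f⟨x_f⟩ + γ_b Σ⟨x_bᵢ⟩` within replicate scatter.

## CME oracle

For tiny models the stationary joint distribution is solved exactly on the
box `x_f ≤ x_max`, `x_bᵢ ≤ Nᵢ` (`y ≤ y_max`): the sparse truncated
generator's null space is found by replacing one balance row with the
normalization constraint and solving directly (exactness at small scale
beats iterative tolerance bookkeeping).  Jumps past the box are dropped;
the stationary probability flux they would carry, as a fraction of total
event flux, is the reported leak, and leak > 1e−6 raises an error
suggesting a larger box.  The oracle is restricted to ≤ 2.5×10⁵ states and
is used only in tests and `oracle-check` — never at production scale.

## Experiment layer and problem sizes

Experiments emit CSV + JSON metadata, never figures; a thin optional
matplotlib helper reads the CSVs.  Heatmap grids default to logarithmic in
`N` (1–10⁴) and `k_d` (10⁻¹–10³).  Default simulation sizes were chosen so
each stationary estimate rests on ≥ 10³ correlation times: tiny-model
oracle comparisons use 10 × 2000 hr, no-decoy Fano checks 8 × 2000 hr,
autocorrelation comparisons 10 × 1500 hr at `Δt = 0.02`, and the
twin-decoy comparison 8 × 1000 hr (strong decoys) and 4 × 250 hr (weak
decoys, whose binding traffic dominates the event count at ~1.8M events per
simulated hour).

## Design notes

- Estimator-style API was considered and rejected: the package is a
  simulator/analysis tool, not a fit/predict method.
- The deterministic fixed point, not the stochastic mean, anchors the LNA.
  For strongly-binding decoys with `β > 0` the two differ markedly: at
  `N = 245, k_d = 1, k_b = 50` the deterministic mean is ≈ 4.07 molecules
  while the simulated stationary mean is ≈ 14.5 — fluctuations keep the
  free pool far above the deterministic balance.  The LNA engine reports
  the deterministic value; the simulator is authoritative in this regime.
- Sweeps hold the *mean free TF* fixed by retuning `k_x` through the
  inverted mean relation; this keeps noise comparisons at matched
  operating points.

## Limitations

- The closed forms assume fast binding/unbinding; the LNA assumes small
  fluctuations.  Both degrade together for small `k_d` with `β > 0`, where
  only the SSA is quantitative.
- The target gene's dose-response is linear; saturating promoters are out
  of scope.
- No extrinsic noise (cell-size, machinery variation), no explicit cell
  division, no spatial effects, no tau-leaping or hybrid acceleration.
- Moment closures beyond the LNA are not implemented.
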