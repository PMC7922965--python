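# Methods

## Model

A particle diffuses in one dimension with a diffusion coefficient that is
itself a stochastic process: `D(t)` alternates between a fast value `D+`
and a slow value `D− < D+` (often `D− = 0`, a frozen state). Sojourn
durations in each state are i.i.d. draws from state-specific laws
`ψ±(τ)` with finite positive means `⟨τ⟩±`; successive sojourns are
independent (a renewal process). Conditioned on the history of `D(t)`,
the displacement over a window `[0, t]` is Gaussian,

    x(t) | T+ ~ N(0, 2 D+ T+ + 2 D− T−),     T+ + T− = t,

where `T+` is the occupation time of the fast state. All displacement
statistics therefore reduce to the law of the occupation fraction
`p+ = T+/t ∈ [0, 1]`, and the propagator is the Gaussian mixture

    P(x, t) = ∫₀¹ N(0, 2 D+ p t)(x) g_t(p) dp        (D− = 0),

where `g_t` generally carries point masses at `p = 0` (never left the slow
state; with `D− = 0` these particles contribute a δ(x) atom of
"non-movers") and at `p = 1` (never left the fast state).

### Initial conditions

Equilibrium initial conditions — the switching process started long before
the observation window — are central: the starting state is drawn with
probability `⟨τ⟩±/(⟨τ⟩+ + ⟨τ⟩−)` and the first observed sojourn follows
the forward-recurrence law `f_eq(τ₁) = S(τ₁)/⟨τ⟩` (S the survival
function). Ordinary (non-equilibrium) modes, where a fresh sojourn starts
at `t = 0` in a prescribed state, are supported by the simulator only; the
short-time universality below holds specifically for equilibrium starts.

## Occupation-fraction laws

* **Short times** (`t ≪ min⟨τ⟩±`): at most one switch matters. For *any*
  sojourn families with finite means,

      g_t(p) ≈ w₁ δ(1−p) + w₀ δ(p) + 2t/(⟨τ⟩+ + ⟨τ⟩−),

  with `w₁ = [⟨τ⟩+/(⟨τ⟩++⟨τ⟩−)](1 − t/⟨τ⟩+)` and `w₀` its mirror. The flat
  interior is the source of the propagator cusp. Only the means enter —
  the package asserts this family-independence explicitly.
* **Exponential sojourns, any `t`** (`g_exact_exponential`): closed form
  with modified Bessel functions `I₀, I₁` and the damping factor
  `exp(−tp/⟨τ⟩+ − t(1−p)/⟨τ⟩−)`; atoms `⟨τ⟩∓ e^{−t/⟨τ⟩∓}/(⟨τ⟩++⟨τ⟩−)`.
  Its `t → 0` expansion reproduces the flat law (the interior sup-norm gap
  decays as `t²`, which the suite fits), and equal means reduce it to the
  classical single-rate law to 1e−10.
* **Long times**: ergodicity concentrates `p+` on
  `⟨τ⟩+/(⟨τ⟩+ + ⟨τ⟩−)`; the mean of `g_t` sits there at *every* `t` under
  equilibrium, a quadrature-checked invariant. Note the *mode* of the
  exact law approaches this point slowly from the left (for
  `⟨τ⟩+ = 1, ⟨τ⟩− = 5` it is still ≈ 0.06 at `t = 10` and reaches 1/6
  only for `t ≳ 300`); "peaked at the stationary fraction" is an
  asymptotic statement.
* **Laplace-space forms**: the double transform of the `T+` law for
  exponential sojourns (rational in both variables) and the transform of
  the occupation-time difference `S_t = 2T+ − t` for equal means. These
  are cross-validation surfaces: the tests invert them numerically
  (analytic partial-fraction inversion in the occupation variable, then a
  Talbot contour in `s` via mpmath at 30 digits) and match the exact law
  to better than 1e−8. Complex arguments evaluate the analytic
  continuation so contour rules can use them; real arguments are
  validated against the convergence region.

## Propagators

* **Short-time closed form** (`propagator_short_time`, requires `D− = 0`):
  Gaussian (weight `w₁`) + δ(x) atom (weight `w₀`) + a unit-mass "tent"
  term `e^{−x²/4D+t}/√(πD+t) − (|x|/2D+t) erfc(|x|/√(4D+t))` with weight
  `2t/(⟨τ⟩++⟨τ⟩−)`. The three weights sum to one algebraically, so the
  default form normalises exactly. The `exponential_weights` flag swaps
  in `e^{−t/⟨τ⟩±}` prefactors (exact atom weights for exponential
  sojourns); that variant normalises only to `O(t²)` — the 1e−6
  normalisation invariant applies to the default form.
  Near the origin `P ≈ c₀ − c₁|x| + c₂x²` with
  `c₁ = 1/(D+(⟨τ⟩++⟨τ⟩−)) > 0`: a genuine non-analytic cusp, which the
  tests distinguish from smooth curvature by showing one-sided slopes
  converge while the central second difference diverges like `1/h`.
  The tent law is an asymptotic `t → 0` truncation: its deviation from
  the exact law is ≈ 1.5% of the peak at `t/⟨τ⟩ = 0.1` but ≈ 20% at
  `t/⟨τ⟩ = 0.5`, so high-statistics goodness-of-fit tests resolve it at
  the latter time even though overlay plots look fine.
* **Subordination quadrature** (`propagator_from_g`): adaptive quadrature
  of the Gaussian mixture with the substitution `p = w²` (absolute
  tolerance 1e−10) to tame the `p^{−1/2}` endpoint singularity.
* **Exact equal-means series** (`series_exact_equal_means`): expanding the
  Bessel functions of the exact occupation law and integrating term by
  term gives terms `k!·U(k+1, 1/2−k, x²/4D+t)` with Tricomi's confluent
  hypergeometric function; the series is truncated adaptively at relative
  contribution 1e−10 and agrees with the quadrature route to ~1e−12 over
  the tested range. (The two-₁F₁ decomposition of each `U` is equivalent
  but numerically worse; `Γ(1/2−k)` at negative half-integers is finite,
  so there is no pole issue.)
* **Long-time Gaussian**: variance `2 D_eff t` with
  `D_eff = (D+⟨τ⟩+ + D−⟨τ⟩−)/(⟨τ⟩+ + ⟨τ⟩−)`, always below `D+`.
* **Tails**: for equal-means exponential sojourns the far tail is the
  never-switching branch `½ e^{−t/⟨τ⟩} N(0, 2D+t)`; the density/tail
  ratio decreases monotonically to 1 (checked at 5, 7, 10 σ).
* **Super-statistics baseline**: an exponential mixture of static
  diffusivities gives the Laplace density `e^{−|x|/√(⟨D⟩t)}/√(4⟨D⟩t)` —
  log-linear everywhere, which the two-state tent is not; the suite
  contrasts the two at 5σ.
* **MSD**: `⟨x²(t)⟩ = 2 D_eff t`, exact at all `t` under equilibrium. The
  factor 2 follows from the conditional-Gaussian construction and from
  the long-time variance; the simulator confirms it (an alternative
  normalisation without the 2 is inconsistent with both).

## Simulation

Renewal sequences are drawn in vectorised blocks; the first sojourn uses
the forward-recurrence law in equilibrium mode. For the named families the
forward-recurrence draw uses the exact length-biased construction — the
interval covering a stationary time point is length-biased, and the point
is uniform within it — giving `Gamma(2, m)·U` for exponential,
`√(a² + U(b²−a²))·U'` for uniform, `Gamma(k+1, θ)·U` for gamma. Custom
laws fall back to inverse-CDF root-finding (tolerance 1e−10 in time
units); heavy-tailed laws with infinite mean are rejected at construction
because every result here assumes finite first moments.

Paths on a uniform grid integrate `D(t)` exactly across each step from the
underlying switch times (via the piecewise-linear cumulative fast-state
occupancy), so the sampler is exact in distribution at any `dt`; a step
wholly inside a frozen `D− = 0` interval is exactly zero. The open
(uncompleted) sojourn at the end of the window is truncated, never
resampled; its elapsed part `τ*` is the backward recurrence time.

All randomness flows through a caller-supplied `numpy` Generator; ensemble
runs derive per-stream seeds with `SeedSequence.spawn`, making outputs
byte-reproducible for a fixed seed.

## TAMSD protocol

Each trajectory's time-averaged MSD is computed over all sliding windows
at lags that are multiples of the grid step, and a diffusivity is fitted
by least squares through the origin, `tamsd = 2 D Δ`, clipped at zero.
Defaults: grid step `dt = 0.01·min⟨τ⟩±` (resolving the faster state), fit
window `Δ ∈ [dt, t/100]` with ~20 geometrically spaced lags, histogram of
30 equal bins on `[0, D+]`. Under equilibrium the ensemble-mean TAMSD is
`2 D_eff Δ` at every lag, so the mean fitted `D` estimates `D_eff`
regardless of the window; the window choice mainly controls per-trajectory
scatter. The reference runs use 1000 trajectories of length `t = 1000`.

## What the generator does and does not emulate

The synthetic trajectories realise the model exactly: two states, renewal
switching, Gaussian increments, no drift, no localisation noise, no finite
exposure-time blur, and no more than two states. Passing tests therefore
validate the mathematics and the implementation, not the applicability of
the two-state renewal description to any particular experimental system;
with real tracking data the TAMSD module can be applied to external
trajectory files, but cusp detection near `x = 0` would additionally
require resolving the non-mover atom against localisation error.

## Numerical choices and degenerate inputs

- Bessel factors use the exponentially scaled `i0e/i1e` with the damping
  collected in one exponent, so `t/⟨τ⟩ ≫ 1` cannot overflow; the
  removable `I₁(z)/z` endpoint singularity is replaced by its limit for
  `z < 1e−8`.
- Interval probabilities flag the origin as a quadrature breakpoint (the
  density kink) and add the atom only when the interval straddles 0.
- `D+ = D−` is allowed (the degenerate single-diffusivity limit used in
  consistency checks); `D+ > 0` and `D+ ≥ D− ≥ 0` are required.
- Short-time laws warn outside `t < min⟨τ⟩±` and raise in `strict` mode;
  for `t ≥ ⟨τ⟩+` the polynomial atom weight would go negative and
  construction fails.
- Writers emit `%.17g` so read-back is lossless at double precision;
  point masses travel in `#` header metadata and are never binned into a
  histogram column.

## Problem sizes in the suite

Unit tests use ensembles of 2·10⁴–2·10⁵ endpoint draws and a few hundred
paths; the end-to-end checks use 10⁵–10⁶ endpoint draws and the full
1000-trajectory TAMSD protocol. These sizes give standard errors a factor
of a few below every asserted tolerance while keeping the whole suite
under a minute apart from the TAMSD ensembles.
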