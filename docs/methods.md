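# Methods

## The model

Reaching is reduced to the motion of an overdamped particle in the bistable
potential

    V(x) = -a x²/2 + b x⁴/4,        a = b = 1 by default,

whose minima at x = ±√(a/b) represent the resting position (x = -1) and the
target position (x = +1) of the arm; the barrier between them has height
ΔV = a²/(4b) (0.25 at defaults, with V(±1) = -0.25).  A trial integrates the
Langevin equation

    dx = ε [a x - b x³ + s(t)] dt + √ε ψ(t) dW,

where s(t) is the "will" kick — a single half-sinusoid of amplitude A₀ and
duration T ms — and ψ is gated noise, active only while the kick is on.
After the window the state relaxes noise-free until it settles into one
basin; the trial is a *reach* iff the settled state lies in the target basin
(x_final > 0).  With the gate closed the relaxation is a deterministic
gradient flow whose basins split exactly at x = 0, which makes the reach
criterion unambiguous.

The kick is sub-threshold by construction.  A constant forcing ξ₀ destroys
the left well at the saddle-node value ξ₀* = (2a/3)√(a/(3b)); for a = b = 1
this is 2/(3√3) ≈ 0.3849, and the default A₀ = 0.25 lies safely below it.
(A value of ±0.366 is sometimes quoted for this threshold from the same
construction — first and second derivative vanishing together — but
carrying the construction through gives 0.3849, which the implementation
returns and verifies against an equilibrium-counting bisection oracle.  The
qualitative conclusion, 0.25 being sub-threshold, is unaffected.)

The rate gain ε multiplies the whole update (drift and kick, with the noise
variance scaled by ε as well), i.e. it is a pure time rescale of the
dynamics.  This is the placement consistent with the reference behaviour of
the ε sweep: a larger gain acts like a longer effective stimulus window and
moves the reach-probability peak to smaller noise levels, exactly as longer
durations T do.  Placing ε on the gradient alone does the opposite (it
deepens the effective well, pushing the peak to larger noise) and makes the
default kick supra-threshold for ε < 0.65, so that reading was rejected.

## Integration and calibration

Euler–Maruyama with step dt = 0.1 (model time units), `steps_per_ms = 4`
integration steps per ms of stimulus time, so one ms of protocol time is
Δ = 0.4 model time units.  After the window, `relax_steps = 2000` steps
(500 ms) of noise-free settling follow — ample for convergence to within
`settle_tol = 1e-3` of a minimum from anywhere in the admissible range.
States are monitored every few steps; |x| > 50 aborts the trial with a
diagnostic rather than letting overflow propagate (unreachable at the
documented parameter ranges: the dt = 0.1 explicit Euler step is stable up
to |x| ≈ 4.5 and the stationary spread at the largest default noise level
keeps |x| ≲ 2.5).

The experiment protocol fixes the *operational* noise axis D (the abscissa
of the reach-probability curves) but not the discretisation, so the mapping
from D to the injected noise is a calibration of the model, set once
against the reference results this package reproduces:

- **White noise.**  Per-step injection √(ε dt)·g·D·η with η ~ N(0,1) and
  gain g = 0.087 per unit D.  Equivalently, the Langevin noise intensity is
  θ = ε (gD)²/2.  The pair (Δ = 0.4, g = 0.087) was chosen so that the
  T = 1000 ms white-noise curve peaks at D ≈ 3.2 with peak P ≈ 0.99, the
  reference operating point; with these two constants fixed, the whole
  duration dependence (T = 100 … 10000) and the high-noise tail (P → 1/2)
  follow without further adjustment.  The two constants are genuinely
  independent: the window length in model time controls the attainable peak
  probability, the gain controls where on the D axis the peak sits.
- **Colored noise.**  A discrete Ornstein–Uhlenbeck (AR(1)) process per
  integration step, c_{n+1} = (1-λ) c_n + inj·η_n with c_0 = 0, injected
  like a smooth forcing (√(ε dt)·c per step).  λ = 1/60 per sample — a
  correlation time of ≈ 15 ms — and the injection amplitude is set so the
  stationary SD of c is 0.008·D.  These two constants were calibrated so
  the colored T = 1000 curve peaks near D = 7.3 with peak P ≈ 0.96; the
  remaining colored rows (T = 100 … 750) then match the reference trend
  with no further tuning.  A correlation time equal to the stimulus window
  (λ = 0.001 at a per-ms cadence, the often-stated per-ms recursion constant) makes
  the colored forcing an essentially frozen random bias over the trial and
  caps the attainable peak probability near 0.6 at *any* amplitude — far
  below the reference 0.96 — so the correlation time has to be treated as a
  calibration constant rather than a literal transcription.

Reproducibility: trial i of a Monte-Carlo estimate draws from
`default_rng([*seed, i])`; grid point j of a sweep uses `[master_seed, j]`.
Estimates are therefore independent of chunking and bit-identical across
reruns; sweeps can be parallelised per point without changing results.

## Experiment protocol

`P(D)` is the fraction of reaches over `n_trials` (default 1000, the
reference trial count) per grid point, on D = 0, 0.2, …, 10.  Curves are
supersampled by inserting linear midpoints (step 0.2 → 0.1) and smoothed by
a centred moving average of odd width WIN (9 white, 15 colored); windows are
truncated at the curve ends, so constants are preserved and no padding
value is invented.  The peak is the grid argmax of the smoothed curve, ties
broken toward the smaller noise level.  The fractional-time metric is the
fraction of integration steps (relaxation included) spent within a
tolerance (default 0.1) of the target minimum.

## The reaching model

The full actor-critic model the reduction comes from: a planar two-link arm
whose joint angles are logistic functions of the agonist–antagonist
activation differences (θ₁ from g₁-g₂, θ₂ from g₃-g₄), a motor-cortex
perceptron g_m = σ(Wξ) keyed by a one-hot target-selection vector, and a
basal-ganglia output g_bg updated by the Go/Explore/NoGo rule on the
dopamine (TD-error) signal δ = r + γV(t) - V(t-1), with the critic
V = exp(-d²/σ_V²) of the Euclidean distance d to the target and reward
r = A inside R_small.  Go (δ > D_hi) repeats the previous increment, NoGo
(δ < D_lo) reverses it, Explore (in between) draws a random 4-vector of
norm η; a momentum term κ·Δg(t-1) is added, and the accumulated g_bg is
kept in the admissible activation box [0,1]⁴ — activations are bounded
neural drives, and without the bound exploration drifts deep into the
saturated, value-flat region of the activation-to-angle map and stalls.
An episode ends at d < R_tol or after `max_steps`.

The reaching constants have no reference values; the defaults (A = 1,
R_small = 0.15, R_tol = 0.1, D_hi = -D_lo = 0.005, η = 0.08, κ = 0.3,
η_m = 1, σ_V = 1, max_steps = 2000, targets = endpoints of four canonical
activation patterns, hence reachable by construction) were chosen so the
untrained, basal-ganglia-driven model reaches in ≥ 80 % of episodes within
the budget.  Training is phased as the source describes qualitatively:
episodes run BG-dominant (α = 0.1, β = 1); each successful reach supplies
its activation vector as the delta-rule target for the cortex
(η_m-gradient through the logistic output, target clipped into the output
range); performance is evaluated cortex-dominant (α = 1, β = 0.2) on a
short budget (100 steps), where a trained cortex reaches almost immediately
and the basal ganglia alone usually cannot.  The Go/NoGo pair without
momentum admits a two-point limit cycle (repeat–overshoot–reverse), which
is why κ > 0 is the default and why the hill-climbing property is asserted
in its one-step form (an explore step that raised the value, repeated once,
keeps raising it in expectation).

## Theory oracles

`kramers_rate` uses the standard overdamped prefactor from the well and
barrier curvatures of the quartic potential, a/(√2 π) (no reference
value exists for the prefactor; the formula is used only for trend
checks, never as an acceptance number).  `stationary_variance` integrates
the Boltzmann density by adaptive quadrature on a range truncated where the
weight is below ~e⁻⁶⁰ of the peak, and is cross-checked against a dense
two-resolution Riemann oracle to 1e-8.  The linear-response amplitude
combines the two; its closed form exhibits the interior maximum in D and
the monotone loss with forcing frequency that the simulation's peak trends
mirror.

## What the simulations do and do not show

All inputs are synthetic by design — the study is a model exploration, not
a data fit.  Passing tests demonstrate the internal phenomenology of the
model (noise-assisted switching, its calibrated operating point, the
duration/colour/gain trends, and the learning dynamics of the reaching
loop); they say nothing about physiological parameter values.  Monte-Carlo
checks run at 300–1000 trials per point, so asserted margins are several
binomial standard errors wide; peak *locations* at the default grid retain
a quantisation of 0.1 in D.  The colored-noise correlation time and both
noise gains are calibrated constants (above), not derived quantities; the
white T = 100 peak sits ~0.4 D-units left of its reference value (5.6), within the
run-to-run spread at 1000 trials but possibly reflecting residual
discretisation mismatch.  No multistable (>2 well) potentials,
position-dependent noise, or 3-D target continua are modelled.
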