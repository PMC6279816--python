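# Methods

## Model

The package implements two-dimensional active Brownian motion with explicit
translational and rotational inertia. The centre of mass `R(t)` and body
orientation angle `φ(t)` obey

    M R̈ + ξ Ṙ   = ξ V_p n(φ) + ξ √(2D)  f(t),      n = (cos φ, sin φ),
    J φ̈ + ξ_r φ̇ = τ_0        + ξ_r √(2D_r) η(t),

with independent Gaussian white noises `f` (vector) and `η` (scalar).
Because both equations can be divided by their friction coefficients,
trajectories identify only six parameters, and the package is parameterised
by them throughout:

| symbol | meaning | unit | generic preset |
| --- | --- | --- | --- |
| `tau`   | velocity relaxation time `M/ξ`   | s | 1/6.46 ≈ 0.155 |
| `tau_r` | angular relaxation time `J/ξ_r`  | s | 1/5.4 ≈ 0.185 |
| `D`     | translational short-time diffusivity | m²/s | 8×10⁻⁵ |
| `D_r`   | rotational diffusivity | rad²/s | 2.59 |
| `V_p`   | propulsion speed | m/s | 0.092 |
| `omega` | mean angular velocity `τ_0/ξ_r` | rad/s | 0.7 |

Absolute scales (`M`, `J`, `ξ`, `ξ_r`, `τ_0`) are accepted as optional,
mutually-checked metadata. Angles are stored unwrapped in radians; `D_r`
values quoted in 1/s are interpreted as rad²/s. The dimensionless delay
numbers `D0 = D_r τ_r`, `D1 = ω τ_r`, `D2 = τ_r/τ` compare rotational
diffusion, circling and velocity relaxation to the angular relaxation time.

Model assumptions worth keeping in mind: scalar (isotropic) friction and
diffusion tensors, a constant body-fixed propulsion speed, a constant
external torque, no particle interactions, walls or alignment couplings.

## Closed forms and their numerics

* **Orientational correlation.** `⟨n(t+s)·n(s)⟩ =
  cos(ωt) exp(−D_r(t − τ_r(1 − e^{−t/τ_r})))`; the inner exponential is the
  inertial memory of the angular velocity. The conditional two-time version
  (given the initial spin) is evaluated exactly and reduces to the
  stationary form for late times — verified in the tests, including that it
  equals 1 at equal times.

* **Incomplete gamma at complex order.** Every closed form funnels through
  `γ(s, x) = ∫₀ˣ t^{s−1}e^{−t}dt` with `Im s ∝ ω`. SciPy covers only real
  orders, so the package evaluates the confluent series
  `γ = x^s e^{−x} h(s,x)/s` for `x ≤ 256` or `Re s ≥ x`, and
  `Γ(s) − Γ(s, x)` with a Lentz continued fraction otherwise; orders with
  `Re s ≤ 1/2` are reached by the upward recurrence. Accuracy target 1e-10,
  checked against adaptive quadrature of the defining integral. Two scaled
  combinations are exposed because they are what the physics needs:
  `x^{−s}γ(s,x)` (finite limit `1/s` at `x → 0`, which resolves the
  removable `D0 → 0` singularities) and `e^x x^{−s} γ(s,x)` (bounded for
  large `D0`, where the bare factors overflow).

* **Kinetic energy and `f`.** `⟨Ṙ²⟩ = 2D/τ + f(D0,D1,D2) V_p²` with
  `f = D2 e^{D0} Re[D0^{−s} γ(s, D0)]`, `s = D0 − iD1 + D2`. For
  `D0 < 1e-10` the rational limit `f = D2(D0+D2)/((D0+D2)² + D1²)` is used
  (exact at `D0 = 0`, avoids subnormal-division overflow). The printed
  small-/large-inertia truncations of the energy hold in the torque-free
  case; with circling the large-`J` active share saturates at
  `V_p²/(1+(ωτ)²)` — the tests exercise the limits at `ω = 0`.

* **Long-time diffusion.** `D_L = D + (V_p²/2) t_p` with persistence time
  `t_p = τ_r e^{D0} Re[D0^{−(D0−iD1)} γ(D0−iD1, D0)]`. `D_r = ω = 0` is
  reported as infinite persistence rather than an error. The small-`J`
  linear form and the large-`J` `√J` asymptote are provided as explicit
  truncations, both expressible through `τ_r` alone (no absolute scales
  required).

* **Delay function.** `C(t) = ⟨Ṙ(t)·n(0)⟩ − ⟨Ṙ(0)·n(t)⟩` has a closed form
  with four incomplete-gamma terms. Evaluated literally it overflows and
  hits genuine poles of `γ(s,·)` at special parameter ratios (e.g. the
  torque-free preset lands exactly on `s = −1`), so the implementation
  regroups it into bounded pieces: the two terms of order `s₊ = D0−iD1+D2`
  use the exp-scaled gamma with all exponentials combined (every exponent is
  ≤ 0 for t ≥ 0), and the `s₋ = D0−iD1−D2` pair — individually divergent,
  jointly finite — is mapped by `u = D0 e^{−v/τ_r}` onto a single bounded
  integral evaluated by adaptive quadrature. The result was cross-checked to
  machine precision against an independent derivation (convolution of the
  orientational correlation with the exponential velocity kernel), which
  also serves as the oracle in the test suite. The `D0 → 0` limit is the
  closed sinusoid `C = V_p D2 Re[(e^{−t/τ} − e^{iωt})(1/s₊ + 1/s₋)]`.

* **Mean squared displacement.** The conditional MSD (given initial velocity
  and spin) reduces the four-fold active integral analytically to
  `V_p² ∬ (1−e^{(a−t)/τ})(1−e^{(b−t)/τ}) ⟨n(a)·n(b)⟩ da db`, evaluated by
  Gauss–Legendre tensor quadrature with order doubling to a 1e-6 relative
  target. The *stationary* (time-averaged) MSD is computed from the
  stationary velocity autocorrelation,
  `MSD(t) = 2∫₀ᵗ (t−s) Z(s) ds`,
  `Z(s) = (2D/τ)e^{−s/τ} + (V_p²/2τ)∫ e^{−|w|/τ} g(|w−s|) dw`,
  with the passive part in closed form. This replaces the originally
  planned Gauss–Hermite average of the conditional MSD over stationary
  initial conditions: the stationary joint law of velocity and orientation
  is *not* Gaussian (that is the whole point of the mixture velocity
  distribution), so the autocorrelation route is both exact and cheaper.
  When the lag exceeds ~50 τ the exponential kernel acts as a delta and
  `Z → V_p² g(s)`; the outer integral is truncated once the orientational
  correlation has decayed (45 correlation times). This keeps the evaluation
  accurate across the six decades of scale separation probed by the
  reduced-density preset.

* **Velocity distributions.** The stationary one-component law is the
  uniform-phase mixture `P(ẋ) = ∫ dφ/2π N(ẋ; W cos φ, q)` (evaluated by
  Chebyshev–Gauss quadrature, exact for this mixture), and the speed law is
  the corresponding Rice distribution. `(q, W)` are matched to the model's
  second and fourth velocity moments, which solve in closed form:
  `W⁴ = (8/3)(3m₂² − m₄)`, `q = m₂ − W²/2`. The second moment is exact
  (via `f`); the fourth moment of the active component has no printed closed
  form and is estimated by Monte Carlo: exact rotational OU paths are
  integrated against the velocity-relaxation kernel. The paths depend only
  on `(D_r, τ_r, ω)` and a fixed seed, so one cached ensemble serves every
  `(τ, D, V_p)` queried during fitting, and the estimate is deterministic.
  Infeasible moment equations (sampling noise near the Gaussian boundary)
  are signalled; the fit falls back to the Gaussian `W = 0`.

## Simulator

The rotational pair `(φ, φ̇)` is an integrated Ornstein–Uhlenbeck process and
is advanced by its exact conditional Gaussian transition, including the
angle/angular-velocity cross-covariance. The translational velocity uses the
exact OU transition toward `V_p n` with the orientation frozen at the step's
start; the position update is the exact integrated-OU one under that freeze.
The only discretisation error is therefore the O(dt²) local splitting error
of the freeze — there is no stiffness constraint from the friction rates. A
step larger than a tenth of the fastest time scale raises a warning (or an
error in strict mode). Default guidance is `dt ≈ min(τ, τ_r)/50`.

Initial conditions: `rest` (zero velocity and spin — the start-up
experiment), `stationary` (uniform angle, stationary Gaussian spin, then a
burn-in of `10·max(τ, τ_r, 1/D_r)` before recording), or `explicit`.
Randomness: run `i` uses `numpy.random.default_rng([seed, i])`, so ensembles
are order-independent and bitwise reproducible; each run consumes its
stream in a fixed per-step order.

## Empirical estimators

Velocities are finite differences over `k` frames,
`v(t) = (r(t+kΔt) − r(t))/(kΔt)`, matching camera tracking; the angular
velocity likewise on the unwrapped angle. MSDs are time-averaged over all
start times within a run and then ensemble-averaged, with s.e.m. bands from
the between-run scatter (the standard single-particle-tracking convention;
the averaging convention is a package choice). Histograms are per-run
densities averaged across runs, with Freedman–Diaconis bins by default; for
the one-component velocity law each run is rotated by a run-specific random
angle (recorded seed) and both components are pooled. An optional
measurement-noise emulation adds Gaussian position noise of 4.7×10⁻⁴ m and
angle noise of 0.013 rad — typical sub-pixel tracking accuracies — and is
off by default.

## Inference

Stage 1 (rotation): `ω` is the first moment of the angular-velocity
histogram; `(D_r, τ_r)` minimise the s.e.m.-weighted squared error of the
stationary angular MSD model `ω²t² + 2D_r(t − τ_r(1 − e^{−t/τ_r}))` in log
parameters. A drift-only angular MSD (noise-free rotator) returns
`D_r = 0` with `τ_r` reported as unidentifiable; a flat MSD is an error.

Stage 2 (translation): the iterative scheme starts from `V_p = √⟨Ṙ²⟩`,
`f = 1`; each iteration fits `(τ, D)` to the one-component velocity law,
then forms two candidates — branch A keeps `f = 1`
(`V_p = √(⟨Ṙ²⟩ − 2D/τ)`, the lower bound), branch B evaluates `f` at the
current parameters (`V_p = √((⟨Ṙ²⟩ − 2D/τ)/f)`, the upper bound). Each
branch re-applies its rule at its own refit `(τ, D)`, so the accepted
iterate sits exactly on its end of the `f`-bounds interval. Candidates are
scored by s.e.m.-weighted MSE against the translational MSD and the speed
law; the worse is discarded. Iteration stops when the tracked curves agree
below the standard error (weighted MSE ≤ 1), when parameters move less than
1e-3 relative, or at a cap of 50 iterations (the cap is a package choice).
Ties prefer branch B, the physically complete rule.

After the branch iteration converges, (τ, D) are refit once more against
the velocity law *and* the translational MSD jointly at the accepted `V_p`
(the velocity distribution alone pins essentially only `D/τ`; the MSD
crossover separates the two). The MSD weights carry a 1% relative-error
floor: time-averaged MSD points can have sub-percent standard errors, which
would otherwise let tiny biases of the parameters held fixed dominate the
fit. Because measured velocities are finite differences over a window `h`,
the model's prediction for their moments is `MSD(h)/h²`; the thermal part
of that window correction is applied to `q` exactly and the measured
`⟨Ṙ²⟩` entering the `V_p` rules is de-biased with the model's own window
ratio.

Known boundary behaviour: for truly passive data (`V_p = 0`) the update
`V_p = √(max(⟨Ṙ²⟩ − 2D/τ, 0))` takes the square root of a noisy
non-negative excess and is therefore positively biased; the surviving
spurious activity loosens the recovery of (τ, D) to the 20–25% level at
moderate ensemble sizes, while `V_p` itself remains consistent with zero.
Active-regime recovery is unaffected.

Full fit: Nelder–Mead over (log τ, log τ_r, log D, log D_r, log V_p, ω)
minimising the weighted sum of mean squared errors of all six empirical
curves, *including the delay function*. Model curves come from simulation at
the empirical sampling interval (sub-stepped if that interval is coarser
than a tenth of the fastest candidate time scale) with common random numbers
— one fixed inner seed — so the objective is deterministic and the simplex
sees no stochastic jitter. The fixed inner realisation does bias the
optimum at the scale of the inner ensemble's own sampling error, so the
inner ensemble should carry at least as much statistical information as the
data being fitted; the recovery checks use 192 inner runs of 8192 frames
against 100 data runs of 10⁴ frames, a size chosen so that this bias stays
inside the recovery tolerances. Default weights are `1/sem²` pointwise,
which puts every observable on its own noise scale; the weight vector is
overridable and an all-zero one is rejected. If the evaluation budget ends
before convergence, the best-so-far parameters are returned with a flag.

Uncertainties: for each parameter, the two-sided variation (others fixed)
that quadruples the minimal weighted MSE, found by doubling steps plus
bisection; a direction that never reaches the threshold is reported as an
open interval. For an ideal quadratic objective this gives `θ* ± s√3`, which
the tests verify.

## Synthetic-data conditions

The simulator doubles as the synthetic-data source; no experimental
trajectories ship with the package. The presets are the two printed
parameter sets: the generic-particle set (`fig2`, circling, strong
rotational noise) and the torque-free density-sweep set (`fig6`, with
absolute scales `M₀ = 4 g`, `J₀ = 1.5×10⁻⁷ kg m²`); `fig6_scaled(fraction)`
reduces the material density, shrinking `τ` and `τ_r` by the common fraction
at fixed `ξ`, `ξ_r`, `D`, `D_r`, `V_p`, `ω`. Synthetic ensembles used in the
tests sample at the experimental camera interval `Δt₀ = 0.0066 s`; the
recovery checks use 100 runs × 10⁴ frames (≈ 66 s per run, a few hundred
orientational correlation times) and smaller ensembles elsewhere, sized so
the whole suite runs in minutes on one core. What passing tests show: the
estimators converge to the closed forms *for data generated by this model* —
ideal sampling, no tracking noise (unless the emulation is switched on), no
boundary collisions, no anisotropy. Real tracking data additionally carry
localisation noise, frame drops and wall events that the package does not
filter.

## Known limitations

* The conditional-MSD quadrature resolves the near-diagonal correlation
  ridge only up to Gauss–Legendre order 512; for lags thousands of times
  beyond all relaxation scales use the stationary MSD (exact by
  construction there).
* `match_qW` carries the Monte-Carlo error of the fourth moment (~1–2% with
  the default 16384 paths); near `W → 0` the moment equations may become
  infeasible at that noise level, in which case the Gaussian fallback is
  used.
* The mixture velocity law is an ansatz for the stationary one-component
  distribution; it matches the second and fourth moments and reproduces
  simulated histograms to total-variation distance < 0.02 at the generic
  preset, but it is not the exact solution of the stationary kinetic
  equation.
* Pure circle swimmers (`D_r = 0`, `ω ≠ 0`) have an oscillatory, non-decaying
  orientational correlation; the stationary-MSD integrator then integrates
  the full lag range, which is accurate but slow for very long times, and
  `D_L` is reported via a vanishing persistence time (`D_L = D`).
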