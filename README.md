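# inertial-abp

Underdamped (inertial) active Brownian motion for macroscopic self-propelled
particles: an exact-transition Langevin simulator, the closed-form analytic
toolbox, empirical trajectory statistics, and trajectory-based parameter
inference.

## The problem

Micron-scale swimmers are overdamped: their velocity is slaved to the
propulsion direction. Macroscopic self-propelled particles — vibration-driven
granular robots ("vibrobots"), floating or levitating grains, flying insects —
are not. Their mass `M` and moment of inertia `J` produce finite relaxation
times, with two observable consequences:

1. **Inertial delay** — the velocity direction Θ systematically lags the body
   orientation φ, like a drifting race car.
2. **Inertia-dependent diffusion** — the long-time diffusion coefficient grows
   with `J` (without bound, as √J), because rotational inertia prolongs the
   persistence of the propulsion direction.

The model is the underdamped Langevin pair

```
M R̈ + ξ Ṙ   = ξ V_p n(φ) + ξ √(2D)  f(t)
J φ̈ + ξ_r φ̇ = τ_0        + ξ_r √(2D_r) η(t)
```

with white noises `f, η`. Trajectories identify six rates: the friction times
`τ = M/ξ`, `τ_r = J/ξ_r`, diffusivities `D`, `D_r`, propulsion speed `V_p`
and mean angular velocity `ω = τ_0/ξ_r`. The dimensionless delay numbers

```
D0 = D_r τ_r,   D1 = ω τ_r,   D2 = τ_r / τ
```

control everything: the stationary kinetic energy is
`⟨Ṙ²⟩ = 2D/τ + f(D0,D1,D2) V_p²` with `f ∈ [0,1]` built from the lower
incomplete gamma function at complex order, and the long-time diffusivity is
`D_L = D + (V_p²/2) t_p` with a persistence time `t_p` of the same structure.

## Layout

| module | contents |
| --- | --- |
| `inertial_abp.params` | `ModelParams`, delay numbers, config I/O |
| `inertial_abp.gammainc` | lower incomplete gamma for complex order |
| `inertial_abp.analytics` | correlations, `f`, `D_L`, MSDs, delay function, velocity laws |
| `inertial_abp.simulate` | exact-transition simulator, ensembles, printed parameter presets |
| `inertial_abp.stats` | finite-difference velocities, empirical MSDs/histograms/delay, CSV I/O |
| `inertial_abp.inference` | rotational fit, iterative f-bounded fit, simplex refinement, uncertainties |

## Worked example

```python
import numpy as np
from inertial_abp import (SimConfig, simulate_ensemble, compute_curveset,
                          delay_function_analytic, fit_rotational,
                          fit_translational_iterative, velocity_second_moment)
from inertial_abp.simulate import preset

p = preset("fig2")            # generic vibrobot: tau=0.155 s, tau_r=0.185 s,
                              # D=8e-5 m^2/s, D_r=2.59 1/s, V_p=0.092 m/s, omega=0.7 1/s
print(round(velocity_second_moment(p), 6))        # 0.008264  (m/s)^2

t = np.linspace(0, 2, 2001)
c = delay_function_analytic(p, t)
print(round(t[np.argmax(c)], 3), round(c.max(), 4))   # 0.343 0.0313

ens = simulate_ensemble(p, SimConfig(dt=0.0066, n_steps=8000, n_runs=72,
                                     seed=77, init_mode="stationary"))
lags = np.unique(np.round(np.geomspace(1, 7500, 55)).astype(int))
curves = compute_curveset(ens, k=1, msd_lags=lags, delay_lags=np.arange(0, 150, 3))
D_r, tau_r, omega = fit_rotational(curves)
D, tau, V_p, _ = fit_translational_iterative(curves, (D_r, tau_r, omega))
print([round(v, 4) for v in (D_r, tau_r, omega, tau, V_p)])
# [2.621, 0.1855, 0.7174, 0.13, 0.0896]
```

Reading: the stationary speed-squared of the generic particle is
0.008264 (m/s)² — noticeably below the naive `2D/τ + V_p²` because only the
fraction `f ≈ 0.854` of the injected kinetic energy survives orientational
decorrelation. The velocity lags the orientation with a peak delay
correlation at 0.343 s, the same order as the friction times. The staged fit
recovers the rotational rates and `V_p` within a few percent from 72
synthetic runs; `τ` (here 0.130 vs the true 0.155 s) is the least
constrained parameter — the velocity law mostly pins the ratio `D/τ` — and
is tightened by the full simplex fit (`fit_full`), which also uses the
delay curve.

The same steps are available from a shell:

```sh
inertial-abp simulate --preset fig2 --dt 0.0066 --n-steps 8000 --runs 72 \
    --seed 77 --out traj.csv
inertial-abp analyze traj.csv --out curves/
inertial-abp fit curves/ --staged --out fit.json
inertial-abp compare --preset fig2 --what delay --t-max 2 --out delay.csv
```

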