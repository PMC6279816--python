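"""Trajectory generation for the underdamped active Brownian particle.

The rotational degree of freedom (phi, phi_dot) is an integrated
Ornstein-Uhlenbeck process and is advanced by its *exact* conditional
Gaussian transition, including the position-velocity cross-covariance.  The
translational velocity is likewise an OU process relaxing towards
V_p n(t); it is advanced by the exact OU transition with the orientation
frozen at the step's start, so the only discretisation error is the O(dt^2)
splitting error of that freeze.  This removes the stiffness of naive
Euler-Maruyama schemes: the step size only needs to resolve the physical
time scales, not the friction rates.

Randomness contract: every run gets its own generator seeded by
``np.random.default_rng([seed, run_index])``, so ensembles are
order-independent and bitwise reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams, ParticleState

__all__ = [
    "SimConfig",
    "Trajectory",
    "Ensemble",
    "step_rotation",
    "step_translation",
    "simulate",
    "simulate_ensemble",
    "preset",
    "PRESETS",
]


@dataclass
class SimConfig:
    """Simulation controls.

    dt : step size, s.  Must resolve the friction times; by default a
        warning is raised when dt exceeds a tenth of the fastest scale
        (``strict=True`` upgrades that to an error).
    n_steps : number of steps (trajectory has n_steps + 1 samples).
    n_runs : ensemble size.
    seed : base seed of the per-run generator streams.
    init_mode : "rest" (R' = 0, phi = 0, phi_dot = 0 — the start-up
        experiment), "stationary" (phi uniform, phi_dot from its stationary
        Gaussian, followed by a burn-in before recording), or "explicit".
    burn_in : burn-in time for stationary mode, s; default
        10 max(tau, tau_r, 1/D_r).
    record_every : keep every k-th sample (dt_out = k dt).
    """

    dt: float
    n_steps: int
    n_runs: int = 1
    seed: int = 0
    init_mode: str = "rest"
    explicit_init: ParticleState | None = None
    burn_in: float | None = None
    record_every: int = 1
    store_velocities: bool = False
    strict: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt!r}")
        if self.n_steps < 1 or self.n_runs < 1 or self.record_every < 1:
            raise ValueError("n_steps, n_runs and record_every must be >= 1")
        if self.init_mode not in ("rest", "stationary", "explicit"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.init_mode == "explicit" and self.explicit_init is None:
            raise ValueError("explicit init_mode requires explicit_init")

    def check_dt(self, p: ModelParams) -> None:
        scales = [p.tau, p.tau_r]
        if p.D_r > 0:
            scales.append(1.0 / p.D_r)
        limit = 0.1 * min(scales)
        if self.dt > limit:
            msg = (
                f"dt = {self.dt:g} s exceeds a tenth of the fastest time scale "
                f"({min(scales):g} s); orientation-freeze splitting error may be visible"
            )
            if self.strict:
                raise ValueError(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=3)


@dataclass
class Trajectory:
    """A single sampled trajectory (uniform times, unwrapped angle)."""

    params: ModelParams
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    phi_dot: np.ndarray | None = None
    run_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-9):
            raise ValueError("trajectory times must be uniform and strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Ensemble:
    """A set of runs with a common sampling grid, stored as (n_runs, n_samples) arrays."""

    params: ModelParams | None
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    phi_dot: np.ndarray | None = None
    vx: np.ndarray | None = None
    vy: np.ndarray | None = None
    run_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("x", "y", "phi"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != len(self.times):
                raise ValueError(f"{name} must have shape (n_runs, n_samples)")
            setattr(self, name, arr)
        if not self.run_ids:
            self.run_ids = list(range(self.x.shape[0]))

    @property
    def n_runs(self) -> int:
        return self.x.shape[0]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __iter__(self):
        for i in range(self.n_runs):
            yield Trajectory(
                params=self.params,
                times=self.times,
                x=self.x[i],
                y=self.y[i],
                phi=self.phi[i],
                phi_dot=None if self.phi_dot is None else self.phi_dot[i],
                run_id=self.run_ids[i],
            )


# ---------------------------------------------------------------------------
# exact one-step transitions
# ---------------------------------------------------------------------------

def _ou_step_coeffs(relax_time: float, diffusivity: float, dt: float):
    """Exact transition coefficients of an integrated OU process over dt.

    For dv = -(v - v_mean)/tau dt + (sqrt(2 Dc)/tau) dW and x' = x + int v:
    returns (e, mix_x, a, b, c) with
      v' = v_mean + (v - v_mean) e + a z1
      x' = x + v_mean dt + (v - v_mean) tau (1 - e) + b z1 + c z2
    where (z1, z2) are iid standard normals and (a, b, c) reproduce the
    exact variances Var v' = (Dc/tau)(1-e^2), Var x' and Cov = Dc (1-e)^2.
    """
    tau = relax_time
    e = math.exp(-dt / tau)
    var_v = diffusivity / tau * (1.0 - e * e)
    cov = diffusivity * (1.0 - e) ** 2
    var_x = 2.0 * diffusivity * (dt - 2.0 * tau * (1.0 - e) + 0.5 * tau * (1.0 - e * e))
    a = math.sqrt(max(var_v, 0.0))
    b = cov / a if a > 0 else 0.0
    c = math.sqrt(max(var_x - b * b, 0.0))
    return e, tau * (1.0 - e), a, b, c


def step_rotation(state: ParticleState, p: ModelParams, dt: float, noise) -> tuple[float, float]:
    """Advance (phi, phi_dot) by the exact conditional Gaussian transition.

    ``noise`` is a pair of standard normal draws (z1 drives the angular
    velocity, z2 the extra angular randomness); the cross-covariance between
    angle and angular velocity over the step is reproduced exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    z1, z2 = noise
    e, mix, a, b, c = _ou_step_coeffs(p.tau_r, p.D_r, dt)
    dev = state.phi_dot - p.omega
    phi = state.phi + p.omega * dt + dev * mix + b * z1 + c * z2
    phi_dot = p.omega + dev * e + a * z1
    return phi, phi_dot


def step_translation(state: ParticleState, p: ModelParams, dt: float, noise) -> tuple[tuple, tuple]:
    """Advance (position, velocity) by the exact OU transition with n frozen.

    ``noise`` is a (2, 2) array of standard normals, one (z1, z2) pair per
    Cartesian component.  The mean velocity relaxes toward V_p n(t) at rate
    1/tau with stationary per-component variance D/tau; the position update
    is the exact integrated-OU one for constant n across the step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    z = np.asarray(noise, dtype=float).reshape(2, 2)
    e, mix, a, b, c = _ou_step_coeffs(p.tau, p.D, dt)
    nx, ny = math.cos(state.phi), math.sin(state.phi)
    pos = []
    vel = []
    for comp, (xc, vc) in enumerate(zip(state.position, state.velocity)):
        vmean = p.V_p * (nx if comp == 0 else ny)
        dev = vc - vmean
        z1, z2 = z[comp]
        pos.append(xc + vmean * dt + dev * mix + b * z1 + c * z2)
        vel.append(vmean + dev * e + a * z1)
    return (pos[0], pos[1]), (vel[0], vel[1])


# ---------------------------------------------------------------------------
# ensemble simulation (vectorised across runs)
# ---------------------------------------------------------------------------

def _default_burn_in(p: ModelParams) -> float:
    scales = [p.tau, p.tau_r]
    if p.D_r > 0:
        scales.append(1.0 / p.D_r)
    return 10.0 * max(scales)


def simulate_ensemble(p: ModelParams, cfg: SimConfig) -> Ensemble:
    """Simulate ``cfg.n_runs`` independent trajectories of the model.

    Deterministic given (p, cfg): run i uses the generator
    ``default_rng([cfg.seed, i])`` regardless of ensemble size or order.
    """
    cfg.check_dt(p)
    dt = cfg.dt
    n_rec = cfg.n_steps // cfg.record_every
    nr = cfg.n_runs
    er, mixr, ar, br, cr = _ou_step_coeffs(p.tau_r, p.D_r, dt)
    et, mixt, at, bt, ct = _ou_step_coeffs(p.tau, p.D, dt)

    burn_steps = 0
    if cfg.init_mode == "stationary":
        burn = cfg.burn_in if cfg.burn_in is not None else _default_burn_in(p)
        burn_steps = int(math.ceil(burn / dt))

    x = np.empty((nr, n_rec + 1))
    y = np.empty((nr, n_rec + 1))
    phi_rec = np.empty((nr, n_rec + 1))
    phid_rec = np.empty((nr, n_rec + 1))
    vx_rec = np.empty((nr, n_rec + 1)) if cfg.store_velocities else None
    vy_rec = np.empty((nr, n_rec + 1)) if cfg.store_velocities else None

    # per-run state arrays
    if cfg.init_mode == "explicit":
        st = cfg.explicit_init
        px = np.full(nr, st.position[0], dtype=float)
        py = np.full(nr, st.position[1], dtype=float)
        vx = np.full(nr, st.velocity[0], dtype=float)
        vy = np.full(nr, st.velocity[1], dtype=float)
        phi = np.full(nr, st.phi, dtype=float)
        phid = np.full(nr, st.phi_dot, dtype=float)
    else:
        px = np.zeros(nr)
        py = np.zeros(nr)
        vx = np.zeros(nr)
        vy = np.zeros(nr)
        phi = np.zeros(nr)
        phid = np.zeros(nr)

    rngs = [np.random.default_rng([cfg.seed, i]) for i in range(nr)]
    if cfg.init_mode == "stationary":
        for i, rng in enumerate(rngs):
            phi[i] = rng.uniform(0.0, 2.0 * math.pi)
            if p.D_r > 0:
                phid[i] = rng.normal(p.omega, math.sqrt(p.D_r / p.tau_r))
            else:
                phid[i] = p.omega

    total_steps = burn_steps + cfg.n_steps
    x[:, 0] = px
    y[:, 0] = py
    phi_rec[:, 0] = phi
    phid_rec[:, 0] = phid
    if cfg.store_velocities:
        vx_rec[:, 0] = vx
        vy_rec[:, 0] = vy

    # noise is drawn from the per-run streams in step blocks: run i consumes
    # its stream in a fixed order independent of ensemble size
    block = max(1, min(total_steps, int(8e5) // max(nr, 1) + 1))
    zblock = np.empty((nr, block, 6))
    step_in_record = 0
    rec = 0
    done = 0
    while done < total_steps:
        nb = min(block, total_steps - done)
        for i, rng in enumerate(rngs):
            zblock[i, :nb] = rng.standard_normal((nb, 6))
        for b in range(nb):
            k = done + b
            z = zblock[:, b, :]
            vmx = p.V_p * np.cos(phi)
            vmy = p.V_p * np.sin(phi)
            px += vmx * dt + (vx - vmx) * mixt + bt * z[:, 0] + ct * z[:, 1]
            vx = vmx + (vx - vmx) * et + at * z[:, 0]
            py += vmy * dt + (vy - vmy) * mixt + bt * z[:, 2] + ct * z[:, 3]
            vy = vmy + (vy - vmy) * et + at * z[:, 2]
            dev = phid - p.omega
            phi = phi + p.omega * dt + dev * mixr + br * z[:, 4] + cr * z[:, 5]
            phid = p.omega + dev * er + ar * z[:, 4]
            if k == burn_steps - 1:
                # recording starts here: move the origin to the current position
                px[:] = 0.0
                py[:] = 0.0
                phi_rec[:, 0] = phi
                phid_rec[:, 0] = phid
                if cfg.store_velocities:
                    vx_rec[:, 0] = vx
                    vy_rec[:, 0] = vy
                continue
            if k >= burn_steps:
                step_in_record += 1
                if step_in_record % cfg.record_every == 0:
                    rec += 1
                    x[:, rec] = px
                    y[:, rec] = py
                    phi_rec[:, rec] = phi
                    phid_rec[:, rec] = phid
                    if cfg.store_velocities:
                        vx_rec[:, rec] = vx
                        vy_rec[:, rec] = vy
        done += nb
    times = dt * cfg.record_every * np.arange(n_rec + 1)
    return Ensemble(
        params=p,
        times=times,
        x=x,
        y=y,
        phi=phi_rec,
        phi_dot=phid_rec,
        vx=vx_rec,
        vy=vy_rec,
        run_ids=list(range(nr)),
    )


def simulate(p: ModelParams, cfg: SimConfig) -> Trajectory:
    """Single-run convenience wrapper over :func:`simulate_ensemble`."""
    single = SimConfig(
        dt=cfg.dt,
        n_steps=cfg.n_steps,
        n_runs=1,
        seed=cfg.seed,
        init_mode=cfg.init_mode,
        explicit_init=cfg.explicit_init,
        burn_in=cfg.burn_in,
        record_every=cfg.record_every,
        store_velocities=cfg.store_velocities,
        strict=cfg.strict,
    )
    ens = simulate_ensemble(p, single)
    return next(iter(ens))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _fig2() -> ModelParams:
    # generic-particle parameter set of the start-up / delay comparison
    return ModelParams(
        tau=1.0 / 6.46, tau_r=1.0 / 5.4, D=8e-5, D_r=2.59, V_p=0.092, omega=0.7
    )


def _fig6() -> ModelParams:
    # density-sweep base set (torque-free); absolute scales printed alongside
    M0, J0 = 4e-3, 1.5e-7
    return ModelParams(
        tau=1.0 / 6.5,
        tau_r=1.0 / 5.5,
        D=1e-4,
        D_r=1.0,
        V_p=0.1,
        omega=0.0,
        M=M0,
        J=J0,
        xi=M0 * 6.5,
        xi_r=J0 * 5.5,
        tau_0=0.0,
    )


PRESETS = {"fig2": _fig2, "fig6": _fig6}


def preset(name: str, fraction: float | None = None) -> ModelParams:
    """Printed parameter sets: "fig2", "fig6", or "fig6_scaled" with a fraction.

    "fig6_scaled" reduces the material density — M and J (hence tau and
    tau_r) shrink by the common fraction while xi, xi_r, D, D_r, V_p, omega
    stay fixed.
    """
    if name in PRESETS:
        return PRESETS[name]()
    if name == "fig6_scaled":
        if fraction is None or not (fraction > 0):
            raise ValueError("fig6_scaled requires a positive fraction")
        base = _fig6()
        return ModelParams(
            tau=base.tau * fraction,
            tau_r=base.tau_r * fraction,
            D=base.D,
            D_r=base.D_r,
            V_p=base.V_p,
            omega=base.omega,
            M=base.M * fraction,
            J=base.J * fraction,
            xi=base.xi,
            xi_r=base.xi_r,
            tau_0=0.0,
        )
    raise ValueError(f"unknown preset {name!r}")
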