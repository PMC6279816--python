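"""Parameter inference from trajectory ensembles.

Recovery of the six rates (tau, tau_r, D, D_r, V_p, omega) proceeds in the
same two stages an experimentalist would use:

1. Rotational stage — omega is the first moment of the angular-velocity
   histogram; (D_r, tau_r) come from least squares of the stationary angular
   MSD model omega^2 t^2 + 2 D_r (t - tau_r (1 - e^(-t/tau_r))).
2. Translational stage — an iterative scheme bounded by the delay-number
   function f: starting from V_p = sqrt(<R'^2>) and f = 1, (tau, D) are
   fitted to the linear-velocity distribution; then either branch A keeps
   f = 1 and sets V_p = sqrt(<R'^2> - 2D/tau), or branch B evaluates f at
   the current parameters and sets V_p = sqrt((<R'^2> - 2D/tau)/f).  Both
   branches are scored against the translational MSD and the speed
   distribution and the worse one is discarded; iteration continues until
   the tracked curves agree below the standard error (or the parameters
   stop moving).  Since f lies in [0, 1], the accepted V_p always lies in
   [sqrt(<R'^2> - 2D/tau), sqrt((<R'^2> - 2D/tau)/f)].

A final simplex (Nelder-Mead) refinement minimises the weighted sum of
mean squared errors of *all* curves — including the delay function — where
the model curves are produced by simulation at the empirical sampling
interval with common random numbers, so the objective is deterministic.
Per-parameter uncertainties are the variations that quadruple the minimal
weighted MSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .analytics import (
    ActiveVelocitySampler,
    MomentMatchError,
    f_delay,
    linear_velocity_pdf,
    match_qW,
    msd_stationary,
    speed_pdf,
    velocity_second_moment,
)
from .params import ModelParams
from .simulate import SimConfig, simulate_ensemble
from .stats import CurveSet

__all__ = [
    "FitResult",
    "RotationalFitError",
    "fit_rotational",
    "fit_translational_iterative",
    "fit_full",
    "uncertainty",
    "angular_msd_model",
]


class RotationalFitError(RuntimeError):
    """The angular MSD does not identify (D_r, tau_r)."""


@dataclass
class FitResult:
    """Estimated parameters with per-curve goodness and uncertainty intervals."""

    params: ModelParams
    method: str
    per_curve_mse: dict[str, float] = field(default_factory=dict)
    objective: float | None = None
    uncertainty: dict[str, tuple[float, float]] | None = None
    iterations: list[dict] = field(default_factory=list)
    converged: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# stage 1: rotation
# ---------------------------------------------------------------------------

def angular_msd_model(t, D_r: float, tau_r: float, omega: float):
    """Stationary angular MSD: omega^2 t^2 + 2 D_r (t - tau_r (1 - e^(-t/tau_r)))."""
    t = np.asarray(t, dtype=float)
    return omega**2 * t**2 + 2.0 * D_r * (t - tau_r * (1.0 - np.exp(-t / tau_r)))


def fit_rotational(curves: CurveSet) -> tuple[float, float, float]:
    """(D_r, tau_r, omega) from the angular-velocity histogram and angular MSD."""
    pdf = curves.pdf_angular_velocity
    msd = curves.msd_ang
    if pdf is None or msd is None:
        raise ValueError("need pdf_angular_velocity and msd_ang curves")
    norm = np.trapezoid(pdf.y, pdf.x)
    if norm <= 0:
        raise RotationalFitError("empty angular-velocity histogram")
    omega = float(np.trapezoid(pdf.x * pdf.y, pdf.x) / norm)

    t = msd.x
    y = msd.y
    resid = y - omega**2 * t**2
    if np.ptp(y) <= 0:
        raise RotationalFitError("angular MSD flat; (D_r, tau_r) not identifiable")
    if np.max(np.abs(resid)) <= 1e-9 * np.max(y):
        # pure drift: a noise-free rotator; D_r consistent with 0, tau_r unidentifiable
        return 0.0, math.nan, omega
    # moment-based initial guesses: long-lag slope -> D_r, short-lag curvature -> tau_r
    dr0 = max(resid[-1] / (2.0 * t[-1]), 1e-12)
    q2 = max(resid[0] / t[0] ** 2, 2.0 * dr0 / t[-1])
    tr0 = float(np.clip(dr0 / q2, t[0] / 10.0, t[-1]))
    sem = msd.sem if msd.sem is not None and np.all(msd.sem > 0) else None
    w = 1.0 / sem**2 if sem is not None else 1.0 / np.maximum(y, 1e-300) ** 2

    def objective(theta):
        dr, tr = np.exp(theta)
        r = angular_msd_model(t, dr, tr, omega) - y
        return float(np.mean(w * r**2))

    res = minimize(
        objective,
        x0=np.log([dr0, tr0]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxfev": 2000},
    )
    D_r, tau_r = np.exp(res.x)
    if not res.success and res.fun > objective(np.log([dr0, tr0])):
        raise RotationalFitError(f"angular MSD fit failed: {res.message}")
    return float(D_r), float(tau_r), omega


# ---------------------------------------------------------------------------
# stage 2: iterative translational fit
# ---------------------------------------------------------------------------

def _curve_weights(curve, rel_floor: float = 0.0) -> np.ndarray:
    """Inverse-variance weights with an optional relative-error floor.

    ``rel_floor`` caps the demanded accuracy at that fraction of the curve
    value: time-averaged MSD points can have sub-percent standard errors,
    which would let tiny biases in parameters held fixed elsewhere dominate
    a least-squares fit.
    """
    if curve.sem is not None and np.any(curve.sem > 0):
        floor = np.percentile(curve.sem[curve.sem > 0], 10)
        sem = np.maximum(curve.sem, floor)
        if rel_floor > 0:
            sem = np.maximum(sem, rel_floor * np.abs(curve.y))
        return 1.0 / sem**2
    scale = max(float(np.max(np.abs(curve.y))), 1e-300)
    return np.full_like(curve.y, 1.0 / scale**2)


def _qW_or_gaussian(p: ModelParams, sampler, window: float = 0.0) -> tuple[float, float]:
    """(q, W) of the mixture law, corrected for the measurement window.

    Finite-difference velocities over a window h carry the variance
    MSD(h)/h^2, not the instantaneous one; the thermal part of that
    reduction is exact and is applied to q (the active part's correction is
    second order in h over the correlation time and neglected).
    """
    try:
        q, W = match_qW(p, sampler=sampler)
    except MomentMatchError:
        q, W = 0.5 * velocity_second_moment(p), 0.0
    if window > 0:
        h = window
        q_th_windowed = 2.0 * p.D * (h - p.tau * (1.0 - math.exp(-h / p.tau))) / h**2
        q = q - (p.D / p.tau - q_th_windowed)
        if q <= 0:
            q = q_th_windowed  # degenerate: thermal floor
    return q, W


def _pdf_mse(p: ModelParams, curve, sampler, window: float = 0.0) -> float:
    q, W = _qW_or_gaussian(p, sampler, window=window)
    model = linear_velocity_pdf(q, W, curve.x)
    w = _curve_weights(curve)
    return float(np.mean(w * (model - curve.y) ** 2))


def _fit_tau_D(
    curves: CurveSet, rot, V_p: float, tau0: float, D0: float, sampler,
    msd_model: "_TransMsdModel" = None, msd_idx=None, window: float = 0.0,
) -> tuple[float, float]:
    """(tau, D) least squares of the mixture velocity law at fixed V_p.

    With ``msd_model`` given, the translational MSD joins the objective:
    the velocity distribution alone pins essentially only D/tau, and the
    MSD crossover separates the two.  The MSD term is reserved for the
    final refinement at the converged V_p — inside the branch iteration the
    provisional V_p would feed a spurious active displacement back into
    (tau, D).
    """
    D_r, tau_r, omega = rot
    curve = curves.pdf_linear_velocity
    msd = curves.msd_trans
    w_msd = _curve_weights(msd, rel_floor=0.01)[msd_idx] if msd_idx is not None else None

    def objective(theta):
        tau, D = np.exp(theta)
        try:
            p = ModelParams(tau=tau, tau_r=tau_r, D=D, D_r=D_r, V_p=V_p, omega=omega)
        except Exception:
            return 1e300
        total = _pdf_mse(p, curve, sampler, window=window)
        if msd_model is not None:
            model = msd_model(tau, D, V_p)
            total += float(np.mean(w_msd * (model - msd.y[msd_idx]) ** 2))
        return total

    res = minimize(
        objective,
        x0=np.log([tau0, D0]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-9, "maxfev": 200},
    )
    tau, D = np.exp(res.x)
    return float(tau), float(D)


def _msd_model_fast(p: ModelParams, ts: np.ndarray) -> np.ndarray:
    """Stationary MSD on a grid via a tabulated velocity autocorrelation.

    Accuracy ~1e-3 relative: plenty for curve scoring inside the fits, at a
    small fraction of the cost of the adaptive-quadrature route.
    """
    from .analytics import _vacf_active_grid

    ts = np.asarray(ts, dtype=float)
    t_corr = p.tau_r + (1.0 / p.D_r if p.D_r > 0 else 0.0)
    s_cut = min(float(np.max(ts)), 45.0 * (p.tau + t_corr))
    grid = np.concatenate([[0.0], np.geomspace(min(p.tau, p.tau_r) / 50.0, s_cut, 400)])
    za = _vacf_active_grid(p, grid)
    # cumulative integrals of Z_a and s Z_a give MSD_a(t) = 2[t I1(t) - I2(t)]
    i1 = np.concatenate([[0.0], np.cumsum(0.5 * (za[1:] + za[:-1]) * np.diff(grid))])
    sza = grid * za
    i2 = np.concatenate([[0.0], np.cumsum(0.5 * (sza[1:] + sza[:-1]) * np.diff(grid))])
    tcl = np.minimum(ts, s_cut)
    out = 4.0 * p.D * (ts - p.tau * (1.0 - np.exp(-ts / p.tau)))
    j1 = np.interp(tcl, grid, i1)
    j2 = np.interp(tcl, grid, i2)
    out += 2.0 * (ts * j1 - j2)
    return out


class _TransMsdModel:
    """Stationary translational MSD on a fixed grid of lags.

    The rotational parameters are frozen during the translational stage;
    each call evaluates the vectorised VACF route directly (milliseconds),
    keeping the optimiser's objective smooth and exact.
    """

    def __init__(self, rot: tuple[float, float, float], ts: np.ndarray) -> None:
        self.rot = rot
        self.ts = np.asarray(ts, dtype=float)

    def __call__(self, tau: float, D: float, V_p: float) -> np.ndarray:
        D_r, tau_r, omega = self.rot
        passive = 4.0 * D * (self.ts - tau * (1.0 - np.exp(-self.ts / tau)))
        if V_p == 0.0:
            return passive
        p1 = ModelParams(tau=tau, tau_r=tau_r, D=0.0, D_r=D_r, V_p=1.0, omega=omega)
        return passive + V_p**2 * _msd_model_fast(p1, self.ts)


def _agreement(
    p: ModelParams, curves: CurveSet, sampler, msd_model: "_TransMsdModel", msd_idx,
    window: float = 0.0,
) -> tuple[float, dict[str, float]]:
    """Weighted MSE of the candidate against translational MSD and speed pdf."""
    mses = {}
    msd = curves.msd_trans
    model = msd_model(p.tau, p.D, p.V_p)
    w = _curve_weights(msd, rel_floor=0.01)[msd_idx]
    mses["msd_trans"] = float(np.mean(w * (model - msd.y[msd_idx]) ** 2))
    spd = curves.pdf_speed
    q, W = _qW_or_gaussian(p, sampler, window=window)
    w = _curve_weights(spd)
    mses["pdf_speed"] = float(np.mean(w * (speed_pdf(q, W, spd.x) - spd.y) ** 2))
    return sum(mses.values()), mses


def fit_translational_iterative(
    curves: CurveSet,
    rot: tuple[float, float, float],
    max_iter: int = 50,
    rel_tol: float = 1e-3,
) -> tuple[float, float, float, list[dict]]:
    """(D, tau, V_p) by the f-bounded branch-and-discard iteration.

    Returns (D, tau, V_p, log); each log entry records both branches, their
    agreement scores and which was accepted.
    """
    D_r, tau_r, omega = rot
    v2 = curves.v2_mean
    if v2 is None or v2 <= 0:
        raise ValueError("curve set lacks a positive velocity second moment")
    V_p = math.sqrt(v2)
    tau, D = tau_r, 0.1 * v2 * tau_r  # neutral starting scales
    window = (curves.dt or 0.0) * curves.k
    sampler = ActiveVelocitySampler(D_r, tau_r, omega, tau_scale=4.0 * tau_r)
    msd = curves.msd_trans
    msd_idx = np.unique(np.round(np.linspace(0, len(msd.x) - 1, 15)).astype(int))
    msd_model = _TransMsdModel(rot, msd.x[msd_idx])
    msd_at_h = _TransMsdModel(rot, np.array([window])) if window > 0 else None

    def v2_debias(tau_c: float, d_c: float, vp_c: float) -> float:
        # measured <v^2> is MSD(h)/h^2 of the model; invert that window bias
        if msd_at_h is None:
            return v2
        p_c = ModelParams(tau=tau_c, tau_r=tau_r, D=d_c, D_r=D_r, V_p=vp_c, omega=omega)
        windowed = float(msd_at_h(tau_c, d_c, vp_c)[0]) / window**2
        c = velocity_second_moment(p_c) / windowed if windowed > 0 else 1.0
        return v2 * c

    tau, D = _fit_tau_D(curves, rot, V_p, tau, D, sampler, window=window)
    log: list[dict] = []
    prev = np.array([tau, D, V_p])
    for it in range(max_iter):
        excess = v2_debias(tau, D, V_p) - 2.0 * D / tau
        candidates = {}
        if excess > 0:
            # each branch proposes V_p from the current (tau, D), refits
            # (tau, D) at that V_p, then re-applies its own V_p rule at the
            # refit values, so the accepted iterate always sits exactly on
            # its end of the f-bounds interval [sqrt(<v^2> - 2D/tau),
            # sqrt((<v^2> - 2D/tau)/f)]
            vp_a = math.sqrt(excess)
            tau_a, d_a = _fit_tau_D(curves, rot, vp_a, tau, D, sampler, window=window)
            ex_a = v2_debias(tau_a, d_a, vp_a) - 2.0 * d_a / tau_a
            if ex_a > 0:
                candidates["A"] = (d_a, tau_a, math.sqrt(ex_a))
            fb = f_delay(D_r * tau_r, omega * tau_r, tau_r / tau)
            if fb > 0:
                vp_b = math.sqrt(excess / fb)
                tau_b, d_b = _fit_tau_D(curves, rot, vp_b, tau, D, sampler, window=window)
                ex_b = v2_debias(tau_b, d_b, vp_b) - 2.0 * d_b / tau_b
                fb2 = f_delay(D_r * tau_r, omega * tau_r, tau_r / tau_b)
                if ex_b > 0 and fb2 > 0:
                    candidates["B"] = (d_b, tau_b, math.sqrt(ex_b / fb2))
        if not candidates:
            if log:
                break  # keep the last accepted iterate
            raise RuntimeError(
                "no feasible V_p branch: 2D/tau exceeds the measured velocity moment"
            )
        scored = {}
        for branch, (d_c, tau_c, vp_c) in candidates.items():
            p_c = ModelParams(tau=tau_c, tau_r=tau_r, D=d_c, D_r=D_r, V_p=vp_c, omega=omega)
            score, per = _agreement(p_c, curves, sampler, msd_model, msd_idx, window=window)
            scored[branch] = (score, per, (d_c, tau_c, vp_c))
        # on a tie prefer branch B (explicit f), the physically complete choice
        best = min(scored, key=lambda b: (scored[b][0], b != "B"))
        score, per, (D, tau, V_p) = scored[best]
        log.append(
            {
                "iteration": it,
                "accepted": best,
                "scores": {b: scored[b][0] for b in scored},
                "per_curve": per,
                "params": {"D": D, "tau": tau, "V_p": V_p},
                "v2_corrected": v2_debias(tau, D, V_p),
            }
        )
        cur = np.array([tau, D, V_p])
        if np.all(np.abs(cur - prev) <= rel_tol * np.abs(prev)):
            break
        prev = cur
        if score <= 1.0:  # weighted by 1/sem^2: below the standard error
            break
    # final refinement at the converged V_p: now the MSD can safely join the
    # (tau, D) objective and break the D/tau ridge degeneracy
    branch = log[-1]["accepted"] if log else "A"
    for _ in range(3):
        tau_n, d_n = _fit_tau_D(
            curves, rot, V_p, tau, D, sampler, msd_model, msd_idx, window=window
        )
        ex = v2_debias(tau_n, d_n, V_p) - 2.0 * d_n / tau_n
        if ex <= 0:
            break
        if branch == "B":
            fb = f_delay(D_r * tau_r, omega * tau_r, tau_r / tau_n)
            vp_n = math.sqrt(ex / fb) if fb > 0 else math.sqrt(ex)
        else:
            vp_n = math.sqrt(ex)
        moved = abs(tau_n - tau) > 1e-3 * tau or abs(vp_n - V_p) > 1e-3 * max(V_p, 1e-12)
        tau, D, V_p = tau_n, d_n, vp_n
        log.append(
            {
                "iteration": len(log),
                "accepted": branch,
                "scores": {},
                "per_curve": {},
                "params": {"D": D, "tau": tau, "V_p": V_p},
                "v2_corrected": v2_debias(tau, D, V_p),
                "refinement": True,
            }
        )
        if not moved:
            break
    return D, tau, V_p, log


# ---------------------------------------------------------------------------
# full simplex fit
# ---------------------------------------------------------------------------

_CURVE_NAMES = (
    "msd_trans",
    "msd_ang",
    "pdf_linear_velocity",
    "pdf_speed",
    "pdf_angular_velocity",
    "delay_curve",
)


class _SimulatedObjective:
    """Deterministic weighted-MSE objective with common random numbers.

    Model curves are produced by simulating at the empirical sampling
    interval (sub-stepped when that interval is too coarse for the
    candidate's time scales) and reduced on the empirical grids.
    """

    def __init__(
        self,
        curves: CurveSet,
        seed: int = 0,
        n_runs: int = 48,
        n_frames: int = 4096,
        weights: dict[str, float] | None = None,
    ) -> None:
        self.curves = curves
        self.seed = seed
        self.n_runs = n_runs
        self.n_frames = n_frames
        self.dt = curves.dt
        self.k = curves.k
        if weights is not None and all(w == 0 for w in weights.values()):
            raise ValueError("at least one curve weight must be non-zero")
        self.weights = weights or {}
        self.grids = {}
        for name in _CURVE_NAMES:
            c = getattr(curves, name)
            if c is None:
                continue
            if name.startswith("msd"):
                lags = np.unique(np.round(c.x / self.dt).astype(int))
                self.grids[name] = lags[(lags > 0) & (lags < n_frames - 1)]
            elif name == "delay_curve":
                lags = np.unique(np.round(c.x / self.dt).astype(int))
                self.grids[name] = lags[lags < n_frames - self.k - 1]

    def model_curves(self, p: ModelParams) -> CurveSet:
        scales = [p.tau, p.tau_r] + ([1.0 / p.D_r] if p.D_r > 0 else [])
        sub = max(1, int(math.ceil(self.dt / (0.1 * min(scales)))))
        cfg = SimConfig(
            dt=self.dt / sub,
            n_steps=self.n_frames * sub,
            n_runs=self.n_runs,
            seed=self.seed,
            init_mode="stationary",
            record_every=sub,
        )
        ens = simulate_ensemble(p, cfg)
        return self._curveset(ens)

    def _curveset(self, ens) -> CurveSet:
        from .stats import (
            delay_function_empirical,
            empirical_msd,
            finite_difference_angular_velocity,
            finite_difference_velocity,
        )

        cs = CurveSet(dt=self.dt, k=self.k)
        if "msd_trans" in self.grids:
            cs.msd_trans = empirical_msd(ens, lags=self.grids["msd_trans"], angular=False)
        if "msd_ang" in self.grids:
            cs.msd_ang = empirical_msd(ens, lags=self.grids["msd_ang"], angular=True)
        if "delay_curve" in self.grids:
            cs.delay_curve = delay_function_empirical(ens, k=self.k, lags=self.grids["delay_curve"])
        vx, vy = finite_difference_velocity(ens, self.k)
        w = finite_difference_angular_velocity(ens, self.k)
        # histogram model samples on the *empirical* bin grids
        for name, samples in (
            ("pdf_linear_velocity", np.concatenate([vx.ravel(), vy.ravel()])),
            ("pdf_speed", np.hypot(vx, vy).ravel()),
            ("pdf_angular_velocity", w.ravel()),
        ):
            emp = getattr(self.curves, name)
            if emp is None:
                continue
            dx = emp.x[1] - emp.x[0]
            edges = np.concatenate([emp.x - 0.5 * dx, [emp.x[-1] + 0.5 * dx]])
            dens, _ = np.histogram(samples, bins=edges, density=False)
            total = max(samples.size, 1)
            setattr(cs, name, type(emp)(x=emp.x, y=dens / (total * dx), kind="pdf"))
        return cs

    def _interp_msd(self, name: str, model: CurveSet):
        emp = getattr(self.curves, name)
        mod = getattr(model, name)
        y = np.interp(emp.x, mod.x, mod.y)
        return emp, y

    def __call__(self, p: ModelParams) -> tuple[float, dict[str, float]]:
        model = self.model_curves(p)
        total = 0.0
        per: dict[str, float] = {}
        for name in _CURVE_NAMES:
            emp = getattr(self.curves, name)
            mod = getattr(model, name)
            if emp is None or mod is None:
                continue
            if name.startswith("msd") or name == "delay_curve":
                y = np.interp(emp.x, mod.x, mod.y)
            else:
                y = mod.y
            w = _curve_weights(emp)
            mse = float(np.mean(w * (y - emp.y) ** 2))
            per[name] = mse
            total += self.weights.get(name, 1.0) * mse
        return total, per


def fit_full(
    curves: CurveSet,
    init: ModelParams,
    seed: int = 0,
    n_runs: int = 48,
    n_frames: int = 4096,
    weights: dict[str, float] | None = None,
    maxfev: int = 150,
) -> FitResult:
    """Nelder-Mead refinement of all six rates against all empirical curves.

    The objective is the weighted sum of per-curve mean squared errors with
    model curves simulated using common random numbers (fixed inner seed),
    so repeated evaluations at the same parameters agree exactly.  Returns
    the best parameters found; if the evaluation budget is exhausted before
    convergence the best-so-far is returned with ``converged=False``.
    """
    objective = _SimulatedObjective(
        curves, seed=seed, n_runs=n_runs, n_frames=n_frames, weights=weights
    )

    def pack(p: ModelParams):
        return np.array([math.log(p.tau), math.log(p.tau_r), math.log(p.D), math.log(p.D_r), math.log(p.V_p), p.omega])

    def unpack(theta) -> ModelParams:
        return ModelParams(
            tau=math.exp(theta[0]),
            tau_r=math.exp(theta[1]),
            D=math.exp(theta[2]),
            D_r=math.exp(theta[3]),
            V_p=math.exp(theta[4]),
            omega=theta[5],
        )

    def fun(theta):
        try:
            p = unpack(theta)
        except Exception:
            return 1e300
        try:
            total, _ = objective(p)
        except (ValueError, FloatingPointError):
            return 1e300
        return total

    res = minimize(
        fun,
        x0=pack(init),
        method="Nelder-Mead",
        options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-12, "adaptive": True},
    )
    best = unpack(res.x)
    total, per = objective(best)
    return FitResult(
        params=best,
        method="full",
        per_curve_mse=per,
        objective=total,
        converged=bool(res.success),
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# uncertainty: parameter variation that quadruples the weighted MSE
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("tau", "tau_r", "D", "D_r", "V_p", "omega")


def uncertainty(
    curves: CurveSet,
    fit: FitResult,
    objective=None,
    factor: float = 4.0,
    span: float = 30.0,
    tol: float = 1e-3,
) -> dict[str, tuple[float, float]]:
    """Per-parameter intervals where the objective reaches ``factor`` x its minimum.

    Each parameter is bisected outward from the optimum with the others
    fixed.  A direction in which the objective never reaches the threshold
    within a factor ``span`` (or +-span characteristic units for omega) is
    reported as open with +-inf.  ``objective`` defaults to the same
    simulated-curve objective used by :func:`fit_full`.
    """
    if objective is None:
        sim_obj = _SimulatedObjective(curves, seed=0)
        objective = lambda p: sim_obj(p)[0]
    p0 = fit.params
    m0 = objective(p0)
    target = factor * m0
    out: dict[str, tuple[float, float]] = {}

    def with_value(name: str, value: float) -> ModelParams | None:
        try:
            return p0.with_(**{name: value})
        except Exception:
            return None

    for name in _PARAM_NAMES:
        v0 = getattr(p0, name)
        scale = abs(v0) if abs(v0) > 0 else math.sqrt(p0.D_r / p0.tau_r) if name == "omega" else 1.0
        bounds = []
        for sign in (-1.0, +1.0):
            lo_off, hi_off = 0.0, None
            step = 0.05 * scale
            off = step
            hit = None
            while off <= span * scale:
                cand = with_value(name, v0 + sign * off)
                if cand is None:
                    break
                try:
                    val = objective(cand)
                except Exception:
                    break
                if val >= target:
                    hit = off
                    break
                lo_off = off
                off *= 2.0
            if hit is None:
                bounds.append(sign * math.inf)
                continue
            lo, hi = lo_off, hit
            while (hi - lo) > tol * scale:
                mid = 0.5 * (lo + hi)
                cand = with_value(name, v0 + sign * mid)
                if cand is None:
                    break
                if objective(cand) >= target:
                    hi = mid
                else:
                    lo = mid
            bounds.append(sign * 0.5 * (lo + hi))
        out[name] = (v0 + bounds[0] if np.isfinite(bounds[0]) else -math.inf,
                     v0 + bounds[1] if np.isfinite(bounds[1]) else math.inf)
    return out
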