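"""Empirical estimators for trajectory ensembles.

These mirror what a particle-tracking experiment measures: velocities from
finite differences of successive positions, time-and-ensemble-averaged mean
squared displacements, normalised velocity histograms, the orientational
correlation, and the orientation-velocity delay function

    C(lag) = <R'(t + lag) . n(t)> - <R'(t) . n(t + lag)>,

with pointwise standard-error bands from the between-run scatter.  All
estimators are invariant under global rotations and translations of the
trajectories and operate on the unwrapped angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analytics import Curve
from .simulate import Ensemble, Trajectory

__all__ = [
    "CurveSet",
    "finite_difference_velocity",
    "finite_difference_angular_velocity",
    "empirical_msd",
    "empirical_distributions",
    "delay_function_empirical",
    "orientation_correlation_empirical",
    "compute_curveset",
    "add_tracking_noise",
    "read_trajectories",
    "write_trajectories",
]

#: tracking accuracies of a typical high-speed-camera setup, used by the
#: optional measurement-noise emulation (off by default)
TRACKING_NOISE_XY = 4.7e-4  # m
TRACKING_NOISE_PHI = 0.013  # rad


@dataclass
class CurveSet:
    """The empirical observables used for parameter determination.

    msd_trans, msd_ang : translational / angular mean squared displacement
    pdf_linear_velocity, pdf_speed, pdf_angular_velocity : normalised histograms
    delay_curve : the orientation-velocity delay function
    orientation_corr : <n(t+s).n(s)>
    v2_mean / v2_sem : the pooled second moment of the 2-D velocity
    dt : sampling interval of the underlying ensemble; k : frame multiple
    """

    msd_trans: Curve | None = None
    msd_ang: Curve | None = None
    pdf_linear_velocity: Curve | None = None
    pdf_speed: Curve | None = None
    pdf_angular_velocity: Curve | None = None
    delay_curve: Curve | None = None
    orientation_corr: Curve | None = None
    v2_mean: float | None = None
    v2_sem: float | None = None
    dt: float | None = None
    k: int = 1

    _FIELDS = (
        "msd_trans",
        "msd_ang",
        "pdf_linear_velocity",
        "pdf_speed",
        "pdf_angular_velocity",
        "delay_curve",
        "orientation_corr",
    )

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        import json

        for name in self._FIELDS:
            c = getattr(self, name)
            if c is not None:
                c.to_csv(path / f"{name}.csv")
        meta = {"v2_mean": self.v2_mean, "v2_sem": self.v2_sem, "dt": self.dt, "k": self.k}
        (path / "summary.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def from_dir(cls, path) -> "CurveSet":
        path = Path(path)
        import json

        kwargs = {}
        for name in cls._FIELDS:
            f = path / f"{name}.csv"
            if f.exists():
                kwargs[name] = Curve.from_csv(f)
        meta = json.loads((path / "summary.json").read_text())
        return cls(**kwargs, **meta)


# ---------------------------------------------------------------------------
# velocities
# ---------------------------------------------------------------------------

def _as_arrays(data: Ensemble | Trajectory):
    if isinstance(data, Trajectory):
        return (
            data.times,
            data.x[None, :],
            data.y[None, :],
            data.phi[None, :],
        )
    return data.times, data.x, data.y, data.phi


def finite_difference_velocity(data: Ensemble | Trajectory, k: int = 1):
    """Velocities v(t) = (r(t + k dt) - r(t)) / (k dt), shape (runs, n - k).

    The velocity angle convention is theta = atan2(vy, vx); the returned
    series is shorter than the trajectory by k samples.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    times, x, y, _ = _as_arrays(data)
    if x.shape[1] <= k:
        raise ValueError(f"trajectory too short ({x.shape[1]} samples) for k = {k}")
    h = k * float(times[1] - times[0])
    vx = (x[:, k:] - x[:, :-k]) / h
    vy = (y[:, k:] - y[:, :-k]) / h
    return vx, vy


def finite_difference_angular_velocity(data: Ensemble | Trajectory, k: int = 1):
    """Angular velocities (phi(t + k dt) - phi(t)) / (k dt) on the unwrapped angle."""
    if k < 1:
        raise ValueError("k must be >= 1")
    times, _, _, phi = _as_arrays(data)
    if phi.shape[1] <= k:
        raise ValueError(f"trajectory too short ({phi.shape[1]} samples) for k = {k}")
    h = k * float(times[1] - times[0])
    return (phi[:, k:] - phi[:, :-k]) / h


# ---------------------------------------------------------------------------
# mean squared displacement
# ---------------------------------------------------------------------------

def _default_lags(n: int, n_lags: int = 60) -> np.ndarray:
    lags = np.unique(np.round(np.geomspace(1, n - 1, n_lags)).astype(int))
    return lags


def empirical_msd(
    data: Ensemble | Trajectory, lags=None, angular: bool = False
) -> Curve:
    """Time-and-ensemble-averaged MSD at integer sample lags.

    Each run is first averaged over all admissible start times; the ensemble
    mean and the standard error of the mean across runs give the curve and
    its band (the single-particle-tracking convention).
    """
    times, x, y, phi = _as_arrays(data)
    n = x.shape[1]
    if lags is None:
        lags = _default_lags(n)
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 0) or np.any(lags >= n):
        raise ValueError(f"lags must lie in [0, {n - 1}]")
    dt = float(times[1] - times[0])
    per_run = np.empty((x.shape[0], len(lags)))
    for j, L in enumerate(lags):
        if L == 0:
            per_run[:, j] = 0.0
            continue
        if angular:
            d2 = (phi[:, L:] - phi[:, :-L]) ** 2
        else:
            d2 = (x[:, L:] - x[:, :-L]) ** 2 + (y[:, L:] - y[:, :-L]) ** 2
        per_run[:, j] = d2.mean(axis=1)
    mean = per_run.mean(axis=0)
    nr = per_run.shape[0]
    sem = per_run.std(axis=0, ddof=1) / math.sqrt(nr) if nr > 1 else np.zeros_like(mean)
    keep = lags > 0  # lag 0 is identically zero; drop it from the curve grid
    return Curve(
        x=lags[keep] * dt,
        y=mean[keep],
        kind="msd_rad2" if angular else "msd_m2",
        sem=sem[keep],
        n=np.full(keep.sum(), nr),
    )


# ---------------------------------------------------------------------------
# velocity distributions
# ---------------------------------------------------------------------------

def _fd_bins(samples: np.ndarray, bins) -> np.ndarray:
    lo, hi = float(samples.min()), float(samples.max())
    if hi <= lo:  # degenerate (constant) sample: a single narrow spike
        h = max(abs(lo), 1.0) * 1e-9
        lo, hi = lo - h, lo + h
    if bins is None:
        q75, q25 = np.percentile(samples, [75, 25])
        iqr = q75 - q25
        width = 2.0 * iqr / len(samples) ** (1.0 / 3.0)
        if width <= 0:
            width = samples.std() / 10 or (hi - lo)
        nbin = max(10, min(400, int(math.ceil((hi - lo) / width))))
        return np.linspace(lo, hi, nbin + 1)
    if np.isscalar(bins):
        return np.linspace(lo, hi, int(bins) + 1)
    return np.asarray(bins, dtype=float)


def _hist_curve(per_run_samples: list[np.ndarray], bins, kind: str = "pdf") -> Curve:
    pooled = np.concatenate(per_run_samples)
    edges = _fd_bins(pooled, bins)
    centers = 0.5 * (edges[1:] + edges[:-1])
    dens = np.array(
        [np.histogram(s, bins=edges, density=True)[0] for s in per_run_samples]
    )
    nr = dens.shape[0]
    mean = dens.mean(axis=0)
    sem = dens.std(axis=0, ddof=1) / math.sqrt(nr) if nr > 1 else np.zeros_like(mean)
    counts = np.histogram(pooled, bins=edges)[0]
    return Curve(x=centers, y=mean, kind=kind, sem=sem, n=counts)


def empirical_distributions(
    data: Ensemble | Trajectory,
    k: int = 1,
    bins=None,
    rotation_seed: int = 0,
) -> dict[str, Curve]:
    """Normalised histograms of linear velocity, speed and angular velocity.

    Each run's velocity vectors are rotated by a run-specific uniform random
    angle before pooling both Cartesian components, removing any residual
    anisotropy from the initial conditions (the rotation seed is recorded in
    the caller).  Densities are per-run histograms averaged across runs with
    s.e.m. bands.
    """
    vx, vy = finite_difference_velocity(data, k)
    w = finite_difference_angular_velocity(data, k)
    nr = vx.shape[0]
    rng = np.random.default_rng(rotation_seed)
    angles = rng.uniform(0.0, 2.0 * math.pi, size=nr)
    ca, sa = np.cos(angles)[:, None], np.sin(angles)[:, None]
    rx = ca * vx - sa * vy
    ry = sa * vx + ca * vy
    lin = [np.concatenate([rx[i], ry[i]]) for i in range(nr)]
    spd = [np.hypot(vx[i], vy[i]) for i in range(nr)]
    ang = [w[i] for i in range(nr)]
    return {
        "pdf_linear_velocity": _hist_curve(lin, bins),
        "pdf_speed": _hist_curve(spd, bins),
        "pdf_angular_velocity": _hist_curve(ang, bins),
    }


# ---------------------------------------------------------------------------
# correlation functions
# ---------------------------------------------------------------------------

def delay_function_empirical(
    data: Ensemble | Trajectory, k: int = 1, lags=None
) -> Curve:
    """Empirical delay function C(lag) with s.e.m. bands.

    C(lag) = <v(t + lag) . n(t)>_T - <v(t) . n(lag + t)>_T, averaged over
    start times and runs, with velocities from k-frame finite differences.
    Identically zero at lag 0 and antisymmetric under exchanging the roles
    of orientation and velocity.
    """
    times, x, y, phi = _as_arrays(data)
    vx, vy = finite_difference_velocity(data, k)
    nvel = vx.shape[1]
    if lags is None:
        lags = np.arange(0, min(nvel, 400))
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 0) or np.any(lags >= nvel):
        raise ValueError(f"lags must lie in [0, {nvel - 1}]")
    dt = float(times[1] - times[0])
    nx = np.cos(phi)[:, :nvel]
    ny = np.sin(phi)[:, :nvel]
    nr = vx.shape[0]
    per_run = np.empty((nr, len(lags)))
    for j, L in enumerate(lags):
        if L == 0:
            per_run[:, j] = 0.0
            continue
        fwd = vx[:, L:] * nx[:, :-L] + vy[:, L:] * ny[:, :-L]
        bwd = vx[:, :-L] * nx[:, L:] + vy[:, :-L] * ny[:, L:]
        per_run[:, j] = (fwd - bwd).mean(axis=1)
    mean = per_run.mean(axis=0)
    sem = per_run.std(axis=0, ddof=1) / math.sqrt(nr) if nr > 1 else np.zeros_like(mean)
    return Curve(x=lags * dt, y=mean, kind="delay", sem=sem, n=np.full(len(lags), nr))


def orientation_correlation_empirical(data: Ensemble | Trajectory, lags=None) -> Curve:
    """Time-averaged <n(t + lag) . n(t)> with s.e.m. bands."""
    times, _, _, phi = _as_arrays(data)
    n = phi.shape[1]
    if lags is None:
        lags = np.arange(0, min(n - 1, 400))
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 0) or np.any(lags >= n):
        raise ValueError(f"lags must lie in [0, {n - 1}]")
    dt = float(times[1] - times[0])
    nx, ny = np.cos(phi), np.sin(phi)
    nr = phi.shape[0]
    per_run = np.empty((nr, len(lags)))
    for j, L in enumerate(lags):
        if L == 0:
            per_run[:, j] = 1.0
            continue
        per_run[:, j] = (nx[:, L:] * nx[:, :-L] + ny[:, L:] * ny[:, :-L]).mean(axis=1)
    mean = per_run.mean(axis=0)
    sem = per_run.std(axis=0, ddof=1) / math.sqrt(nr) if nr > 1 else np.zeros_like(mean)
    return Curve(x=lags * dt, y=mean, kind="correlation", sem=sem, n=np.full(len(lags), nr))


def compute_curveset(
    data: Ensemble | Trajectory,
    k: int = 1,
    msd_lags=None,
    delay_lags=None,
    corr_lags=None,
    bins=None,
    rotation_seed: int = 0,
) -> CurveSet:
    """All empirical observables of an ensemble in one container."""
    times, x, _, _ = _as_arrays(data)
    dt = float(times[1] - times[0])
    vx, vy = finite_difference_velocity(data, k)
    v2 = vx**2 + vy**2
    per_run_v2 = v2.mean(axis=1)
    nr = v2.shape[0]
    dists = empirical_distributions(data, k=k, bins=bins, rotation_seed=rotation_seed)
    return CurveSet(
        msd_trans=empirical_msd(data, lags=msd_lags, angular=False),
        msd_ang=empirical_msd(data, lags=msd_lags, angular=True),
        pdf_linear_velocity=dists["pdf_linear_velocity"],
        pdf_speed=dists["pdf_speed"],
        pdf_angular_velocity=dists["pdf_angular_velocity"],
        delay_curve=delay_function_empirical(data, k=k, lags=delay_lags),
        orientation_corr=orientation_correlation_empirical(data, lags=corr_lags),
        v2_mean=float(per_run_v2.mean()),
        v2_sem=float(per_run_v2.std(ddof=1) / math.sqrt(nr)) if nr > 1 else 0.0,
        dt=dt,
        k=k,
    )


def add_tracking_noise(
    ens: Ensemble,
    sigma_xy: float = TRACKING_NOISE_XY,
    sigma_phi: float = TRACKING_NOISE_PHI,
    seed: int = 0,
) -> Ensemble:
    """Emulate finite tracking accuracy with additive Gaussian noise.

    Defaults correspond to sub-pixel camera tracking of a centimetre-scale
    particle.  Returns a new ensemble; phi_dot (a model-internal quantity
    not observable by a tracker) is dropped.
    """
    rng = np.random.default_rng(seed)
    return Ensemble(
        params=ens.params,
        times=ens.times,
        x=ens.x + rng.normal(0.0, sigma_xy, ens.x.shape),
        y=ens.y + rng.normal(0.0, sigma_xy, ens.y.shape),
        phi=ens.phi + rng.normal(0.0, sigma_phi, ens.phi.shape),
        phi_dot=None,
        run_ids=list(ens.run_ids),
    )


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def write_trajectories(data: Ensemble | Trajectory, path) -> None:
    """Write an ensemble as long-format CSV: run,t,x,y,phi[,phi_dot] (SI, rad)."""
    if isinstance(data, Trajectory):
        data = Ensemble(
            params=data.params,
            times=data.times,
            x=data.x[None, :],
            y=data.y[None, :],
            phi=data.phi[None, :],
            phi_dot=None if data.phi_dot is None else data.phi_dot[None, :],
            run_ids=[data.run_id],
        )
    frames = []
    for i, rid in enumerate(data.run_ids):
        cols = {
            "run": np.full(len(data.times), rid, dtype=int),
            "t": data.times,
            "x": data.x[i],
            "y": data.y[i],
            "phi": data.phi[i],
        }
        if data.phi_dot is not None:
            cols["phi_dot"] = data.phi_dot[i]
        frames.append(pd.DataFrame(cols))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_trajectories(path) -> Ensemble:
    """Read a trajectory CSV (long format with a run column, or single-run).

    Times must be uniform within 1e-9 s and strictly increasing per run;
    violations are reported with the offending file line number.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as err:
        raise ValueError(f"malformed trajectory file {path}: {err}") from err
    required = {"t", "x", "y", "phi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in required | ({"phi_dot"} & set(df.columns)):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}")
    if "run" not in df.columns:
        df = df.assign(run=0)
    has_pd = "phi_dot" in df.columns
    run_ids, xs, ys, phis, pds = [], [], [], [], []
    times = None
    for rid, grp in df.groupby("run", sort=True):
        t = grp["t"].to_numpy(dtype=float)
        dts = np.diff(t)
        if np.any(dts <= 0):
            line = grp.index[int(np.argmax(dts <= 0)) + 1] + 2
            raise ValueError(f"{path}: non-monotone time at line {line} (run {rid})")
        if len(dts) and np.ptp(dts) > 1e-9:
            line = grp.index[int(np.argmax(np.abs(dts - dts[0]) > 1e-9)) + 1] + 2
            raise ValueError(f"{path}: non-uniform time step at line {line} (run {rid})")
        if times is None:
            times = t
        elif len(t) != len(times) or np.max(np.abs(t - times)) > 1e-9:
            raise ValueError(f"{path}: run {rid} has a different sampling grid")
        run_ids.append(int(rid))
        xs.append(grp["x"].to_numpy(dtype=float))
        ys.append(grp["y"].to_numpy(dtype=float))
        phis.append(grp["phi"].to_numpy(dtype=float))
        if has_pd:
            pds.append(grp["phi_dot"].to_numpy(dtype=float))
    return Ensemble(
        params=None,
        times=times,
        x=np.vstack(xs),
        y=np.vstack(ys),
        phi=np.vstack(phis),
        phi_dot=np.vstack(pds) if has_pd else None,
        run_ids=run_ids,
    )
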