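"""Parameter containers and unit conventions for the inertial active Brownian particle model.

The translational and rotational Langevin equations

    M R''(t) + xi R'(t)    = xi V_p n(t) + xi sqrt(2 D)   f(t)
    J phi''(t) + xi_r phi'(t) = tau_0    + xi_r sqrt(2 D_r) eta(t)

are identifiable from trajectories only through six rate-level parameters:
the friction (relaxation) times ``tau = M/xi`` and ``tau_r = J/xi_r``, the
short-time diffusion coefficients ``D`` (m^2/s) and ``D_r`` (rad^2/s), the
propulsion speed ``V_p`` (m/s) and the mean angular velocity
``omega = tau_0/xi_r`` (rad/s).  Absolute scales (M, J, xi, xi_r, tau_0) are
optional metadata; when present they must be mutually consistent with the
rates.  All quantities are SI (m, s, kg, rad); angles are stored unwrapped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParams",
    "DelayNumbers",
    "ParticleState",
    "make_params",
    "delay_numbers",
    "load_params",
    "dump_params",
]

#: relative tolerance for consistency of redundant absolute scales
_SCALE_RTOL = 1e-12


class ParameterError(ValueError):
    """Raised when a parameter set violates the model invariants."""


@dataclass(frozen=True)
class ModelParams:
    """The six identifiable rates plus optional absolute scales.

    Attributes
    ----------
    tau : float
        Translational friction (velocity relaxation) time ``M/xi`` in s.
    tau_r : float
        Rotational friction time ``J/xi_r`` in s.
    D : float
        Translational short-time diffusion coefficient in m^2/s.
    D_r : float
        Rotational diffusion coefficient in rad^2/s.
    V_p : float
        Propulsion speed in m/s.
    omega : float
        Mean angular velocity ``tau_0/xi_r`` in rad/s (any sign).
    M, J, xi, xi_r, tau_0 : float or None
        Optional absolute scales (kg, kg m^2, kg/s, kg m^2/s, N m).
    """

    tau: float
    tau_r: float
    D: float
    D_r: float
    V_p: float
    omega: float
    M: float | None = None
    J: float | None = None
    xi: float | None = None
    xi_r: float | None = None
    tau_0: float | None = None

    def __post_init__(self) -> None:
        for name in ("tau", "tau_r"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be positive and finite, got {v!r}")
        for name in ("D", "D_r", "V_p"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ParameterError(f"{name} must be non-negative and finite, got {v!r}")
        if not np.isfinite(self.omega):
            raise ParameterError(f"omega must be finite, got {self.omega!r}")
        self._check_scales()

    def _check_scales(self) -> None:
        def close(a: float, b: float) -> bool:
            return math.isclose(a, b, rel_tol=_SCALE_RTOL, abs_tol=0.0)

        if (self.M is not None) and (self.xi is not None):
            if not close(self.tau * self.xi, self.M):
                raise ParameterError(
                    f"inconsistent absolute scales: tau*xi = {self.tau * self.xi!r} != M = {self.M!r}"
                )
        if (self.J is not None) and (self.xi_r is not None):
            if not close(self.tau_r * self.xi_r, self.J):
                raise ParameterError(
                    f"inconsistent absolute scales: tau_r*xi_r = {self.tau_r * self.xi_r!r} != J = {self.J!r}"
                )
        if (self.tau_0 is not None) and (self.xi_r is not None):
            if not close(self.omega * self.xi_r, self.tau_0):
                raise ParameterError(
                    f"inconsistent absolute scales: omega*xi_r = {self.omega * self.xi_r!r} != tau_0 = {self.tau_0!r}"
                )

    # -- convenience -------------------------------------------------------
    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (scales dropped if stale)."""
        rate_names = {"tau", "tau_r", "D", "D_r", "V_p", "omega"}
        if rate_names & set(changes):
            # rates changed: drop absolute scales rather than carry stale ones
            drop = {n: changes.get(n) for n in ("M", "J", "xi", "xi_r", "tau_0")}
            changes = {**changes, **drop}
        return replace(self, **changes)

    def as_dict(self, include_scales: bool = True) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if not include_scales:
            d = {k: d[k] for k in ("tau", "tau_r", "D", "D_r", "V_p", "omega")}
        return {k: v for k, v in d.items() if v is not None}


@dataclass(frozen=True)
class DelayNumbers:
    """Dimensionless delay numbers (D0, D1, D2) = (D_r tau_r, omega tau_r, tau_r/tau)."""

    d0: float
    d1: float
    d2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d0) and self.d0 >= 0):
            raise ParameterError(f"d0 must be non-negative, got {self.d0!r}")
        if not (np.isfinite(self.d2) and self.d2 > 0):
            raise ParameterError(f"d2 must be positive, got {self.d2!r}")
        if not np.isfinite(self.d1):
            raise ParameterError(f"d1 must be finite, got {self.d1!r}")


@dataclass
class ParticleState:
    """Instantaneous kinematic state (t, R, R', phi, phi'); phi unwrapped."""

    t: float
    position: tuple[float, float]
    velocity: tuple[float, float]
    phi: float
    phi_dot: float

    def __post_init__(self) -> None:
        vals = (self.t, *self.position, *self.velocity, self.phi, self.phi_dot)
        if not all(np.isfinite(v) for v in vals):
            raise ParameterError(f"non-finite entry in particle state: {vals!r}")

    @property
    def orientation(self) -> tuple[float, float]:
        """Unit orientation vector n = (cos phi, sin phi)."""
        return (math.cos(self.phi), math.sin(self.phi))


# keys accepted by make_params; rate aliases give the friction *rates* xi/M, xi_r/J
_RATE_ALIASES = {
    "xi_over_M": "tau",
    "xi_r_over_J": "tau_r",
}
_FIELD_NAMES = {f.name for f in fields(ModelParams)}
_KNOWN_KEYS = _FIELD_NAMES | set(_RATE_ALIASES)


def make_params(raw: Mapping[str, float]) -> ModelParams:
    """Build and validate :class:`ModelParams` from a flat map of named coefficients.

    Accepts the field names directly, or the friction rates as printed in the
    figure captions: ``xi_over_M`` (= 1/tau, s^-1) and ``xi_r_over_J``
    (= 1/tau_r, s^-1); reciprocal conversions are applied exactly.  Missing
    rates are derived from absolute scales where possible (tau = M/xi,
    tau_r = J/xi_r, omega = tau_0/xi_r).  Unknown keys are rejected.
    """
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
    d: dict[str, float] = {}
    for key, value in raw.items():
        if key in _RATE_ALIASES:
            target = _RATE_ALIASES[key]
            if value <= 0 or not np.isfinite(value):
                raise ParameterError(f"{key} must be positive and finite, got {value!r}")
            d[target] = 1.0 / value
        else:
            d[key] = float(value)
    # derive rates from absolute scales when absent
    if "tau" not in d and {"M", "xi"} <= set(d):
        d["tau"] = d["M"] / d["xi"]
    if "tau_r" not in d and {"J", "xi_r"} <= set(d):
        d["tau_r"] = d["J"] / d["xi_r"]
    if "omega" not in d and {"tau_0", "xi_r"} <= set(d):
        d["omega"] = d["tau_0"] / d["xi_r"]
    missing = {"tau", "tau_r", "D", "D_r", "V_p", "omega"} - set(d)
    if missing:
        raise ParameterError(f"missing required parameters: {sorted(missing)}")
    return ModelParams(**d)


def delay_numbers(p: ModelParams) -> DelayNumbers:
    """Dimensionless delay numbers D0 = D_r tau_r, D1 = omega tau_r, D2 = tau_r/tau."""
    return DelayNumbers(d0=p.D_r * p.tau_r, d1=p.omega * p.tau_r, d2=p.tau_r / p.tau)


def load_params(path: str | Path) -> ModelParams:
    """Read a parameter file (.json or .toml, flat key-value) into ModelParams."""
    path = Path(path)
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
    elif path.suffix == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text())
    else:
        raise ParameterError(f"unsupported parameter file type: {path.suffix!r}")
    if not isinstance(raw, dict):
        raise ParameterError("parameter file must contain a flat key-value table")
    return make_params(raw)


def dump_params(p: ModelParams, path: str | Path) -> None:
    """Write ModelParams as JSON; round-trips exactly through load_params."""
    Path(path).write_text(json.dumps(p.as_dict(), indent=2, sort_keys=True) + "\n")
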