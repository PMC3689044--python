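"""Reaction kinetics: enzyme mass action and coupled glucose/pH feedback.

Two layers:

* the elementary enzyme scheme E + S <-> ES -> E + P integrated as mass
  action ODEs, with its Michaelis-Menten quasi-steady-state reduction
  v = Vmax S / (Km + S), Km = (kr + kcat) / kf, for cross-validation;

* a minimal two-species phase-lagged feedback system

      dx/dt =  a x - b x y
      dy/dt = -c y + d x y

  (Lotka-Volterra form) standing in for coupled glucose and pH
  oscillations.  Positive orbits cycle around the equilibrium
  (c/d, a/b); the first integral

      V(x, y) = d x - c ln x + b y - a ln y

  is conserved along trajectories and is used to validate the
  integrator (fixed-step classical Runge-Kutta, 4th order).

Stoichiometric bookkeeping constants: glycolysis yields 2 NADH and
4 ADP-level phosphorylations per glucose (documented only; not a model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "EnzymeParams",
    "OdeParams",
    "Trajectory",
    "simulate_enzyme",
    "mm_velocity",
    "integrate_coupled",
    "equilibrium",
    "conserved_quantity",
    "NADH_PER_GLUCOSE",
    "ADP_PER_GLUCOSE",
]

NADH_PER_GLUCOSE = 2
ADP_PER_GLUCOSE = 4


@dataclass(frozen=True)
class EnzymeParams:
    """Mass-action rates for E + S <-> ES -> E + P."""

    kf: float  # forward binding, conc^-1 s^-1
    kr: float  # unbinding, s^-1
    kcat: float  # product formation, s^-1
    e_total: float  # total enzyme, conc
    s0: float  # initial substrate, conc

    def __post_init__(self) -> None:
        for name in ("kf", "kr", "kcat"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in ("e_total", "s0"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    @property
    def km(self) -> float:
        if self.kf == 0:
            raise ValueError("Km undefined for kf = 0")
        return (self.kr + self.kcat) / self.kf


@dataclass(frozen=True)
class OdeParams:
    """Coefficients and integration settings for the coupled system."""

    a: float = 0.3
    b: float = 0.4
    c: float = 0.2
    d: float = 0.2
    x0: float = 0.5
    y0: float = 0.5
    t_end: float = 200.0
    dt: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        for name in ("x0", "y0"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not (math.isfinite(self.dt) and self.dt > 0) or self.t_end <= 0:
            raise ValueError("t_end and dt must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Time series of an integrated system."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_vars)
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.columns))
        df.insert(0, "t", self.times)
        return df

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]


def simulate_enzyme(p: EnzymeParams, t_end: float = 50.0, dt: float = 0.1) -> Trajectory:
    """Integrate the mass-action enzyme scheme over (E, S, ES, P).

    Uses a stiff-capable adaptive solver at tight tolerance; the two
    linear conservation laws E + ES = e_total and S + ES + P = s0 hold
    at every output time within the integration tolerance (< 1e-8
    relative drift at the defaults).
    """
    if t_end <= 0 or dt <= 0:
        raise ValueError("t_end and dt must be positive")

    def rhs(_t, z):
        E, S, ES, _P = z
        bind = p.kf * E * S
        unbind = p.kr * ES
        cat = p.kcat * ES
        return [-bind + unbind + cat, -bind + unbind, bind - unbind - cat, cat]

    t_eval = np.arange(0.0, t_end + dt / 2, dt)
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])),
        [p.e_total, p.s0, 0.0, 0.0],
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"enzyme integration failed: {sol.message}")
    return Trajectory(times=sol.t, states=sol.y.T, columns=("E", "S", "ES", "P"))


def mm_velocity(s, vmax: float, km: float):
    """Michaelis-Menten initial velocity v = vmax s / (km + s)."""
    if vmax <= 0 or km <= 0:
        raise ValueError("vmax and km must be > 0")
    arr = np.asarray(s, float)
    if np.any(arr < 0):
        raise ValueError("substrate concentration must be >= 0")
    v = vmax * arr / (km + arr)
    return float(v) if np.ndim(s) == 0 else v


def integrate_coupled(p: OdeParams) -> Trajectory:
    """Integrate the coupled feedback system with fixed-step RK4.

    The fixed step makes runs bit-for-bit reproducible and gives clean
    4th-order convergence of the first-integral drift.  Raises if the
    orbit leaves the positive quadrant, which at reasonable parameters
    only happens when dt is too large for the orbit's stiffness.
    """
    a, b, c, d = p.a, p.b, p.c, p.d
    dt = p.dt
    n = int(round(p.t_end / dt))
    times = np.arange(n + 1) * dt
    states = np.empty((n + 1, 2))
    x, y = p.x0, p.y0
    states[0] = (x, y)
    h2 = dt / 2.0
    h6 = dt / 6.0
    for i in range(1, n + 1):
        k1x = a * x - b * x * y
        k1y = -c * y + d * x * y
        x2 = x + h2 * k1x
        y2 = y + h2 * k1y
        k2x = a * x2 - b * x2 * y2
        k2y = -c * y2 + d * x2 * y2
        x3 = x + h2 * k2x
        y3 = y + h2 * k2y
        k3x = a * x3 - b * x3 * y3
        k3y = -c * y3 + d * x3 * y3
        x4 = x + dt * k3x
        y4 = y + dt * k3y
        k4x = a * x4 - b * x4 * y4
        k4y = -c * y4 + d * x4 * y4
        x = x + h6 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
        y = y + h6 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
        if x <= 0.0 or y <= 0.0 or not (math.isfinite(x) and math.isfinite(y)):
            raise ValueError(
                f"state left the positive quadrant at t={i * dt:g}; "
                "use a smaller dt"
            )
        states[i] = (x, y)
    return Trajectory(times=times, states=states, columns=("x", "y"))


def equilibrium(p: OdeParams) -> tuple[float, float]:
    """The unique positive stationary point (c/d, a/b)."""
    return p.c / p.d, p.a / p.b


def conserved_quantity(state, p: OdeParams):
    """First integral V = d x - c ln x + b y - a ln y.

    Constant along exact trajectories of the coupled system; its drift
    under numerical integration measures integrator error.  Accepts a
    (x, y) pair of scalars or arrays.
    """
    x = np.asarray(state[0], float)
    y = np.asarray(state[1], float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("V is defined only for positive states")
    v = p.d * x - p.c * np.log(x) + p.b * y - p.a * np.log(y)
    return float(v) if v.ndim == 0 else v
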