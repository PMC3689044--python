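"""Single sine-circle-map oscillator.

The map

    theta_{t+1} = theta_t + (kappa / 2 pi) * sin(m pi theta_t)

with harmonic ``m = 2`` is used here as a minimal model of a glycolytic
oscillator: ``kappa`` plays the role of the glucose drive, and increasing
it carries the orbit through a period-doubling cascade (fixed point ->
2-cycle -> 4-cycle -> aperiodic).  No modular reduction is applied during
iteration — the raw difference equation is iterated as printed — but orbit
classification works on fractional parts, since the map commutes with
integer shifts of theta.

The nontrivial fixed points satisfy sin(m pi theta*) = 0; at the stable
one the multiplier is 1 - kappa m / 2, so the first period doubling occurs
at kappa = 4 / m (kappa = 2 for the default harmonic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CircleMapParams",
    "Orbit",
    "AttractorLabel",
    "step",
    "iterate",
    "classify_attractor",
    "stability_boundary",
    "bifurcation_scan",
    "scan_attractors",
]

#: default iteration counts (bifurcation diagrams are computed after
#: 10,000 iterations; the last 1,000 are kept for classification)
DEFAULT_N_ITER = 10_000
DEFAULT_TRANSIENT = 9_000
DEFAULT_TOL = 1e-6
DEFAULT_MAX_PERIOD = 64
BLOWUP_BOUND = 1e6


@dataclass(frozen=True)
class CircleMapParams:
    """Parameters of the sine-circle map.

    Parameters
    ----------
    kappa : float
        Bifurcation/drive parameter, dimensionless, >= 0.
    harmonic : int
        Integer m >= 2 in the sine argument ``sin(m pi theta)``.  The
        default m = 2 gives the standard ``sin(2 pi theta)``; larger
        harmonics shift the bifurcation points (boundary at 4/m).
    theta0 : float
        Initial state.
    """

    kappa: float
    harmonic: int = 2
    theta0: float = 0.3

    def __post_init__(self) -> None:
        if not math.isfinite(self.kappa) or self.kappa < 0:
            raise ValueError(f"kappa must be finite and >= 0, got {self.kappa}")
        if not isinstance(self.harmonic, (int, np.integer)) or self.harmonic < 2:
            raise ValueError(f"harmonic must be an integer >= 2, got {self.harmonic}")
        if not math.isfinite(self.theta0):
            raise ValueError(f"theta0 must be finite, got {self.theta0}")


@dataclass(frozen=True)
class Orbit:
    """An iterated trajectory of the map.

    ``states`` has length ``n_iter + 1`` (it includes theta0).  The
    ``divergent`` flag is set when any state exceeds the blow-up bound
    or is non-finite.
    """

    states: np.ndarray
    transient: int
    n_iter: int
    divergent: bool = False

    def __post_init__(self) -> None:
        if len(self.states) != self.n_iter + 1:
            raise ValueError("orbit length must equal n_iter + 1")

    @property
    def post_transient(self) -> np.ndarray:
        return self.states[self.transient + 1 :]


@dataclass(frozen=True)
class AttractorLabel:
    """Classification of an orbit.

    ``kind`` is one of ``fixed_point``, ``cycle``, ``aperiodic``,
    ``divergent``; ``period`` is defined only for the first two
    (``fixed_point`` is exactly period 1).
    """

    kind: str
    period: int | None
    tolerance: float

    _KINDS = frozenset({"fixed_point", "cycle", "aperiodic", "divergent"})

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown attractor kind {self.kind!r}")
        has_period = self.period is not None
        if has_period != (self.kind in ("fixed_point", "cycle")):
            raise ValueError("period is defined iff kind is fixed_point or cycle")
        if self.kind == "fixed_point" and self.period != 1:
            raise ValueError("fixed_point implies period 1")


def step(theta, params: CircleMapParams):
    """One application of the map: theta + (kappa/2pi) sin(m pi theta).

    Accepts a scalar or an ndarray (applied elementwise).  No modular
    wrapping is performed.
    """
    arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("theta must be finite")
    out = arr + params.kappa / (2.0 * np.pi) * np.sin(params.harmonic * np.pi * arr)
    if np.ndim(theta) == 0:
        return float(out)
    return out


def iterate(
    params: CircleMapParams,
    n_iter: int = DEFAULT_N_ITER,
    transient: int = DEFAULT_TRANSIENT,
    blowup_bound: float = BLOWUP_BOUND,
) -> Orbit:
    """Generate an orbit of ``n_iter`` map applications from theta0.

    The orbit is flagged divergent if any iterate leaves
    ``[-blowup_bound, blowup_bound]`` or becomes non-finite.
    """
    if n_iter < transient or transient < 0:
        raise ValueError("require n_iter >= transient >= 0")
    states = np.empty(n_iter + 1)
    states[0] = params.theta0
    c = params.kappa / (2.0 * math.pi)
    w = params.harmonic * math.pi
    th = params.theta0
    divergent = False
    for t in range(1, n_iter + 1):
        th = th + c * math.sin(w * th)
        states[t] = th
        if not math.isfinite(th) or abs(th) > blowup_bound:
            divergent = True
            states[t:] = th
            break
    return Orbit(states=states, transient=transient, n_iter=n_iter, divergent=divergent)


def _circle_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance between fractional parts on the unit circle."""
    d = np.abs(a - b)
    return np.minimum(d, 1.0 - d)


def classify_attractor(
    orbit: Orbit,
    tol: float = DEFAULT_TOL,
    max_period: int = DEFAULT_MAX_PERIOD,
) -> AttractorLabel:
    """Classify an orbit as fixed point, p-cycle, aperiodic or divergent.

    The smallest period p <= ``max_period`` such that every post-transient
    pair (theta_t, theta_{t+p}) agrees within ``tol`` wins.  Comparison is
    on fractional parts with circular distance, so the label is invariant
    under integer shifts of the whole orbit.
    """
    if orbit.divergent:
        return AttractorLabel(kind="divergent", period=None, tolerance=tol)
    pts = np.mod(orbit.post_transient, 1.0)
    if len(pts) < 2 * max_period:
        raise ValueError(
            f"need >= {2 * max_period} post-transient points, got {len(pts)}"
        )
    for p in range(1, max_period + 1):
        if np.max(_circle_distance(pts[p:], pts[:-p])) < tol:
            kind = "fixed_point" if p == 1 else "cycle"
            return AttractorLabel(kind=kind, period=p, tolerance=tol)
    return AttractorLabel(kind="aperiodic", period=None, tolerance=tol)


def stability_boundary(harmonic: int = 2) -> float:
    """Kappa at which the stable nontrivial fixed point loses stability.

    Fixed points solve sin(m pi theta*) = 0; the multiplier there is
    1 + (kappa m / 2) cos(m pi theta*).  At the stable branch
    (cos = -1) the multiplier crosses -1, hence period doubling, at

        kappa = 4 / m.

    For the default harmonic m = 2 this is the hard boundary kappa = 2
    seen in the coupled-lattice phase diagram.
    """
    if not isinstance(harmonic, (int, np.integer)) or harmonic < 2:
        raise ValueError(f"harmonic must be an integer >= 2, got {harmonic}")
    return 4.0 / harmonic


def _iterate_grid(
    kappa_grid: np.ndarray,
    params: CircleMapParams,
    n_iter: int,
    n_keep: int,
    blowup_bound: float = BLOWUP_BOUND,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised iteration over a kappa grid.

    Returns (kept, divergent): ``kept`` has shape (n_keep, n_kappa) and
    holds the last ``n_keep`` raw states; ``divergent`` flags each kappa.
    """
    kappa = np.asarray(kappa_grid, dtype=float)
    th = np.full(kappa.shape, params.theta0)
    c = kappa / (2.0 * np.pi)
    w = params.harmonic * np.pi
    kept = np.empty((n_keep, kappa.size))
    divergent = np.zeros(kappa.shape, dtype=bool)
    start = n_iter - n_keep
    for t in range(1, n_iter + 1):
        th = th + c * np.sin(w * th)
        bad = ~np.isfinite(th) | (np.abs(th) > blowup_bound)
        if bad.any():
            divergent |= bad
            th = np.where(bad, 0.0, th)  # freeze runaway columns
        if t > start:
            kept[t - start - 1] = th
    return kept, divergent


def bifurcation_scan(
    kappa_grid: Sequence[float],
    params: CircleMapParams | None = None,
    n_iter: int = DEFAULT_N_ITER,
    n_keep: int = 100,
) -> pd.DataFrame:
    """Post-transient states over a kappa grid (a bifurcation diagram).

    For each kappa the last ``n_keep`` states are reduced to fractional
    parts and returned in long format with columns ``kappa, theta``.
    """
    kappa = np.asarray(list(kappa_grid), dtype=float)
    if kappa.size == 0:
        raise ValueError("kappa_grid must be non-empty")
    if params is None:
        params = CircleMapParams(kappa=float(kappa[0]))
    if n_keep > n_iter:
        raise ValueError("n_keep must not exceed n_iter")
    kept, _ = _iterate_grid(kappa, params, n_iter, n_keep)
    frac = np.mod(kept, 1.0)
    return pd.DataFrame(
        {
            "kappa": np.repeat(kappa, n_keep),
            "theta": frac.T.ravel(),
        }
    )


def scan_attractors(
    kappa_grid: Sequence[float],
    params: CircleMapParams | None = None,
    n_iter: int = DEFAULT_N_ITER,
    transient: int = DEFAULT_TRANSIENT,
    tol: float = DEFAULT_TOL,
    max_period: int = DEFAULT_MAX_PERIOD,
) -> pd.DataFrame:
    """Attractor classification along a kappa grid.

    Vectorised equivalent of ``classify_attractor(iterate(...))`` per
    kappa.  Returns a frame with columns ``kappa, kind, period`` (period
    is NaN for aperiodic/divergent rows).
    """
    kappa = np.asarray(list(kappa_grid), dtype=float)
    if kappa.size == 0:
        raise ValueError("kappa_grid must be non-empty")
    if params is None:
        params = CircleMapParams(kappa=float(kappa[0]))
    n_keep = n_iter - transient
    if n_keep < 2 * max_period:
        raise ValueError("need n_iter - transient >= 2 * max_period")
    kept, divergent = _iterate_grid(kappa, params, n_iter, n_keep)
    frac = np.mod(kept, 1.0)
    period = np.full(kappa.shape, -1, dtype=int)
    for p in range(1, max_period + 1):
        unassigned = period < 0
        if not unassigned.any():
            break
        dist = _circle_distance(frac[p:], frac[:-p]).max(axis=0)
        hit = unassigned & ~divergent & (dist < tol)
        period[hit] = p
    kinds = np.where(
        divergent,
        "divergent",
        np.where(period == 1, "fixed_point", np.where(period > 1, "cycle", "aperiodic")),
    )
    return pd.DataFrame(
        {
            "kappa": kappa,
            "kind": kinds,
            "period": np.where(period > 0, period, np.nan),
        }
    )
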