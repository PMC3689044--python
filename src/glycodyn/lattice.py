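"""Coupled map lattice of sine-circle oscillators.

Two coupling schemes are implemented:

* **diffusive** — the classic nearest-neighbour averaging

      x'(i) = (1 - eps) f(x(i)) + (eps/2) [f(x(i+1)) + f(x(i-1))]

  with f the sine-circle map;

* **threshold** — sandpile-like adaptive transfer: after every site takes
  a map step, any site whose value exceeds the threshold x* sends its
  excess delta(i) = x(i) - x* to one fixed neighbour (rightward by
  default; the symmetry-breaking direction is preserved for the whole
  run).  Two variants exist: the ``literal`` variant only adds the excess
  to the receiver, exactly as the update rule reads, and can blow up
  (e.g. x* = 0.15, kappa = 1.0); the ``conservative`` variant also resets
  the sender to x*, which makes the transfer phase conserve the lattice
  sum exactly.

All updates are phase-synchronous (map sweep, threshold sweep, transfer
sweep), so results are independent of site ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .circle_map import (
    DEFAULT_MAX_PERIOD,
    DEFAULT_N_ITER,
    DEFAULT_TOL,
    DEFAULT_TRANSIENT,
    AttractorLabel,
    _circle_distance,
)

__all__ = [
    "LatticeConfig",
    "LatticeState",
    "LatticeRun",
    "PhaseDiagram",
    "diffusive_step",
    "threshold_step",
    "run_lattice",
    "classify_lattice",
    "phase_diagram",
]


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry, map parameters and coupling scheme of the lattice."""

    size: int
    kappa: float
    harmonic: int = 2
    coupling_mode: str = "threshold"
    epsilon: float | None = None
    x_star: float | None = None
    transfer_variant: str = "conservative"
    boundary: str = "periodic"
    direction: str = "right"
    seed: int = 0
    blowup_bound: float = 1e6

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("lattice size must be >= 2")
        if self.kappa < 0 or not np.isfinite(self.kappa):
            raise ValueError("kappa must be finite and >= 0")
        if self.harmonic < 2:
            raise ValueError("harmonic must be >= 2")
        if self.coupling_mode not in ("diffusive", "threshold"):
            raise ValueError(f"unknown coupling_mode {self.coupling_mode!r}")
        if self.coupling_mode == "diffusive":
            if self.epsilon is None or not 0.0 <= self.epsilon <= 1.0:
                raise ValueError("diffusive mode requires epsilon in [0, 1]")
        else:
            if self.x_star is None or not np.isfinite(self.x_star):
                raise ValueError("threshold mode requires a finite x_star")
        if self.transfer_variant not in ("conservative", "literal"):
            raise ValueError(f"unknown transfer_variant {self.transfer_variant!r}")
        if self.boundary not in ("periodic", "open"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.direction not in ("right", "left"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.blowup_bound <= 0:
            raise ValueError("blowup_bound must be positive")


@dataclass(frozen=True)
class LatticeState:
    """Site values x(i) at iteration index t."""

    x: np.ndarray
    t: int = 0

    @property
    def divergent(self) -> bool:
        return bool(~np.all(np.isfinite(self.x)) or np.any(np.abs(self.x) > 1e6))


@dataclass(frozen=True)
class LatticeRun:
    """A full lattice trajectory: states has shape (n_steps + 1, N)."""

    states: np.ndarray
    transient: int
    divergent: bool
    config: LatticeConfig

    @property
    def post_transient(self) -> np.ndarray:
        return self.states[self.transient + 1 :]

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns t, site, value."""
        n_t, n_sites = self.states.shape
        return pd.DataFrame(
            {
                "t": np.repeat(np.arange(n_t), n_sites),
                "site": np.tile(np.arange(n_sites), n_t),
                "value": self.states.ravel(),
            }
        )


@dataclass(frozen=True)
class PhaseDiagram:
    """Classification of lattice dynamics over an (x*, kappa) grid."""

    x_star_grid: np.ndarray
    kappa_grid: np.ndarray
    kinds: np.ndarray  # (n_xstar, n_kappa) array of str labels
    periods: np.ndarray  # matching float array, NaN where no period

    def __post_init__(self) -> None:
        shape = (len(self.x_star_grid), len(self.kappa_grid))
        if self.kinds.shape != shape or self.periods.shape != shape:
            raise ValueError("label grid dimensions must match axes")

    def label(self, i: int, j: int) -> AttractorLabel:
        kind = str(self.kinds[i, j])
        p = self.periods[i, j]
        return AttractorLabel(
            kind=kind,
            period=int(p) if np.isfinite(p) else None,
            tolerance=DEFAULT_TOL,
        )

    def to_frame(self) -> pd.DataFrame:
        xs, ks = np.meshgrid(self.x_star_grid, self.kappa_grid, indexing="ij")
        return pd.DataFrame(
            {
                "x_star": xs.ravel(),
                "kappa": ks.ravel(),
                "label": self.kinds.ravel(),
                "period": self.periods.ravel(),
            }
        )


def _map_step(x: np.ndarray, kappa, harmonic: int) -> np.ndarray:
    """Elementwise sine-circle map; kappa may be scalar or broadcastable."""
    return x + kappa / (2.0 * np.pi) * np.sin(harmonic * np.pi * x)


def _neighbor_sum(fx: np.ndarray, boundary: str) -> np.ndarray:
    if boundary == "periodic":
        return np.roll(fx, 1, axis=-1) + np.roll(fx, -1, axis=-1)
    # open boundary: missing neighbour replaced by the site itself
    # (zero-flux), so a homogeneous state stays homogeneous
    left = np.empty_like(fx)
    right = np.empty_like(fx)
    left[..., 1:] = fx[..., :-1]
    left[..., 0] = fx[..., 0]
    right[..., :-1] = fx[..., 1:]
    right[..., -1] = fx[..., -1]
    return left + right


def diffusive_step(state: LatticeState, config: LatticeConfig) -> LatticeState:
    """One synchronous diffusive update of the whole lattice."""
    if config.coupling_mode != "diffusive":
        raise ValueError("config is not in diffusive mode")
    if state.divergent:
        raise ValueError("cannot step a divergent state")
    fx = _map_step(state.x, config.kappa, config.harmonic)
    eps = config.epsilon
    x_new = (1.0 - eps) * fx + (eps / 2.0) * _neighbor_sum(fx, config.boundary)
    return LatticeState(x=x_new, t=state.t + 1)


def _transfer(x: np.ndarray, config: LatticeConfig) -> np.ndarray:
    """Threshold + transfer sweeps (phases 2-4); x is post-map-step."""
    delta = np.maximum(x - config.x_star, 0.0)
    shift = -1 if config.direction == "right" else 1
    if config.boundary == "periodic":
        received = np.roll(delta, -shift, axis=-1)
    else:
        received = np.zeros_like(delta)
        if config.direction == "right":
            received[..., 1:] = delta[..., :-1]  # last site's excess discarded
        else:
            received[..., :-1] = delta[..., 1:]
    if config.transfer_variant == "conservative":
        x = np.where(delta > 0, config.x_star, x)
    return x + received


def threshold_step(state: LatticeState, config: LatticeConfig) -> LatticeState:
    """One synchronous threshold-transfer update (map, threshold, send).

    A divergent input propagates the divergent flag: the state is
    returned unchanged with the time index advanced.
    """
    if config.coupling_mode != "threshold":
        raise ValueError("config is not in threshold mode")
    if state.divergent:
        return LatticeState(x=state.x, t=state.t + 1)
    fx = _map_step(state.x, config.kappa, config.harmonic)
    return LatticeState(x=_transfer(fx, config), t=state.t + 1)


def run_lattice(
    config: LatticeConfig,
    n_iter: int = DEFAULT_N_ITER,
    transient: int = DEFAULT_TRANSIENT,
    init: Sequence[float] | None = None,
) -> LatticeRun:
    """Iterate the configured lattice, halting early on blow-up.

    Initial conditions are uniform [0, 1) draws from ``config.seed``
    unless an explicit ``init`` vector is given.
    """
    if n_iter < transient or transient < 0:
        raise ValueError("require n_iter >= transient >= 0")
    if init is None:
        rng = np.random.default_rng(config.seed)
        x = rng.uniform(0.0, 1.0, size=config.size)
    else:
        x = np.asarray(init, dtype=float)
        if x.shape != (config.size,):
            raise ValueError(f"init must have length {config.size}")
    stepper = diffusive_step if config.coupling_mode == "diffusive" else threshold_step
    states = np.empty((n_iter + 1, config.size))
    states[0] = x
    st = LatticeState(x=x, t=0)
    divergent = False
    bound = config.blowup_bound
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(1, n_iter + 1):
            st = stepper(st, config)
            states[t] = st.x
            if not np.all(np.isfinite(st.x)) or np.any(np.abs(st.x) > bound):
                divergent = True
                states[t + 1 :] = st.x
                break
    return LatticeRun(states=states, transient=transient, divergent=divergent, config=config)


def classify_lattice(
    run: LatticeRun,
    tol: float = DEFAULT_TOL,
    max_period: int = DEFAULT_MAX_PERIOD,
) -> AttractorLabel:
    """Classify a lattice trajectory by its global temporal period.

    The smallest p with sup-norm distance between x(t+p) and x(t) below
    ``tol`` (fractional parts, circular distance, all post-transient t)
    wins; divergence and aperiodicity are reported as such.
    """
    if run.divergent:
        return AttractorLabel(kind="divergent", period=None, tolerance=tol)
    pts = np.mod(run.post_transient, 1.0)
    if len(pts) < 2 * max_period:
        raise ValueError(
            f"need >= {2 * max_period} post-transient states, got {len(pts)}"
        )
    for p in range(1, max_period + 1):
        if np.max(_circle_distance(pts[p:], pts[:-p])) < tol:
            kind = "fixed_point" if p == 1 else "cycle"
            return AttractorLabel(kind=kind, period=p, tolerance=tol)
    return AttractorLabel(kind="aperiodic", period=None, tolerance=tol)


DEFAULT_X_STAR_GRID = np.round(np.arange(0.05, 1.0 + 1e-9, 0.05), 10)
DEFAULT_KAPPA_GRID = np.round(np.arange(0.5, 4.5 + 1e-9, 0.05), 10)


def phase_diagram(
    x_star_grid: Sequence[float] | None = None,
    kappa_grid: Sequence[float] | None = None,
    config: LatticeConfig | None = None,
    n_iter: int = DEFAULT_N_ITER,
    transient: int = DEFAULT_TRANSIENT,
    tol: float = DEFAULT_TOL,
    max_period: int = DEFAULT_MAX_PERIOD,
) -> PhaseDiagram:
    """Classify threshold-lattice dynamics over an (x*, kappa) grid.

    All grid cells are iterated simultaneously (one big batch), keeping a
    trailing window of 2 * ``max_period`` states per cell for the period
    search.  The default template uses the ``literal`` transfer variant,
    which is the one whose written update rule admits blow-up and hence
    produces the "undefined" (divergent) region of the diagram alongside
    fixed-point, n-cycle and aperiodic regions.

    Each cell shares the same seeded random initial state.
    """
    xs = DEFAULT_X_STAR_GRID if x_star_grid is None else np.asarray(list(x_star_grid), float)
    ks = DEFAULT_KAPPA_GRID if kappa_grid is None else np.asarray(list(kappa_grid), float)
    if xs.size == 0 or ks.size == 0:
        raise ValueError("grids must be non-empty")
    if config is None:
        config = LatticeConfig(
            size=64, kappa=1.0, coupling_mode="threshold", x_star=0.5,
            transfer_variant="literal",
        )
    if config.coupling_mode != "threshold":
        raise ValueError("phase_diagram requires a threshold-mode config")
    n_keep = 2 * max_period
    if n_iter - transient < n_keep:
        raise ValueError("need n_iter - transient >= 2 * max_period")

    n_cells = xs.size * ks.size
    N = config.size
    rng = np.random.default_rng(config.seed)
    x0 = rng.uniform(0.0, 1.0, size=N)
    x = np.broadcast_to(x0, (n_cells, N)).copy()
    xstar_col = np.repeat(xs, ks.size)[:, None]  # (n_cells, 1)
    kappa_col = np.tile(ks, xs.size)[:, None]
    shift = -1 if config.direction == "right" else 1
    conservative = config.transfer_variant == "conservative"
    bound = config.blowup_bound
    divergent = np.zeros(n_cells, dtype=bool)
    kept = np.empty((n_keep, n_cells, N))
    start = n_iter - n_keep
    harmonic = config.harmonic
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(1, n_iter + 1):
            fx = x + kappa_col / (2.0 * np.pi) * np.sin(harmonic * np.pi * x)
            delta = np.maximum(fx - xstar_col, 0.0)
            if config.boundary == "periodic":
                received = np.roll(delta, -shift, axis=-1)
            else:
                received = np.zeros_like(delta)
                if config.direction == "right":
                    received[:, 1:] = delta[:, :-1]
                else:
                    received[:, :-1] = delta[:, 1:]
            if conservative:
                fx = np.where(delta > 0, xstar_col, fx)
            x_new = fx + received
            bad = ~np.all(np.isfinite(x_new), axis=-1) | (
                np.max(np.abs(np.where(np.isfinite(x_new), x_new, 0.0)), axis=-1) > bound
            )
            newly = bad & ~divergent
            if newly.any():
                divergent |= newly
            x = np.where(divergent[:, None], x, x_new)  # freeze diverged cells
            if t > start:
                kept[t - start - 1] = x

    frac = np.mod(kept, 1.0)
    period = np.full(n_cells, -1, dtype=int)
    for p in range(1, max_period + 1):
        if not (period < 0).any():
            break
        dist = _circle_distance(frac[p:], frac[:-p]).max(axis=(0, 2))
        hit = (period < 0) & ~divergent & (dist < tol)
        period[hit] = p
    kinds = np.where(
        divergent,
        "divergent",
        np.where(period == 1, "fixed_point", np.where(period > 1, "cycle", "aperiodic")),
    ).reshape(xs.size, ks.size)
    periods = np.where(period > 0, period, np.nan).reshape(xs.size, ks.size).astype(float)
    return PhaseDiagram(x_star_grid=xs, kappa_grid=ks, kinds=kinds, periods=periods)
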