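"""Convection-analog characteristic times for glycolytic oscillations.

A heated fluid layer transitions from conduction to ordered convection
rolls once the Rayleigh number exceeds a critical value; the roll
turnover has characteristic time

    tau_RB = mu / (rho g alpha_T d deltaT).

By analogy, a cell exposed to an external nutrient gradient deltaC is
assigned the characteristic oscillation time

    tau = nu / (Phi alpha deltaC)

where nu is the cytoplasmic kinematic viscosity (cm^2 s^-1), Phi the
specific energy density of metabolism (erg g^-1 = cm^2 s^-2), and alpha
an expansion-coefficient analog with units inverse to the concentration
(alpha * deltaC is dimensionless).  Because the specific metabolic rate
falls with size/concentration with exponents between -0.5 and 0, Phi is
allowed to depend on the gradient through a power law

    Phi(deltaC) = Phi0 * (deltaC / c_ref) ** beta,   beta in [-0.5, 0],

and the module fits (Phi0, beta) to observed period-versus-concentration
tables by weighted least squares in log space (relative, ~10%, errors).

Units note: the analogy requires Phi to be a specific energy density
(erg g^-1); literature "energy rate density" values are quoted per
second (erg g^-1 s^-1) and cannot be inserted directly — see
``dimension_check``.  Likewise nu is kinematic (cm^2 s^-1): a dynamic
viscosity of 10 P at unit (1 g cm^-3) density gives the default
nu = 10 cm^2 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FluidParams",
    "CellParams",
    "PeriodDataset",
    "TauFit",
    "rb_time_constant",
    "rayleigh_criterion",
    "cell_time_constant",
    "dimension_check",
    "tau_curve",
    "fit_tau",
]

#: dimension vectors as (L, M, T) exponents
DIM_TIME = (0, 0, 1)
DIM_KINEMATIC_VISCOSITY = (2, 0, -1)
DIM_SPECIFIC_ENERGY = (2, 0, -2)  # erg g^-1 = cm^2 s^-2
DIM_DIMENSIONLESS = (0, 0, 0)


@dataclass(frozen=True)
class FluidParams:
    """Fluid-layer parameters (cgs units)."""

    mu: float  # dynamic viscosity, P
    rho: float  # mean density, g cm^-3
    g: float  # gravitational acceleration, cm s^-2
    alpha_T: float  # thermal expansion coefficient, K^-1
    d: float  # layer thickness, cm
    D_T: float  # thermal diffusion coefficient, cm^2 s^-1
    delta_T: float  # temperature difference, K

    def __post_init__(self) -> None:
        for name in ("mu", "rho", "g", "alpha_T", "d", "D_T", "delta_T"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class CellParams:
    """Cellular analog parameters.

    nu : kinematic viscosity, cm^2 s^-1 (default 10, i.e. ~1000x water)
    phi0 : baseline specific energy density Phi0, erg g^-1
    alpha : expansion-coefficient analog, inverse concentration units
        (default 1e-4); alpha * deltaC must be dimensionless
    beta : scaling exponent of Phi with concentration, in [-0.5, 0]
    c_ref : reference concentration anchoring the Phi power law
    """

    nu: float = 10.0
    phi0: float = 250.0
    alpha: float = 1e-4
    beta: float = 0.0
    c_ref: float = 30.0

    def __post_init__(self) -> None:
        for name in ("nu", "phi0", "c_ref"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not (math.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be finite and > 0, got {self.alpha}")
        if not -0.5 <= self.beta <= 0.0:
            raise ValueError(f"beta must lie in [-0.5, 0], got {self.beta}")


@dataclass(frozen=True)
class PeriodDataset:
    """Oscillation period versus concentration gradient.

    Rows of (delta_c, tau seconds, relative uncertainty); delta_c must be
    strictly increasing and everything positive.
    """

    delta_c: np.ndarray
    tau: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        dc = np.asarray(self.delta_c, float)
        tau = np.asarray(self.tau, float)
        sig = np.asarray(self.sigma, float)
        if not (dc.shape == tau.shape == sig.shape) or dc.ndim != 1:
            raise ValueError("delta_c, tau, sigma must be 1-d and equal length")
        if not np.all(dc > 0) or not np.all(tau > 0):
            raise ValueError("delta_c and tau must be strictly positive")
        if not np.all(np.diff(dc) > 0):
            raise ValueError("delta_c must be strictly increasing")
        object.__setattr__(self, "delta_c", dc)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "sigma", sig)

    def __len__(self) -> int:
        return len(self.delta_c)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_c": self.delta_c, "tau_seconds": self.tau, "sigma_rel": self.sigma}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PeriodDataset":
        return cls(
            delta_c=df["delta_c"].to_numpy(float),
            tau=df["tau_seconds"].to_numpy(float),
            sigma=df["sigma_rel"].to_numpy(float),
        )


def rb_time_constant(p: FluidParams) -> float:
    """Characteristic displacement time of the fluid layer.

    tau_RB = mu / (rho g alpha_T d deltaT), seconds.
    """
    return p.mu / (p.rho * p.g * p.alpha_T * p.d * p.delta_T)


def rayleigh_criterion(p: FluidParams, R_RB: float) -> tuple[float, bool]:
    """Rayleigh number and the sustained-convection flag.

    R = rho g alpha_T d^3 deltaT / (mu D_T); convection is sustained
    when R >= R_RB (the critical Rayleigh number).
    """
    if not (math.isfinite(R_RB) and R_RB > 0):
        raise ValueError(f"R_RB must be finite and > 0, got {R_RB}")
    R = p.rho * p.g * p.alpha_T * p.d**3 * p.delta_T / (p.mu * p.D_T)
    return R, R >= R_RB


def _phi(p: CellParams, delta_c) -> np.ndarray:
    return p.phi0 * (np.asarray(delta_c, float) / p.c_ref) ** p.beta


def cell_time_constant(p: CellParams, delta_c) -> float | np.ndarray:
    """Cellular oscillation time tau = nu / (Phi(deltaC) alpha deltaC).

    With beta = 0 this is the bare analog formula; otherwise Phi follows
    the power law anchored at c_ref.  Accepts a scalar or array delta_c.
    """
    dc = np.asarray(delta_c, float)
    if not np.all(np.isfinite(dc)) or np.any(dc <= 0):
        raise ValueError("delta_c must be finite and > 0")
    tau = p.nu / (_phi(p, dc) * p.alpha * dc)
    if np.ndim(delta_c) == 0:
        return float(tau)
    return tau


def dimension_check(
    nu_dim: tuple[int, int, int] = DIM_KINEMATIC_VISCOSITY,
    phi_dim: tuple[int, int, int] = DIM_SPECIFIC_ENERGY,
    alpha_dc_dim: tuple[int, int, int] = DIM_DIMENSIONLESS,
) -> bool:
    """Check that nu / (Phi * alpha * deltaC) carries dimensions of time.

    Dimensions are (L, M, T) exponent triples.  With the defaults —
    kinematic viscosity L^2 T^-1, Phi a specific energy density L^2 T^-2,
    alpha*deltaC dimensionless — the quotient reduces to T and the check
    passes.  Reading Phi as an energy *rate* density (L^2 T^-3, the
    per-second literature convention) makes the quotient T^2, so the
    check fails: the formula needs the time-integrated quantity.
    """
    result = tuple(
        n - (p + a) for n, p, a in zip(nu_dim, phi_dim, alpha_dc_dim)
    )
    return result == DIM_TIME


def tau_curve(p: CellParams, delta_c_grid) -> pd.DataFrame:
    """Oscillation time over a concentration grid (columns delta_c, tau).

    The grid must be positive and strictly increasing; the output is then
    strictly decreasing in delta_c for every admissible beta.
    """
    grid = np.asarray(list(delta_c_grid), float)
    if grid.size == 0 or np.any(grid <= 0) or not np.all(np.isfinite(grid)):
        raise ValueError("delta_c grid must be non-empty, finite and positive")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("delta_c grid must be strictly increasing")
    tau = cell_time_constant(p, grid)
    return pd.DataFrame({"delta_c": grid, "tau": np.atleast_1d(tau)})


@dataclass(frozen=True)
class TauFit:
    """Result of fitting the power-law time-constant model."""

    phi0: float
    beta: float
    residuals: np.ndarray  # per-row residuals of log tau
    beta_clamped: bool


def fit_tau(
    data: PeriodDataset,
    alpha_fixed: float = 1e-4,
    nu_fixed: float = 10.0,
    c_ref: float = 30.0,
) -> TauFit:
    """Weighted least-squares fit of (Phi0, beta) in log space.

    The model is linear in log space,

        log tau = log(nu / (Phi0 alpha)) + beta log c_ref
                  - (1 + beta) log deltaC,

    with weights 1/sigma^2 (sigma is the relative error, i.e. the
    standard deviation of log tau).  alpha and nu are held fixed: only
    the product nu/(Phi0 alpha) is identifiable from the intercept.
    beta is clamped to [-0.5, 0]; when the clamp is active the intercept
    is re-estimated at the boundary slope and the fit is flagged.
    """
    if len(data) < 3:
        raise ValueError("fit_tau requires at least 3 rows")
    L = np.log(data.delta_c)
    if np.ptp(L) == 0:
        raise ValueError("delta_c has zero variance")
    y = np.log(data.tau)
    sig = np.where(data.sigma > 0, data.sigma, 1.0)
    w = 1.0 / sig**2
    # weighted linear regression y = a0 + a1 L
    W = np.sum(w)
    Lbar = np.sum(w * L) / W
    ybar = np.sum(w * y) / W
    a1 = np.sum(w * (L - Lbar) * (y - ybar)) / np.sum(w * (L - Lbar) ** 2)
    beta = -1.0 - a1
    clamped = not (-0.5 <= beta <= 0.0)
    beta = float(np.clip(beta, -0.5, 0.0))
    # intercept at the (possibly clamped) slope
    a0 = np.sum(w * (y + (1.0 + beta) * L)) / W
    # a0 = log(nu/(Phi0 alpha)) + beta log c_ref
    log_phi0 = math.log(nu_fixed) - math.log(alpha_fixed) + beta * math.log(c_ref) - a0
    phi0 = math.exp(log_phi0)
    model = a0 - (1.0 + beta) * L
    return TauFit(phi0=phi0, beta=beta, residuals=y - model, beta_clamped=clamped)
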