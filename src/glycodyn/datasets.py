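"""Seeded synthetic period-versus-concentration tables.

Emulates dose-response tables of glycolytic oscillation period against
injected sugar concentration in yeast extract (periods of order minutes,
falling as the dose rises, with ~10% relative error bars).  The noise
model is multiplicative log-normal: tau_i = curve(dC_i) * exp(eps_i)
with eps_i ~ N(0, noise_rel), matching relative error bars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .convection import CellParams, PeriodDataset, cell_time_constant

__all__ = ["SyntheticSpec", "generate_period_data"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings for a synthetic period table.

    Defaults: nu = 10 cm^2 s^-1 (cytoplasm ~1000x water), Phi0 = 250
    erg g^-1 (single-cell scale), alpha = 1e-4, beta = -0.25 (middle of
    the admissible specific-metabolic-rate scaling range), 20 log-spaced
    doses spanning 5-200 concentration units, 10% relative noise.
    """

    nu: float = 10.0
    phi0: float = 250.0
    alpha: float = 1e-4
    beta: float = -0.25
    c_ref: float = 30.0
    c_min: float = 5.0
    c_max: float = 200.0
    n: int = 20
    spacing: str = "log"
    noise_rel: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.c_min < self.c_max):
            raise ValueError("require 0 < c_min < c_max")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.spacing not in ("linear", "log"):
            raise ValueError(f"spacing must be 'linear' or 'log', got {self.spacing!r}")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")

    @property
    def cell_params(self) -> CellParams:
        return CellParams(
            nu=self.nu, phi0=self.phi0, alpha=self.alpha, beta=self.beta,
            c_ref=self.c_ref,
        )

    def grid(self) -> np.ndarray:
        if self.spacing == "linear":
            return np.linspace(self.c_min, self.c_max, self.n)
        return np.geomspace(self.c_min, self.c_max, self.n)


def generate_period_data(spec: SyntheticSpec) -> PeriodDataset:
    """Draw a seeded synthetic period table from the time-constant model.

    Identical spec (including seed) yields an identical dataset.
    """
    dc = spec.grid()
    truth = np.atleast_1d(cell_time_constant(spec.cell_params, dc))
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.noise_rel, size=dc.shape) if spec.noise_rel > 0 else 0.0
    tau = truth * np.exp(eps)
    sigma = np.full(dc.shape, spec.noise_rel)
    return PeriodDataset(delta_c=dc, tau=tau, sigma=sigma)
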