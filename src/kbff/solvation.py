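"""Thermodynamic-integration bookkeeping and solvation free-energy corrections.

A two-stage alchemical protocol (Lennard-Jones growth, then charging)
yields a raw simulated free energy F_sim from the quadrature of
<dH/dlambda> over the coupling parameter.  Two analytic corrections turn
it into a solvation free energy comparable to experiment:

* the periodic-boundary correction for a charged solute under Ewald
  summation with a neutralizing background,

      dF_corr = k_e q^2 [ -xi / (2 eps L)  +  pi r^2 (1 - 1/eps) / (3 L^3) ],

  with xi the cubic-lattice Wigner constant, eps the water-model
  dielectric constant, L the cubic box length and r = 2^(1/6) sigma the
  ion's Lennard-Jones radius (the first term removes the screened
  interaction of the ion with its periodic images, the second the
  effect of the homogeneous background charge over the ion volume); and

* the standard-state term F_p = kT ln(p1/p0) for transferring an ideal
  gas at p0 = 1 atm into a 1 mol/l ideal solution, with p1 = kT n.

The total is F = F_sim + dF_corr + F_p.  Salt (pair) free energies are
sums of the cation and anion single-ion totals, so only pair values are
ever compared with experiment and no extra-thermodynamic single-ion
split is introduced.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from . import constants
from .ewald import LatticeSumSpec, wigner_constant

__all__ = [
    "TIRecord",
    "SolvationResult",
    "ti_integrate",
    "finite_size_correction",
    "pressure_correction",
    "solvation_free_energy",
]


@dataclass
class TIRecord:
    """lambda-grid of <dH/dlambda> means and errors for one TI stage."""

    lambdas: np.ndarray
    dHdl_means: np.ndarray  # kJ/mol
    dHdl_errors: np.ndarray  # kJ/mol
    stage: str = "charging"  # or "lj-growth"

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.dHdl_means = np.asarray(self.dHdl_means, dtype=float)
        self.dHdl_errors = np.asarray(self.dHdl_errors, dtype=float)
        lam = self.lambdas
        if lam.ndim != 1 or len(lam) != len(self.dHdl_means) or \
                len(lam) != len(self.dHdl_errors):
            raise ValueError("lambda grid and value arrays must align")
        if np.any((lam < 0) | (lam > 1)):
            raise ValueError("lambda values must lie in [0, 1]")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("lambda values must be sorted and unique")
        if np.any(self.dHdl_errors < 0):
            raise ValueError("dH/dlambda errors must be non-negative")

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "lambda": self.lambdas,
            "dHdl_mean": self.dHdl_means,
            "dHdl_err": self.dHdl_errors,
            "stage": self.stage,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> list["TIRecord"]:
        df = pd.read_csv(path)
        required = {"lambda", "dHdl_mean", "dHdl_err", "stage"}
        if required - set(df.columns):
            raise ValueError(
                f"{path}: missing columns {sorted(required - set(df.columns))}"
            )
        return [
            cls(g["lambda"].to_numpy(), g["dHdl_mean"].to_numpy(),
                g["dHdl_err"].to_numpy(), stage=str(stage))
            for stage, g in df.groupby("stage", sort=False)
        ]


@dataclass
class SolvationResult:
    """Assembled solvation free energy, F_total = F_sim + F_corr + F_p."""

    F_sim: float
    F_corr: float
    F_p: float
    box_length: float = float("nan")
    dielectric_used: float = float("nan")
    ion_sigma: float = float("nan")

    @property
    def F_total(self) -> float:
        return self.F_sim + self.F_corr + self.F_p


def ti_integrate(record: TIRecord, scheme: str = "trapezoid",
                 ) -> tuple[float, float]:
    """Integrate <dH/dlambda> over [0, 1]; returns (free energy, error).

    Trapezoid (default, exact for linear integrands on any grid) or
    natural cubic spline.  The error is propagated from the per-lambda
    standard errors assuming independence between lambda states; for
    the spline scheme the trapezoid weights are used as a conservative
    proxy for the (nearly identical) spline quadrature weights.
    """
    lam = record.lambdas
    if len(lam) < 2:
        raise ValueError("need at least two lambda points")
    y = record.dHdl_means
    if scheme == "trapezoid":
        value = float(np.trapezoid(y, lam))
    elif scheme == "cubic-spline":
        value = float(CubicSpline(lam, y).integrate(lam[0], lam[-1]))
    else:
        raise ValueError(f"unknown quadrature scheme {scheme!r}")
    # trapezoid weights
    w = np.zeros_like(lam)
    w[1:] += 0.5 * np.diff(lam)
    w[:-1] += 0.5 * np.diff(lam)
    error = float(np.sqrt(np.sum((w * record.dHdl_errors) ** 2)))
    return value, error


@lru_cache(maxsize=8)
def _xi(tol: float = 1e-6) -> float:
    return wigner_constant(LatticeSumSpec(tol=tol))


def finite_size_correction(q: float, dielectric: float, L: float,
                           sigma_ion: float) -> float:
    """Periodic-boundary/background correction for a solvated ion, kJ/mol.

    Quadratic in the ion charge, vanishing for large boxes.  The ion
    radius enters as r = 2^(1/6) sigma.
    """
    if L <= 0:
        raise ValueError(f"box length must be > 0, got {L}")
    if dielectric < 1:
        raise ValueError(
            f"dielectric constant must be >= 1, got {dielectric}"
        )
    if sigma_ion <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma_ion}")
    r = 2.0 ** (1.0 / 6.0) * sigma_ion
    image_term = -_xi() / (2.0 * dielectric * L)
    background_term = (np.pi * r**2 / (3.0 * L**3)) * (1.0 - 1.0 / dielectric)
    return constants.KE * q**2 * (image_term + background_term)


def pressure_correction(temperature: float, target_concentration: float = 1.0,
                        p0_atm: float = 1.0) -> float:
    """Standard-state term kT ln(p1/p0) with p1 = kT n, in kJ/mol.

    ``target_concentration`` in mol/L (1 mol/l ideal solution by
    default), ``p0_atm`` in atmospheres (ideal gas at 1 atm).
    """
    if target_concentration <= 0:
        raise ValueError("concentration must be positive")
    if p0_atm <= 0:
        raise ValueError("reference pressure must be positive")
    kT = constants.thermal_energy(temperature)
    n = constants.concentration_to_density(target_concentration)  # nm^-3
    p1 = kT * n  # kJ mol^-1 nm^-3
    p0 = p0_atm * constants.ATM
    return kT * float(np.log(p1 / p0))


def solvation_free_energy(F_sim: float, corr: float, F_p: float,
                          box_length: float = float("nan"),
                          dielectric: float = float("nan"),
                          ion_sigma: float = float("nan")) -> SolvationResult:
    """Assemble the corrected solvation free energy."""
    return SolvationResult(F_sim=F_sim, F_corr=corr, F_p=F_p,
                           box_length=box_length, dielectric_used=dielectric,
                           ion_sigma=ion_sigma)
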