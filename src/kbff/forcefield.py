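"""Force-field data model.

Per-species Lennard-Jones parameters and charges, Lorentz-Berthelot
mixing, the cutoff-shifted Lennard-Jones potential and its soft-core
variant used for alchemical decoupling.

The optimized alkali-halide ion parameters ship with the package as
``data/table1_ions.csv`` (sigma in nm, epsilon in kJ/mol, charge in e,
mass in u) and are accessible through :func:`table1_ions`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesParams",
    "PairParams",
    "ForceField",
    "combine_lorentz_berthelot",
    "lj_potential_shifted",
    "softcore_potential",
    "load_forcefield",
    "table1_ions",
]

#: Default Lennard-Jones cutoff in nm; the potential is shifted to zero
#: there and no long-range dispersion correction is applied.
DEFAULT_CUTOFF = 0.9


@dataclass(frozen=True)
class SpeciesParams:
    """Lennard-Jones parameters and charge of one species."""

    name: str
    sigma: float  # nm
    epsilon: float  # kJ/mol
    charge: float = 0.0  # e
    mass: float = 0.0  # u

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"{self.name}: sigma must be > 0, got {self.sigma}")
        if self.epsilon < 0:
            raise ValueError(
                f"{self.name}: epsilon must be >= 0, got {self.epsilon}"
            )


@dataclass(frozen=True)
class PairParams:
    """Mixed pair interaction: LJ parameters, cutoff and shift.

    ``shift`` equals the unshifted LJ value at the cutoff, so that the
    shifted potential is exactly zero there.
    """

    sigma: float  # nm
    epsilon: float  # kJ/mol
    cutoff: float = DEFAULT_CUTOFF  # nm
    charge_product: float = 0.0  # e^2

    @property
    def shift(self) -> float:
        return _lj(self.cutoff, self.sigma, self.epsilon)


def _lj(r, sigma, epsilon):
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6**2 - sr6)


def combine_lorentz_berthelot(
    i: SpeciesParams, j: SpeciesParams, cutoff: float = DEFAULT_CUTOFF
) -> PairParams:
    """Lorentz-Berthelot mixing: arithmetic-mean sigma, geometric-mean epsilon."""
    return PairParams(
        sigma=0.5 * (i.sigma + j.sigma),
        epsilon=float(np.sqrt(i.epsilon * j.epsilon)),
        cutoff=cutoff,
        charge_product=i.charge * j.charge,
    )


def lj_potential_shifted(r, pair: PairParams):
    """Cutoff-shifted Lennard-Jones potential in kJ/mol.

    4 eps [(sigma/r)^12 - (sigma/r)^6] - shift inside the cutoff, zero
    outside; continuous at the cutoff by construction.  Accepts scalars
    or arrays for ``r``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    inside = r <= pair.cutoff
    out = np.where(inside, _lj(np.where(inside, r, pair.cutoff), pair.sigma,
                               pair.epsilon) - pair.shift, 0.0)
    return out if out.ndim else float(out)


def softcore_potential(r, lam: float, pair: PairParams,
                       alpha: float = 0.5, p: float = 1.0):
    """Soft-core Lennard-Jones interaction for alchemical growth.

    Uses the standard lambda-dependent radial remapping

        r_sc(r) = (alpha * sigma^6 * (1 - lam)^p + r^6)^(1/6),

    applied to the cutoff-shifted LJ potential and scaled by lam, so that
    the interaction is zero at lam = 0, equals the plain shifted LJ at
    lam = 1, and stays finite at r = 0 for lam < 1.  ``alpha`` is the
    soft-core parameter (0.5 by convention) and ``p`` the soft-core power.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    if lam == 0.0:
        out = np.zeros_like(r)
        return out if out.ndim else 0.0
    r_sc = (alpha * pair.sigma**6 * (1.0 - lam) ** p + r**6) ** (1.0 / 6.0)
    out = lam * np.asarray(lj_potential_shifted(r_sc, pair))
    return out if out.ndim else float(out)


class ForceField:
    """A named collection of :class:`SpeciesParams` with mixing."""

    def __init__(self, species: dict[str, SpeciesParams] | list[SpeciesParams],
                 cutoff: float = DEFAULT_CUTOFF):
        if not isinstance(species, dict):
            species = {s.name: s for s in species}
        self.species = dict(species)
        self.cutoff = cutoff

    def __getitem__(self, name: str) -> SpeciesParams:
        try:
            return self.species[name]
        except KeyError:
            raise KeyError(
                f"unknown species {name!r}; known: {sorted(self.species)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.species

    def pair(self, a: str, b: str) -> PairParams:
        return combine_lorentz_berthelot(self[a], self[b], cutoff=self.cutoff)

    def replace(self, params: SpeciesParams) -> "ForceField":
        """Return a copy with one species' parameters replaced."""
        new = dict(self.species)
        new[params.name] = params
        return ForceField(new, cutoff=self.cutoff)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": s.name, "sigma_nm": s.sigma, "epsilon_kjmol": s.epsilon,
             "charge_e": s.charge, "mass_u": s.mass}
            for s in self.species.values()
        ]
        return pd.DataFrame(rows)


def load_forcefield(path, cutoff: float = DEFAULT_CUTOFF) -> ForceField:
    """Read a force field from a CSV table.

    Required header: ``species, sigma_nm, epsilon_kjmol, charge_e, mass_u``.
    """
    df = pd.read_csv(path)
    required = {"species", "sigma_nm", "epsilon_kjmol", "charge_e", "mass_u"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    species = [
        SpeciesParams(
            name=str(row.species),
            sigma=float(row.sigma_nm),
            epsilon=float(row.epsilon_kjmol),
            charge=float(row.charge_e),
            mass=float(row.mass_u),
        )
        for row in df.itertuples()
    ]
    return ForceField(species, cutoff=cutoff)


def table1_ions() -> ForceField:
    """The optimized K+/Na+/Cl-/Br- ion parameter set bundled with kbff."""
    with resources.as_file(
        resources.files("kbff").joinpath("data/table1_ions.csv")
    ) as p:
        return load_forcefield(Path(p))
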