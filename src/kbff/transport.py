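"""Self-diffusion and ionic conductivity.

Self-diffusion constants come from a linear fit to the long-time
mean-squared displacement, MSD(tau) = 6 D tau + c, where the offset c
absorbs short-time non-diffusive behaviour.  Periodic-box hydrodynamic
self-interaction depresses the simulated value; the Yeh-Hummer
correction restores the infinite-system value,

    D_self = D_sim - kT xi / (6 pi eta L),

with the (negative) cubic-lattice constant xi, the water-model shear
viscosity eta and the box length L, so the correction is positive and
scales as T/(eta L).  The Einstein-Smoluchowski relation then gives the
conductivity of a monovalent salt,

    kappa = n e^2 (D+ + D-) / (kB T),

reported in S/m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from . import constants
from .ewald import LatticeSumSpec, wigner_constant
from .trajectory import Trajectory

__all__ = [
    "MSDCurve",
    "DiffusionResult",
    "mean_squared_displacement",
    "fit_self_diffusion",
    "finite_size_diffusion_correction",
    "conductivity",
    "viscosity_from_mpas",
]


@dataclass
class MSDCurve:
    """Mean-squared displacement vs lag time for one species."""

    lag_times: np.ndarray  # ps
    msd: np.ndarray  # nm^2
    species: str
    n_particles: int


@dataclass
class DiffusionResult:
    """Fitted and finite-size-corrected self-diffusion, nm^2/ps."""

    D_sim: float
    c_offset: float  # nm^2, short-time intercept
    fit_window: tuple[float, float]  # ps
    r_squared: float
    curvature: float = 0.0  # relative slope change across the window
    D_sim_stderr: float = float("nan")
    D_self: float = float("nan")
    eta_used: float = float("nan")  # kJ mol^-1 ps nm^-3
    L_used: float = float("nan")  # nm

    @property
    def linear_ok(self) -> bool:
        """Diagnostic: the MSD was acceptably linear over the fit window.

        R^2 alone barely distinguishes a quadratic from a line over a
        finite window, so the relative slope change between the two
        window halves is checked as well.
        """
        return bool(self.r_squared >= 0.9 and abs(self.curvature) <= 0.5)


def viscosity_from_mpas(eta_mpas: float) -> float:
    """Convert a shear viscosity from mPa s to kJ mol^-1 ps nm^-3."""
    # 1 Pa s = 1 J s / m^3 = (N_A/1000) kJ/mol * 1e12 ps / 1e27 nm^3
    return eta_mpas * 1e-3 * constants.N_AVOGADRO / 1000.0 * 1e12 / 1e27


def _detect_wrapped(pos: np.ndarray, L: float) -> bool:
    d = np.abs(np.diff(pos, axis=0))
    return bool(np.any(d > 0.5 * L))


def mean_squared_displacement(traj: Trajectory, species: str,
                              max_lag: float | None = None,
                              n_lags: int = 100) -> MSDCurve:
    """MSD averaged over all time origins and all particles of a species.

    Requires unwrapped coordinates (a frame-to-frame jump above L/2 is
    taken as evidence of wrapping and raises).  ``max_lag`` defaults to
    half the trajectory length; lags are an evenly spaced integer subset
    of the available multiples of dt, at most ``n_lags`` of them, always
    including lag zero.
    """
    idx = traj.select(species)
    if len(idx) == 0:
        raise ValueError(f"no particles of species {species!r}")
    pos = traj.positions[:, idx, :]
    if _detect_wrapped(pos, traj.box_length):
        raise ValueError(
            "trajectory appears to be wrapped (jump > L/2 between frames); "
            "apply kbff.trajectory.unwrap first"
        )
    n_frames = traj.n_frames
    if max_lag is None:
        max_lag = 0.5 * (n_frames - 1) * traj.dt
    max_steps = int(round(max_lag / traj.dt))
    if max_steps < 1 or max_steps > n_frames - 1:
        raise ValueError(
            f"max_lag={max_lag} ps outside the usable range "
            f"(dt..{(n_frames - 1) * traj.dt} ps)"
        )
    lags = np.unique(np.linspace(0, max_steps, min(n_lags, max_steps) + 1,
                                 dtype=int))
    msd = np.empty(len(lags))
    for k, lag in enumerate(lags):
        if lag == 0:
            msd[k] = 0.0
            continue
        d = pos[lag:] - pos[:-lag]
        msd[k] = np.mean(np.sum(d * d, axis=-1))
    return MSDCurve(lag_times=lags * traj.dt, msd=msd, species=species,
                    n_particles=len(idx))


def fit_self_diffusion(msd: MSDCurve,
                       window: tuple[float, float] | None = None,
                       ) -> DiffusionResult:
    """Least-squares line MSD = 6 D tau + c over a lag window.

    The default window covers lags in [10%, 50%] of the longest
    available lag — the long-time diffusive regime for the fixtures
    this package generates; the window actually used is recorded in the
    result.  A low R^2 (``linear_ok`` False) flags non-diffusive input.
    """
    t_max = float(msd.lag_times.max())
    if window is None:
        window = (0.1 * t_max, 0.5 * t_max)
    lo, hi = window
    sel = (msd.lag_times >= lo) & (msd.lag_times <= hi)
    if np.sum(sel) < 3:
        raise ValueError(
            f"fewer than 3 MSD lags inside fit window {window} ps"
        )
    x, y = msd.lag_times[sel], msd.msd[sel]
    fit = sp_stats.linregress(x, y)
    r2 = float(fit.rvalue**2) if np.std(y) > 0 else 1.0
    mid = 0.5 * (x[0] + x[-1])
    left, right = x <= mid, x >= mid
    curvature = 0.0
    if np.sum(left) >= 2 and np.sum(right) >= 2 and fit.slope != 0:
        s1 = sp_stats.linregress(x[left], y[left]).slope
        s2 = sp_stats.linregress(x[right], y[right]).slope
        curvature = float((s2 - s1) / fit.slope)
    return DiffusionResult(
        D_sim=float(fit.slope / 6.0),
        c_offset=float(fit.intercept),
        fit_window=(float(lo), float(hi)),
        r_squared=r2,
        curvature=curvature,
        D_sim_stderr=float(fit.stderr / 6.0),
    )


def finite_size_diffusion_correction(result: DiffusionResult | float,
                                     temperature: float, eta: float,
                                     L: float) -> DiffusionResult:
    """Apply the Yeh-Hummer periodic-box correction.

    ``eta`` is the water-model shear viscosity in kJ mol^-1 ps nm^-3
    (see :func:`viscosity_from_mpas`); it is a required input — no
    bundled default, because it is a property of the water model.
    """
    if eta is None or not np.isfinite(eta) or eta <= 0:
        raise ValueError(
            "a positive water-model viscosity is required (no default); "
            "convert from mPa s with viscosity_from_mpas"
        )
    if L <= 0:
        raise ValueError(f"box length must be > 0, got {L}")
    if isinstance(result, (int, float)):
        result = DiffusionResult(D_sim=float(result), c_offset=float("nan"),
                                 fit_window=(float("nan"), float("nan")),
                                 r_squared=float("nan"))
    xi = wigner_constant(LatticeSumSpec())
    kT = constants.thermal_energy(temperature)
    correction = -kT * xi / (6.0 * np.pi * eta * L)
    return DiffusionResult(
        D_sim=result.D_sim, c_offset=result.c_offset,
        fit_window=result.fit_window, r_squared=result.r_squared,
        D_sim_stderr=result.D_sim_stderr,
        D_self=result.D_sim + correction, eta_used=eta, L_used=L,
    )


def conductivity(n: float, d_plus: float, d_minus: float,
                 temperature: float) -> float:
    """Einstein-Smoluchowski conductivity of a monovalent salt, S/m.

    ``n`` is the salt number density in nm^-3 (cation density = anion
    density), diffusivities in nm^2/ps.
    """
    if n < 0 or d_plus < 0 or d_minus < 0:
        raise ValueError("density and diffusivities must be non-negative")
    n_si = n * 1e27  # m^-3
    d_si = (d_plus + d_minus) * 1e-6  # m^2/s
    kt_joule = constants.KB * temperature * 1000.0 / constants.N_AVOGADRO
    return n_si * constants.E_CHARGE**2 * d_si / kt_joule
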