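"""Static dielectric constant of salt solutions from fluctuations.

For a conducting medium the total electric susceptibility splits into
three additive contributions — water-dipole, water-dipole/ion-current
cross, and ion-current — estimated from equilibrium time-correlation
functions of the collective water dipole moment M(t) (e nm) and the ion
current J(t) (e nm/ps):

    chi_ww = <dM^2> / (3 eps0 V kT)
    chi_wi = -2/(3 eps0 V kT) * int_0^inf <dM(0).J(t)> dt
    chi_ii = -1/(3 eps0 V kT) * int_0^inf t <J(0).J(t)> dt

The static dielectric constant is eps = 1 + chi_ww + chi_wi + chi_ii
(the zero-frequency limit taken analytically: for any stationary
process with decaying correlations the two time integrals equal the
static cross-covariance <dM.dM_I> (twice) and the ion-dipole variance
<dM_I^2>, where M_I is the itinerant ion dipole whose derivative is J).
The dielectric decrement is the difference to the pure-water value of
the same water model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate

from . import constants
from .stats import block_means
from .trajectory import ScalarSeries

__all__ = [
    "SusceptibilityResult",
    "susceptibility_components",
    "dielectric_decrement",
]


@dataclass
class SusceptibilityResult:
    """Three-term susceptibility decomposition and the resulting epsilon."""

    chi_ww: float
    chi_wi: float
    chi_ii: float
    volume: float  # nm^3
    temperature: float  # K

    @property
    def epsilon_total(self) -> float:
        return 1.0 + self.chi_ww + self.chi_wi + self.chi_ii


def _as_vectors(series: ScalarSeries, name: str) -> np.ndarray:
    v = np.atleast_2d(series.values.T).T
    if v.shape[1] not in (1, 3):
        raise ValueError(f"{name}: expected scalar or 3-vector series")
    return v


def _correlation_dot(x: np.ndarray, y: np.ndarray, max_steps: int) -> np.ndarray:
    """c[k] = mean over origins t of x(t) . y(t+k), for k = 0..max_steps.

    FFT-based with explicit zero padding; each lag is normalized by its
    own origin count (unbiased in the origin average).
    """
    n = x.shape[0]
    out = np.zeros(max_steps + 1)
    counts = n - np.arange(max_steps + 1)
    for comp in range(x.shape[1]):
        full = correlate(y[:, comp], x[:, comp], mode="full", method="fft")
        # index n-1+k holds sum_t x(t) y(t+k)
        out += full[n - 1: n + max_steps]
    return out / counts


def susceptibility_components(M: ScalarSeries, J: ScalarSeries,
                              volume: float, temperature: float,
                              max_lag: float | None = None,
                              drift_check: bool = True,
                              ) -> SusceptibilityResult:
    """Estimate the three zero-frequency susceptibility contributions.

    ``M`` and ``J`` must be aligned, equally spaced series of the same
    length; the correlation integrals are truncated at ``max_lag``
    (default: a twentieth of the series length).  Choose ``max_lag`` a
    few tens of correlation times: long enough that the correlations
    have decayed, short enough that the t-weighted ion-current integral
    is not dominated by large-lag noise.  A drifting M series (block
    means moving by more than 5 standard errors between the early and
    late blocks) triggers a non-stationarity warning.
    """
    if len(M) != len(J):
        raise ValueError(
            f"series length mismatch: M has {len(M)}, J has {len(J)}"
        )
    if abs(M.dt - J.dt) > 1e-12:
        raise ValueError("M and J must share the same time step")
    if volume <= 0:
        raise ValueError("volume must be positive")
    m = _as_vectors(M, "M")
    j = _as_vectors(J, "J")
    n = m.shape[0]
    dt = M.dt
    if max_lag is None:
        max_lag = 0.05 * (n - 1) * dt
    max_steps = int(round(max_lag / dt))
    if not 1 <= max_steps <= n - 1:
        raise ValueError(f"max_lag={max_lag} ps outside usable range")

    if drift_check:
        # a pure trend inflates the raw block SE itself, so measure the
        # drift against the block means detrended by their linear fit
        mags = np.sqrt(np.sum(m * m, axis=1))
        bm = block_means(mags, 5)
        idx = np.arange(5.0)
        slope, intercept = np.polyfit(idx, bm, 1)
        resid = bm - (slope * idx + intercept)
        se = np.std(resid, ddof=2) / np.sqrt(5)
        drift = abs(slope) * 4.0
        if drift > 5.0 * max(se, 1e-12 * (abs(bm).mean() + 1e-300)):
            warnings.warn(
                "dipole series looks non-stationary (fitted block-mean "
                f"drift {drift:.3g} > 5 x detrended SE {se:.3g}); trim "
                "transients", stacklevel=2,
            )

    kT = constants.thermal_energy(temperature)
    norm = 1.0 / (3.0 * constants.EPS0 * volume * kT)

    dm = m - m.mean(axis=0)
    chi_ww = norm * float(np.sum(dm.var(axis=0)))

    lags = dt * np.arange(max_steps + 1)
    if np.any(j):
        c_mj = _correlation_dot(dm, j, max_steps)
        chi_wi = -2.0 * norm * float(np.trapezoid(c_mj, lags))
        c_jj = _correlation_dot(j, j, max_steps)
        chi_ii = -norm * float(np.trapezoid(lags * c_jj, lags))
    else:
        chi_wi = 0.0
        chi_ii = 0.0
    return SusceptibilityResult(chi_ww=chi_ww, chi_wi=chi_wi, chi_ii=chi_ii,
                                volume=volume, temperature=temperature)


def dielectric_decrement(epsilon_solution: float, epsilon_pure: float) -> float:
    """Dielectric decrement: eps(solution) - eps(pure water).

    ``epsilon_pure`` is a property of the water model and must be
    supplied by the caller (72.0 for extended simple point charge
    water is the common example value).
    """
    if epsilon_solution < 1 or epsilon_pure < 1:
        raise ValueError("dielectric constants must be >= 1")
    return epsilon_solution - epsilon_pure
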