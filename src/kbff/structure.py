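"""Pair correlation functions and finite-volume Kirkwood-Buff integrals.

The route from structure to thermodynamics: minimum-image radial
distribution functions g_ab(r), finite-volume KB integrals G^R over
spherical subvolumes of radius R, and the linear extrapolation of G^R
versus 1/R to the thermodynamic limit G^inf.

The finite-volume integral uses the spherical-subvolume geometric weight

    G^R = 4 pi  int_0^{2R}  h(r) r^2 [1 - 3x/2 + x^3/2] dr,   x = r/(2R),

with h(r) = g(r) - 1, which converges to the plain KB integral as
R -> inf for short-ranged h and approaches it linearly in 1/R, the
property the extrapolation relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .trajectory import Trajectory, minimum_image_displacement

__all__ = [
    "RDFTable",
    "KBResult",
    "radial_distribution",
    "kb_integral_finite",
    "kb_curve",
    "kb_extrapolate",
    "density_from_kb",
]

#: Default histogram bin width in nm.
DEFAULT_BIN_WIDTH = 0.002


@dataclass
class RDFTable:
    """Binned pair correlation function for one species pair.

    Bins are uniform and half-open [lo, hi); ``g`` is the ideal-gas
    normalized histogram, ``counts`` the raw pair counts.
    """

    pair: tuple[str, str]
    bin_edges: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    n_frames: int

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def r_max(self) -> float:
        return float(self.bin_edges[-1])


@dataclass
class KBResult:
    """Finite-volume KB integrals and their 1/R -> 0 extrapolation."""

    R_values: np.ndarray  # nm
    G_R: np.ndarray  # nm^3
    G_infinity: float  # nm^3
    fit_slope: float  # nm^4 (coefficient of 1/R)
    fit_window: tuple[float, float]  # interval in 1/R
    stderr: float  # standard error of the intercept, nm^3
    slope_stderr: float = float("nan")
    r_squared: float = float("nan")


def radial_distribution(traj: Trajectory, pair: tuple[str, str],
                        bin_width: float = DEFAULT_BIN_WIDTH,
                        r_max: float | None = None,
                        frames: slice | np.ndarray | None = None) -> RDFTable:
    """Minimum-image RDF histogram, ideal-gas normalized.

    For identical species self-pairs are excluded and each unordered
    pair is counted once.  ``r_max`` defaults to L/2 and may not exceed
    it (minimum-image validity).  ``frames`` optionally restricts the
    estimate to a subset of frames (used for block averaging).
    """
    L = traj.box_length
    if r_max is None:
        r_max = L / 2.0
    if r_max > L / 2.0 + 1e-12:
        raise ValueError(f"r_max={r_max} exceeds L/2={L / 2.0} (minimum image)")
    a, b = pair
    idx_a = traj.select(a)
    idx_b = traj.select(b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(f"no particles of species {a if not len(idx_a) else b}")
    same = a == b
    if same and len(idx_a) < 2:
        raise ValueError(f"need at least two particles of species {a}")

    n_bins = int(np.floor(r_max / bin_width + 1e-9))
    edges = bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)

    positions = traj.positions if frames is None else traj.positions[frames]
    n_frames = positions.shape[0]
    for f in range(n_frames):
        pa = positions[f, idx_a]
        pb = positions[f, idx_b]
        d = minimum_image_displacement(pa[:, None, :] - pb[None, :, :], L)
        r = np.sqrt(np.sum(d * d, axis=-1))
        if same:
            iu = np.triu_indices(len(idx_a), k=1)
            r = r[iu]
        else:
            r = r.ravel()
        r = r[r < edges[-1]]  # ties at exactly r_max excluded
        counts += np.histogram(r, bins=edges)[0]

    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    if same:
        n_pairs = len(idx_a) * (len(idx_a) - 1) / 2.0
    else:
        n_pairs = len(idx_a) * len(idx_b)
    expected = n_frames * n_pairs * shell_vol / traj.volume
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    return RDFTable(pair=(a, b), bin_edges=edges, g=g, counts=counts,
                    n_frames=n_frames)


def _kb_weight(x: np.ndarray) -> np.ndarray:
    return 1.0 - 1.5 * x + 0.5 * x**3


def kb_integral_finite(rdf: RDFTable, R: float) -> float:
    """Finite-volume KB integral G^R (nm^3) over a sphere of radius R.

    Midpoint-rule quadrature of h(r) = g(r) - 1 against the spherical
    geometric weight over r in [0, 2R]; requires the RDF to resolve
    distances up to 2R.
    """
    if 2.0 * R > rdf.r_max + 1e-12:
        raise ValueError(
            f"R={R} needs g(r) up to {2 * R:.3f} nm but the RDF stops at "
            f"{rdf.r_max:.3f} nm"
        )
    r = rdf.r_mid
    mask = r < 2.0 * R
    r = r[mask]
    h = rdf.g[mask] - 1.0
    x = r / (2.0 * R)
    integrand = h * r**2 * _kb_weight(x)
    return float(4.0 * np.pi * np.sum(integrand) * rdf.bin_width)


def kb_curve(rdf: RDFTable, R_values) -> np.ndarray:
    """G^R evaluated on a grid of subvolume radii."""
    return np.array([kb_integral_finite(rdf, R) for R in np.asarray(R_values)])


def kb_extrapolate(R_values, G_R, fit_window: tuple[float, float] | None = None,
                   ) -> KBResult:
    """Extrapolate G^R to infinite subvolume by a linear fit in 1/R.

    Ordinary least squares of G^R against 1/R over ``fit_window`` (an
    interval in 1/R); the intercept is G^inf.  If no window is given,
    the largest window starting from the smallest available 1/R whose
    fit retains R^2 >= 0.99 is used (falling back to the three smallest
    1/R points for very noisy input).
    """
    R_values = np.asarray(R_values, dtype=float)
    G_R = np.asarray(G_R, dtype=float)
    if R_values.shape != G_R.shape:
        raise ValueError("R_values and G_R must have equal shapes")
    inv_r = 1.0 / R_values
    order = np.argsort(inv_r)
    inv_r, g = inv_r[order], G_R[order]

    if fit_window is None:
        lo = inv_r[0]
        best_hi = None
        for k in range(2, len(inv_r)):
            x, y = inv_r[: k + 1], g[: k + 1]
            if np.ptp(x) == 0:
                continue
            r2 = sp_stats.pearsonr(x, y)[0] ** 2 if np.std(y) > 0 else 1.0
            if r2 >= 0.99:
                best_hi = x[-1]
        if best_hi is None:
            if len(inv_r) < 3:
                raise ValueError("need at least 3 points for extrapolation")
            best_hi = inv_r[2]
        fit_window = (lo, best_hi)

    w_lo, w_hi = fit_window
    sel = (inv_r >= w_lo - 1e-12) & (inv_r <= w_hi + 1e-12)
    x, y = inv_r[sel], g[sel]
    if len(x) < 3:
        raise ValueError(
            f"fewer than 3 points inside fit window {fit_window} "
            f"(got {len(x)})"
        )
    if np.ptp(x) == 0:
        raise ValueError("zero variance in 1/R inside the fit window")
    fit = sp_stats.linregress(x, y)
    return KBResult(
        R_values=1.0 / x,
        G_R=y,
        G_infinity=float(fit.intercept),
        fit_slope=float(fit.slope),
        fit_window=(float(w_lo), float(w_hi)),
        stderr=float(fit.intercept_stderr),
        slope_stderr=float(fit.stderr),
        r_squared=float(fit.rvalue**2) if len(x) > 2 else float("nan"),
    )


def density_from_kb(G_plus_minus: float, G_plus_plus: float) -> float:
    """Ion number density from KB integrals, n = 1/(G_+- - G_++).

    Consistency check between composition and structure for a charge
    neutral 1:1 salt.
    """
    diff = G_plus_minus - G_plus_plus
    if diff == 0:
        raise ValueError(
            "G_+- equals G_++; the KB density relation is undefined"
        )
    return 1.0 / diff
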