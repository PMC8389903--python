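"""Salt activity derivatives from Kirkwood-Buff integrals.

For a fully dissociated 1:1 salt at constant temperature and pressure,
Kirkwood-Buff theory gives the logarithmic derivative of the mean salt
activity a with respect to the salt number density n as

    a_cc = d ln a / d ln n = 1 / (1 + n (G_++ + G_+- - 2 G_+s)),

where G_ab are the infinite-volume KB integrals between cation (+),
anion (-) and solvent (s), and the ion-solvent integral is the mean of
the cation-solvent and anion-solvent values.  The expression follows
from the binary-mixture fluctuation result with the salt mapped onto an
indistinguishable ion pair; the solvent-solvent integral drops out at
constant pressure.  a_cc = 1 for an ideal solution, a_cc < 1 when
ion-ion association lowers the activity.  Electroneutrality ties the
density to structure through n = 1/(G_+- - G_++), used as an internal
consistency check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import kb_curve, kb_extrapolate, radial_distribution
from .trajectory import Trajectory

__all__ = [
    "KBSet",
    "ActivityCurve",
    "activity_derivative",
    "activity_curve",
    "load_reference_curve",
]

#: Molality range (mol/kg) of the optimization; points outside trigger
#: a warning when loading reference data.
MOLALITY_RANGE = (0.0, 5.0)


@dataclass
class KBSet:
    """Infinite-volume KB integrals (nm^3) and densities (1/nm^3)."""

    G_pp: float  # cation-cation
    G_pm: float  # cation-anion
    G_ps: float  # cation-solvent
    G_ss: float  # solvent-solvent (informational; drops out at constant p)
    G_ms: float  # anion-solvent
    n_salt: float
    n_solvent: float = float("nan")

    def __post_init__(self):
        vals = [self.G_pp, self.G_pm, self.G_ps, self.G_ss, self.G_ms,
                self.n_salt]
        if not np.all(np.isfinite(np.asarray(vals, dtype=float))):
            raise ValueError("all KB integrals and n_salt must be finite")


@dataclass
class ActivityCurve:
    """a_cc on a molality grid, with per-point errors."""

    molalities: np.ndarray  # mol/kg, strictly increasing
    a_cc: np.ndarray
    errors: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.molalities = np.asarray(self.molalities, dtype=float)
        self.a_cc = np.asarray(self.a_cc, dtype=float)
        if self.molalities.shape != self.a_cc.shape:
            raise ValueError("molalities and a_cc must align")
        if np.any(np.diff(self.molalities) <= 0):
            raise ValueError("molalities must be strictly increasing")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.a_cc.shape:
                raise ValueError("errors must align with a_cc")

    def interpolate(self, molalities) -> np.ndarray:
        """Linear interpolation of the curve onto another molality grid."""
        m = np.asarray(molalities, dtype=float)
        if m.min() < self.molalities.min() - 1e-9 or \
                m.max() > self.molalities.max() + 1e-9:
            raise ValueError(
                "requested molalities extend beyond the reference curve"
            )
        return np.interp(m, self.molalities, self.a_cc)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"molality_molkg": self.molalities,
                           "a_cc": self.a_cc})
        df["error"] = self.errors if self.errors is not None else np.nan
        df.to_csv(path, index=False)


def activity_derivative(kb: KBSet) -> float:
    """Evaluate a_cc from a set of KB integrals (pure function).

    Raises if the KB combination drives the denominator to zero
    (thermodynamically singular composition fluctuations).
    """
    g_is = 0.5 * (kb.G_ps + kb.G_ms)
    denom = 1.0 + kb.n_salt * (kb.G_pp + kb.G_pm - 2.0 * g_is)
    if abs(denom) < 1e-12:
        raise ZeroDivisionError(
            "singular activity derivative: 1 + n (G_++ + G_+- - 2 G_+s) "
            f"= {denom:.3g} vanishes"
        )
    return 1.0 / denom


def _kb_infinity(traj: Trajectory, pair: tuple[str, str], R_values, bin_width,
                 fit_window, frames=None) -> float:
    rdf = radial_distribution(traj, pair, bin_width=bin_width, frames=frames)
    g_r = kb_curve(rdf, R_values)
    return kb_extrapolate(R_values, g_r, fit_window=fit_window).G_infinity


def activity_curve(trajectories: dict[float, Trajectory],
                   cation: str, anion: str, solvent: str,
                   R_values=None, bin_width: float = 0.02,
                   fit_window: tuple[float, float] | None = None,
                   n_blocks: int = 5, label: str = "") -> ActivityCurve:
    """Chain structure -> KB -> a_cc for one trajectory per molality.

    For each molality the five relevant RDFs are estimated, integrated
    over finite subvolumes, extrapolated in 1/R, and combined into
    a_cc.  Errors are the block-averaging standard errors over
    ``n_blocks`` contiguous frame blocks, the convention used for all
    error bars in this package.
    """
    mols = sorted(trajectories)
    values, errors = [], []
    for m in mols:
        traj = trajectories[m]
        if R_values is None:
            r_grid = np.linspace(0.3 * traj.box_length / 2,
                                 0.98 * traj.box_length / 2, 12) / 2.0
        else:
            r_grid = np.asarray(R_values, dtype=float)
        n_salt = traj.number_density(cation)

        def a_cc_for(frames=None, _traj=traj, _n=n_salt, _grid=r_grid):
            try:
                kb = KBSet(
                    G_pp=_kb_infinity(_traj, (cation, cation), _grid,
                                      bin_width, fit_window, frames),
                    G_pm=_kb_infinity(_traj, (cation, anion), _grid,
                                      bin_width, fit_window, frames),
                    G_ps=_kb_infinity(_traj, (cation, solvent), _grid,
                                      bin_width, fit_window, frames),
                    G_ss=_kb_infinity(_traj, (solvent, solvent), _grid,
                                      bin_width, fit_window, frames),
                    G_ms=_kb_infinity(_traj, (anion, solvent), _grid,
                                      bin_width, fit_window, frames),
                    n_salt=_n,
                )
            except (ValueError, ZeroDivisionError) as err:
                raise RuntimeError(
                    f"activity chain failed at molality {m} mol/kg: {err}"
                ) from err
            return activity_derivative(kb)

        values.append(a_cc_for())
        n_f = traj.n_frames
        block_len = n_f // n_blocks
        if block_len >= 1 and n_f >= n_blocks:
            block_vals = [
                a_cc_for(frames=slice(b * block_len, (b + 1) * block_len))
                for b in range(n_blocks)
            ]
            errors.append(float(np.std(block_vals, ddof=1) / np.sqrt(n_blocks)))
        else:
            errors.append(float("nan"))
    return ActivityCurve(np.array(mols), np.array(values), np.array(errors),
                         label=label)


def load_reference_curve(path, label: str = "") -> ActivityCurve:
    """Load an experimental reference curve from CSV.

    Expected header: ``molality_molkg, a_cc[, error]``.  Molalities must
    be strictly increasing; points outside the (0, 5] mol/kg
    optimization range trigger a warning.
    """
    df = pd.read_csv(path)
    required = {"molality_molkg", "a_cc"}
    if required - set(df.columns):
        raise ValueError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    m = df["molality_molkg"].to_numpy(dtype=float)
    if len(np.unique(m)) != len(m):
        raise ValueError(f"{path}: duplicated molality values")
    if np.any(np.diff(m) <= 0):
        raise ValueError(f"{path}: molalities must be strictly increasing")
    if np.any((m <= MOLALITY_RANGE[0]) | (m > MOLALITY_RANGE[1])):
        warnings.warn(
            f"{path}: molalities outside the optimization range "
            f"(0, {MOLALITY_RANGE[1]}] mol/kg", stacklevel=2
        )
    err = df["error"].to_numpy(dtype=float) if "error" in df.columns else None
    return ActivityCurve(m, df["a_cc"].to_numpy(dtype=float), err, label=label)
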