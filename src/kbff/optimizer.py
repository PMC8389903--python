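"""Staged global optimization of ion Lennard-Jones parameters.

The search strategy mirrors the physics of the observables: the salt
solvation free energy pins one combination of (sigma, epsilon) per ion,
so cation parameters are restricted to solvation-free-energy *isolines*
(curves in parameter space reproducing the experimental pair free
energy), and the remaining freedom is resolved by the concentration-
dependent activity derivative a_cc.  Concretely:

1. For each candidate chloride (sigma, epsilon) on a grid, find K+ and
   Na+ isoline candidates for the KCl and NaCl free-energy targets,
   keep the candidate minimizing the chloride-salt activity objective,
   and record the objective k (mean squared deviation of a_cc from the
   reference over salts and molalities).
2. Pick the best chloride; holding the cations fixed, repeat the grid
   search for bromide against the bromide-salt activity curves.

The optimal set therefore depends only on the initial chloride grid.
The objective landscape over (sigma, epsilon) is cubically interpolated
for reporting; following the conservative convention, the best *sampled*
point is selected unless the interpolated improvement exceeds an
explicit noise floor.

The optimizer is agnostic of where observables come from: any backend
with ``pair_free_energy(cation, anion)`` and
``activity_curve(salt, cation, anion, molalities)`` works — the mock
analytic backend for tests, or a file-based provider of precomputed
simulation observables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator
from scipy.optimize import brentq

from .activity import ActivityCurve
from .forcefield import ForceField, SpeciesParams

logger = logging.getLogger(__name__)

__all__ = [
    "ObjectiveSpec",
    "Landscape",
    "objective_k",
    "free_energy_isoline",
    "SaltFamilyOptimizer",
    "OptimizationResults",
]

#: The four salts of the family, as (cation, anion) pairs.
SALTS = {"NaCl": ("Na", "Cl"), "KCl": ("K", "Cl"),
         "NaBr": ("Na", "Br"), "KBr": ("K", "Br")}


def default_molality_grid(spacing: float = 0.25) -> np.ndarray:
    """Molality grid strictly inside the (0, 5) mol/kg optimization range."""
    return np.arange(spacing, 5.0, spacing)


@dataclass
class ObjectiveSpec:
    """What the activity objective averages over.

    ``reference`` maps salt labels to experimental a_cc curves;
    ``molality_grid`` must lie strictly inside (0, 5) mol/kg.
    """

    reference: dict[str, ActivityCurve]
    salts: tuple[str, ...] = ("NaCl", "KCl", "NaBr", "KBr")
    molality_grid: np.ndarray = field(default_factory=default_molality_grid)

    def __post_init__(self):
        self.molality_grid = np.asarray(self.molality_grid, dtype=float)
        if np.any((self.molality_grid <= 0.0) | (self.molality_grid >= 5.0)):
            raise ValueError(
                "molality grid must lie strictly inside (0, 5) mol/kg"
            )
        for salt in self.salts:
            if salt not in SALTS:
                raise ValueError(f"unknown salt {salt!r}")


@dataclass
class Landscape:
    """Objective k sampled over an anion (sigma, epsilon) grid."""

    grid: np.ndarray  # (n, 2) sampled (sigma, epsilon)
    k_values: np.ndarray  # objective at each point (nan = invalid)
    best_sampled: tuple[float, float]
    interpolated_minimum: tuple[float, float]
    interpolation: str = "cubic"


def objective_k(simulated: dict[str, ActivityCurve],
                spec: ObjectiveSpec,
                salts: tuple[str, ...] | None = None) -> float:
    """Mean squared deviation of a_cc from the reference.

    The mean runs over the given salts (default: all salts of the spec)
    and over the molalities of each simulated curve; the reference is
    interpolated linearly onto the simulated molalities when the grids
    differ.
    """
    salts = tuple(salts if salts is not None else spec.salts)
    per_salt = []
    for salt in salts:
        if salt not in simulated:
            raise KeyError(f"missing simulated activity curve for {salt}")
        sim = simulated[salt]
        ref = spec.reference[salt]
        if (len(ref.molalities) == len(sim.molalities)
                and np.allclose(ref.molalities, sim.molalities)):
            ref_vals = ref.a_cc
        else:
            ref_vals = ref.interpolate(sim.molalities)
        per_salt.append(np.mean((sim.a_cc - ref_vals) ** 2))
    return float(np.mean(per_salt))


def free_energy_isoline(anion: SpeciesParams, cation_name: str,
                        target_f_pair: float, backend,
                        epsilon_grid, sigma_bounds: tuple[float, float],
                        tol: float = 0.001, charge: float = 1.0,
                        ) -> list[SpeciesParams]:
    """Cation candidates reproducing a target pair solvation free energy.

    For each epsilon on the grid, the sigma solving
    ``pair_free_energy(cation, anion) = target`` is bracketed and
    root-found to ``tol`` (nm, matching the significant third decimal
    of the sigma parameters); epsilons without a root in the bracket
    are skipped with a log note.  An entirely empty isoline raises.
    """
    lo, hi = sigma_bounds
    candidates: list[SpeciesParams] = []

    def make(sigma, eps):
        return SpeciesParams(name=cation_name, sigma=float(sigma),
                             epsilon=float(eps), charge=charge)

    for eps in np.asarray(epsilon_grid, dtype=float):
        def f(sigma, _eps=eps):
            return backend.pair_free_energy(make(sigma, _eps), anion) \
                - target_f_pair
        try:
            f_lo, f_hi = f(lo), f(hi)
        except ValueError:
            logger.info("isoline %s: epsilon=%.3f outside backend domain",
                        cation_name, eps)
            continue
        if f_lo * f_hi > 0:
            logger.info(
                "isoline %s: no root in sigma bracket for epsilon=%.3f",
                cation_name, eps,
            )
            continue
        sigma = brentq(f, lo, hi, xtol=tol)
        candidates.append(make(sigma, eps))
    if not candidates:
        raise ValueError(
            f"empty isoline: target {target_f_pair:.1f} kJ/mol for "
            f"{cation_name} with anion ({anion.sigma:.3f}, "
            f"{anion.epsilon:.3f}) is unattainable in the search range"
        )
    return candidates


def _interpolate_minimum(grid: np.ndarray, k: np.ndarray,
                         ) -> tuple[tuple[float, float], float, str]:
    """Cubic-interpolated landscape minimum within the sampled hull."""
    valid = np.isfinite(k)
    pts, vals = grid[valid], k[valid]
    i_best = int(np.argmin(vals))
    best = (float(pts[i_best, 0]), float(pts[i_best, 1]))
    if len(pts) < 4 or np.ptp(pts[:, 0]) == 0 or np.ptp(pts[:, 1]) == 0:
        warnings.warn("too few landscape points for cubic interpolation; "
                      "reporting the best sampled point", stacklevel=2)
        return best, float(vals[i_best]), "none"
    scale = np.ptp(pts, axis=0)
    norm = (pts - pts.min(axis=0)) / scale
    try:
        interp = CloughTocher2DInterpolator(norm, vals)
    except Exception:  # degenerate geometry (collinear points)
        return best, float(vals[i_best]), "none"
    xs = np.linspace(0.0, 1.0, 121)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    zz = interp(np.column_stack([gx.ravel(), gy.ravel()]))
    if not np.any(np.isfinite(zz)):
        return best, float(vals[i_best]), "none"
    j = int(np.nanargmin(zz))
    p_norm = (gx.ravel()[j], gy.ravel()[j])
    p = (float(p_norm[0] * scale[0] + pts[:, 0].min()),
         float(p_norm[1] * scale[1] + pts[:, 1].min()))
    return p, float(zz[j]), "cubic"


@dataclass
class OptimizationResults:
    """Optimal parameter set with landscapes and diagnostics."""

    forcefield: ForceField
    k_chloride: float
    k_bromide: float
    landscape_chloride: Landscape
    landscape_bromide: Landscape
    cation_candidates: dict[str, int]
    spec: ObjectiveSpec

    @property
    def k_total(self) -> float:
        return 0.5 * (self.k_chloride + self.k_bromide)

    def summary(self) -> str:
        lines = [
            "Salt-family Lennard-Jones optimization",
            "=" * 54,
            f"{'ion':<6}{'sigma (nm)':>12}{'epsilon (kJ/mol)':>18}{'q (e)':>8}",
            "-" * 54,
        ]
        for name in ("K", "Na", "Cl", "Br"):
            if name in self.forcefield:
                s = self.forcefield[name]
                lines.append(
                    f"{name:<6}{s.sigma:>12.3f}{s.epsilon:>18.3f}"
                    f"{s.charge:>8.0f}"
                )
        lines += [
            "-" * 54,
            f"objective k (chloride salts): {self.k_chloride:.3e}",
            f"objective k (bromide salts):  {self.k_bromide:.3e}",
            f"chloride landscape: {len(self.landscape_chloride.grid)} points, "
            f"interpolated min at "
            f"({self.landscape_chloride.interpolated_minimum[0]:.3f}, "
            f"{self.landscape_chloride.interpolated_minimum[1]:.3f})",
            f"bromide landscape:  {len(self.landscape_bromide.grid)} points, "
            f"interpolated min at "
            f"({self.landscape_bromide.interpolated_minimum[0]:.3f}, "
            f"{self.landscape_bromide.interpolated_minimum[1]:.3f})",
        ]
        return "\n".join(lines)


class SaltFamilyOptimizer:
    """Staged optimizer for the K/Na/Cl/Br family against a backend.

    Parameters
    ----------
    backend
        Observable provider with ``pair_free_energy`` and
        ``activity_curve``.
    spec
        Reference curves and molality grid of the activity objective.
    targets
        Pair solvation free-energy targets, keyed by salt label
        (kJ/mol); the experimental values in production use.
    chloride_grid, bromide_grid
        Iterables of (sigma, epsilon) anion samples.
    epsilon_grid
        Epsilon values at which cation isolines are traversed.
    sigma_bounds
        Sigma bracket for the isoline root find.
    noise_floor
        Interpolated landscape minima are reported always, but replace
        the best sampled point only when the interpolated improvement in
        k exceeds this floor; ``None`` (default) keeps the sampled point
        unconditionally, which is the honest choice when the landscape
        is interpolated from noisy samples.
    """

    def __init__(self, backend, spec: ObjectiveSpec, targets: dict[str, float],
                 chloride_grid, bromide_grid,
                 epsilon_grid=None, sigma_bounds: tuple[float, float] = (0.16, 0.59),
                 isoline_tol: float = 0.001,
                 noise_floor: float | None = None):
        self.backend = backend
        self.spec = spec
        self.targets = dict(targets)
        self.chloride_grid = np.asarray(list(chloride_grid), dtype=float)
        self.bromide_grid = np.asarray(list(bromide_grid), dtype=float)
        self.epsilon_grid = (np.asarray(epsilon_grid, dtype=float)
                             if epsilon_grid is not None
                             else np.arange(0.1, 1.31, 0.05))
        self.sigma_bounds = sigma_bounds
        self.isoline_tol = isoline_tol
        self.noise_floor = noise_floor

    # -- helpers ----------------------------------------------------------

    def _curves(self, salts, cations: dict[str, SpeciesParams],
                anion: SpeciesParams) -> dict[str, ActivityCurve]:
        out = {}
        for salt in salts:
            cat_name, _ = SALTS[salt]
            a_cc = self.backend.activity_curve(
                SALTS[salt], cations[cat_name], anion,
                self.spec.molality_grid,
            )
            out[salt] = ActivityCurve(self.spec.molality_grid, a_cc,
                                      label=salt)
        return out

    def _best_cations(self, anion: SpeciesParams, salts,
                      ) -> tuple[dict[str, SpeciesParams], float, int]:
        """Per-cation isoline candidates, activity-selected; returns
        (cations, objective k over the given salts, candidate count)."""
        chosen: dict[str, SpeciesParams] = {}
        n_candidates = 0
        for salt in salts:
            cat_name, _ = SALTS[salt]
            candidates = free_energy_isoline(
                anion, cat_name, self.targets[salt], self.backend,
                self.epsilon_grid, self.sigma_bounds, tol=self.isoline_tol,
            )
            n_candidates += len(candidates)
            best, best_k = None, np.inf
            # deterministic tie-break: candidates scanned in (sigma, eps) order
            for cand in sorted(candidates, key=lambda c: (c.sigma, c.epsilon)):
                k = objective_k(
                    self._curves([salt], {cat_name: cand}, anion),
                    self.spec, salts=(salt,),
                )
                if k < best_k - 1e-15:
                    best, best_k = cand, k
            chosen[cat_name] = best
        k_all = objective_k(self._curves(salts, chosen, anion), self.spec,
                            salts=tuple(salts))
        return chosen, k_all, n_candidates

    def _grid_search(self, grid: np.ndarray, evaluate):
        """Evaluate k over an anion grid; returns (landscape, point, k, payload).

        Failed grid points are excluded from the landscape with a log
        note.  Among equal-k points the smallest sigma, then epsilon,
        wins (deterministic tie-break).  The best sampled point is
        selected unless an interpolated minimum beats it by more than
        the configured noise floor, in which case the interpolated
        point is re-evaluated through the backend and selected only if
        the improvement is real.
        """
        ks = np.full(len(grid), np.nan)
        payloads: list = [None] * len(grid)
        for i, (sig, eps) in enumerate(grid):
            try:
                ks[i], payloads[i] = evaluate(float(sig), float(eps))
            except (ValueError, KeyError, RuntimeError) as err:
                logger.warning("landscape point (%.3f, %.3f) invalid: %s",
                               sig, eps, err)
        if not np.any(np.isfinite(ks)):
            raise RuntimeError("every landscape point failed")
        order = np.lexsort((grid[:, 1], grid[:, 0]))
        i_best = min((i for i in order if np.isfinite(ks[i])),
                     key=lambda i: ks[i])
        interp_min, interp_k, method = _interpolate_minimum(grid, ks)
        landscape = Landscape(
            grid=grid, k_values=ks,
            best_sampled=(float(grid[i_best, 0]), float(grid[i_best, 1])),
            interpolated_minimum=interp_min, interpolation=method,
        )
        point = landscape.best_sampled
        k_sel, payload = float(ks[i_best]), payloads[i_best]
        if (self.noise_floor is not None and method == "cubic"
                and ks[i_best] - interp_k > self.noise_floor):
            try:
                k_new, payload_new = evaluate(*interp_min)
            except (ValueError, KeyError, RuntimeError):
                k_new = np.inf
            if k_new < k_sel - self.noise_floor:
                logger.info(
                    "interpolated minimum improves k by %.3g (> noise "
                    "floor); selecting it", k_sel - k_new,
                )
                point, k_sel, payload = interp_min, float(k_new), payload_new
        return landscape, point, k_sel, payload

    # -- the fit ----------------------------------------------------------

    def fit(self) -> OptimizationResults:
        """Run both stages and return the assembled optimum."""
        chloride_salts = [s for s in self.spec.salts if SALTS[s][1] == "Cl"]
        bromide_salts = [s for s in self.spec.salts if SALTS[s][1] == "Br"]
        counts: dict[str, int] = {}

        def eval_cl(sig, eps):
            anion = SpeciesParams("Cl", sig, eps, charge=-1.0)
            cations, k, n_cand = self._best_cations(anion, chloride_salts)
            counts["isoline_candidates"] = counts.get(
                "isoline_candidates", 0) + n_cand
            return k, cations

        if len(self.chloride_grid) == 1:
            warnings.warn("single-point chloride grid: no interpolation",
                          stacklevel=2)
        land_cl, best_cl, k_cl, cations = self._grid_search(
            self.chloride_grid, eval_cl
        )
        anion_cl = SpeciesParams("Cl", best_cl[0], best_cl[1], charge=-1.0)

        def eval_br(sig, eps):
            anion = SpeciesParams("Br", sig, eps, charge=-1.0)
            k = objective_k(self._curves(bromide_salts, cations, anion),
                            self.spec, salts=tuple(bromide_salts))
            return k, anion

        if len(self.bromide_grid) == 1:
            warnings.warn("single-point bromide grid: no interpolation",
                          stacklevel=2)
        land_br, best_br, k_br, anion_br = self._grid_search(
            self.bromide_grid, eval_br
        )

        ff = ForceField([cations["K"], cations["Na"], anion_cl, anion_br])
        return OptimizationResults(
            forcefield=ff, k_chloride=k_cl, k_bromide=k_br,
            landscape_chloride=land_cl, landscape_bromide=land_br,
            cation_candidates=counts, spec=self.spec,
        )
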