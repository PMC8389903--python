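"""Synthetic trajectory and time-series generators with planted truth.

Production molecular dynamics of electrolyte boxes is far outside desk
scale, but none of the estimators in this package care *how* their input
was generated — only that it has the right statistical structure.  Each
generator here produces exactly the structure one estimator assumes,
with the ground truth planted and returned alongside the data:

* :func:`ideal_gas` — uncorrelated uniform configurations, the null
  model for pair correlations (g = 1, all Kirkwood-Buff integrals 0).
* :func:`mc_fluid` — Metropolis Monte Carlo of a small shifted
  Lennard-Jones (optionally + minimum-image Coulomb) fluid, an
  equilibrium correlated-fluid fixture for RDF/KB estimators.
* :func:`brownian` — diffusive trajectories with planted per-species
  self-diffusion constants, for MSD/conductivity estimators.
* :func:`dipole_process` — stationary Gaussian box-dipole / ion-current
  series with planted static susceptibility components, for the
  dielectric estimator.
* :func:`mock_backend` — an analytic observable backend mapping ion
  (sigma, epsilon) parameters to solvation free energies and activity
  curves with a planted optimum, for optimizer tests.

All generators draw from a ``numpy.random.default_rng(seed)`` stream and
are bit-reproducible for a fixed spec.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from . import constants
from .forcefield import ForceField, SpeciesParams
from .stats import block_average_error
from .trajectory import ScalarSeries, Trajectory, minimum_image_displacement, wrap

logger = logging.getLogger(__name__)

__all__ = [
    "ideal_gas",
    "mc_fluid",
    "MCFluidResult",
    "brownian",
    "dipole_process",
    "DipoleProcessResult",
    "mock_backend",
    "MockBackend",
]


# ---------------------------------------------------------------------------
# ideal gas

def ideal_gas(composition: dict[str, int], box_length: float, n_frames: int,
              seed: int, dt: float = 1.0, charges: dict[str, float] | None = None,
              ) -> Trajectory:
    """Uncorrelated uniform iid configurations (g(r) = 1 in expectation).

    ``composition`` maps species label to particle count.
    """
    if box_length <= 0:
        raise ValueError(f"box_length must be > 0, got {box_length}")
    n_total = int(sum(composition.values()))
    if n_total < 2:
        raise ValueError("need at least two particles")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box_length, size=(n_frames, n_total, 3))
    species = np.concatenate(
        [np.full(n, name, dtype=object) for name, n in composition.items()]
    )
    q = None
    if charges:
        q = np.array([charges.get(s, 0.0) for s in species])
    return Trajectory(pos, box_length, species, q, dt)


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo fluid

@dataclass
class MCFluidResult:
    """Sampled configurations plus sampling diagnostics."""

    trajectory: Trajectory
    acceptance_rate: float
    energies: np.ndarray  # potential energy per stored frame, kJ/mol
    max_displacement: float


def _pair_energy_matrix(ff: ForceField, labels: np.ndarray, coulomb: bool):
    kinds = sorted(set(labels))
    index = {k: i for i, k in enumerate(kinds)}
    idx = np.array([index[s] for s in labels])
    nk = len(kinds)
    sig = np.empty((nk, nk))
    eps = np.empty((nk, nk))
    shift = np.empty((nk, nk))
    qq = np.zeros((nk, nk))
    for a in kinds:
        for b in kinds:
            p = ff.pair(a, b)
            sig[index[a], index[b]] = p.sigma
            eps[index[a], index[b]] = p.epsilon
            shift[index[a], index[b]] = p.shift
            if coulomb:
                qq[index[a], index[b]] = p.charge_product
    return idx, sig, eps, shift, qq, ff.cutoff


def _energy_with(idx, sig, eps, shift, qq, cutoff, pos_others, pos_i, kind_i,
                 others_idx, L):
    d = minimum_image_displacement(pos_others - pos_i, L)
    r2 = np.sum(d * d, axis=1)
    r2 = np.maximum(r2, 1e-12)
    s = sig[kind_i, others_idx]
    e = eps[kind_i, others_idx]
    sh = shift[kind_i, others_idx]
    inside = r2 <= cutoff**2
    sr6 = (s * s / r2) ** 3
    u_lj = np.where(inside, 4.0 * e * (sr6 * sr6 - sr6) - sh, 0.0)
    u = float(np.sum(u_lj))
    q = qq[kind_i, others_idx]
    if np.any(q):
        u += float(np.sum(constants.KE * q / np.sqrt(r2)))
    return u


def mc_fluid(forcefield: ForceField, composition: dict[str, int],
             box_length: float, temperature: float, seed: int,
             n_sweeps: int = 2000, equilibration: int = 500, stride: int = 10,
             max_displacement: float = 0.1, coulomb: bool = False,
             tune: bool = True, stationarity_check: bool = True,
             ) -> MCFluidResult:
    """Sample configurations of a small LJ(+Coulomb) fluid by Metropolis MC.

    Single-particle displacement moves; one sweep attempts one move per
    particle.  The maximum displacement is tuned during equilibration
    toward ~40% acceptance unless ``tune=False``.  Coulomb interactions,
    if enabled, use the bare minimum-image potential (adequate for the
    weakly charged desk-scale fixtures this generator serves).

    Intended for N <= ~200; the move update is O(N).
    """
    n_total = int(sum(composition.values()))
    if n_total < 2:
        raise ValueError("need at least two particles")
    if n_total > 512:
        raise ValueError(f"mc_fluid is a desk-scale sampler; N={n_total} too large")
    labels = np.concatenate(
        [np.full(n, name, dtype=object) for name, n in composition.items()]
    )
    charges = np.array([forcefield[s].charge for s in labels], dtype=float)
    if not coulomb:
        charges = np.zeros_like(charges)
    rng = np.random.default_rng(seed)
    L = box_length
    beta = 1.0 / constants.thermal_energy(temperature)
    idx, sig, eps, shift, qq, cutoff = _pair_energy_matrix(
        forcefield, labels, coulomb
    )
    pos = rng.uniform(0.0, L, size=(n_total, 3))
    all_i = np.arange(n_total)

    def particle_energy(i, xi):
        others = all_i != i
        return _energy_with(idx, sig, eps, shift, qq, cutoff,
                            pos[others], xi, idx[i], idx[others], L)

    def total_energy():
        return 0.5 * sum(particle_energy(i, pos[i]) for i in range(n_total))

    frames, energies = [], []
    n_acc = n_try = 0
    disp = max_displacement
    for sweep in range(n_sweeps):
        for _ in range(n_total):
            i = int(rng.integers(n_total))
            old = pos[i].copy()
            new = np.mod(old + rng.uniform(-disp, disp, size=3), L)
            dU = particle_energy(i, new) - particle_energy(i, old)
            n_try += 1
            if dU <= 0 or rng.random() < np.exp(-beta * dU):
                pos[i] = new
                n_acc += 1
        if tune and sweep < equilibration and (sweep + 1) % 50 == 0:
            rate = n_acc / max(n_try, 1)
            if rate < 0.3:
                disp = max(disp * 0.8, 1e-4)
            elif rate > 0.5:
                disp = min(disp * 1.25, L / 4)
        if sweep >= equilibration and (sweep - equilibration) % stride == 0:
            frames.append(pos.copy())
            energies.append(total_energy())
    rate = n_acc / max(n_try, 1)
    logger.info("mc_fluid: acceptance rate %.3f, max displacement %.4f nm",
                rate, disp)
    if not 0.05 < rate < 0.95:
        warnings.warn(
            f"mc_fluid acceptance rate {rate:.3f} outside (0.05, 0.95); "
            "samples may be poorly decorrelated", stacklevel=2
        )
    energies = np.array(energies)
    if stationarity_check and len(energies) >= 10:
        half = len(energies) // 2
        se = block_average_error(energies, n_blocks=5)
        drift = abs(energies[:half].mean() - energies[half:].mean())
        if se > 0 and drift > 6.0 * se:
            raise RuntimeError(
                f"mc_fluid energy trace is non-stationary (drift {drift:.3g} "
                f"kJ/mol > 6 x block SE {se:.3g}); increase equilibration"
            )
    traj = Trajectory(np.array(frames), L, labels, charges, dt=float(stride))
    return MCFluidResult(traj, rate, energies, disp)


# ---------------------------------------------------------------------------
# Brownian dynamics

def brownian(d_by_species: dict[str, float], composition: dict[str, int],
             box_length: float, n_steps: int, dt: float, seed: int,
             charges: dict[str, float] | None = None) -> Trajectory:
    """Diffusive trajectories with planted per-species diffusion constants.

    Each particle performs an independent Gaussian random walk with
    displacement variance 2*D*dt per Cartesian component per step.
    Coordinates are stored wrapped; the continuous track is recoverable
    with :func:`kbff.trajectory.unwrap` because steps stay below L/2.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    for name, d in d_by_species.items():
        if d < 0:
            raise ValueError(f"negative diffusion constant for {name}")
        step = np.sqrt(2.0 * d * dt)
        if 6.0 * step >= box_length / 2.0:
            raise ValueError(
                f"step size for {name} too large for unambiguous unwrapping; "
                "reduce dt or D, or enlarge the box"
            )
    rng = np.random.default_rng(seed)
    species = np.concatenate(
        [np.full(n, name, dtype=object) for name, n in composition.items()]
    )
    n_total = len(species)
    stds = np.array([np.sqrt(2.0 * d_by_species[s] * dt) for s in species])
    steps = rng.standard_normal((n_steps, n_total, 3)) * stds[None, :, None]
    start = rng.uniform(0.0, box_length, size=(n_total, 3))
    pos = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    q = None
    if charges:
        q = np.array([charges.get(s, 0.0) for s in species])
    traj = Trajectory(pos, box_length, species, q, dt)
    return wrap(traj)


# ---------------------------------------------------------------------------
# dipole / ion-current process

@dataclass
class DipoleProcessResult:
    """Box-dipole and ion-current series with their planted statics.

    ``M`` is the water collective dipole moment (e nm), ``J`` the ion
    current (e nm / ps); ``M_ion`` is the latent itinerant ion dipole the
    current derives from, kept for oracle tests.  ``planted`` holds the
    three static susceptibility contributions the series were constructed
    to have.
    """

    M: ScalarSeries
    J: ScalarSeries
    M_ion: ScalarSeries
    planted: dict
    volume: float
    temperature: float


def dipole_process(chi_ww: float, chi_wi: float, chi_ii: float,
                   volume: float, temperature: float, n_steps: int, dt: float,
                   seed: int, tau_water: float = 5.0, tau_ion: float = 8.0,
                   ) -> DipoleProcessResult:
    """Stationary Gaussian M(t), J(t) with planted susceptibility parts.

    The ion dipole M_I and current J = dM_I/dt follow a critically
    damped harmonic Ornstein-Uhlenbeck pair (keeping M_I stationary so
    the ion contribution to the static susceptibility is finite); the
    water dipole is chi-correlated to M_I plus an independent OU term.
    The planted static contributions are, per the fluctuation formulas,

        chi_ww = <dM_W^2> / (3 eps0 V kT)
        chi_wi = 2 <dM_W . dM_I> / (3 eps0 V kT)
        chi_ii = <dM_I^2> / (3 eps0 V kT)

    and the generator solves for process parameters that realize them.
    """
    if tau_water <= 0 or tau_ion <= 0:
        raise ValueError("correlation times must be positive")
    if chi_ww < 0 or chi_ii < 0:
        raise ValueError("diagonal susceptibility contributions must be >= 0")
    kT = constants.thermal_energy(temperature)
    scale = 3.0 * constants.EPS0 * volume * kT  # e^2 nm^2 per unit chi
    var_mi = chi_ii * scale / 3.0  # per Cartesian component
    var_mw_total = chi_ww * scale
    cov_wi_total = chi_wi * scale / 2.0
    if var_mi == 0.0:
        if chi_wi != 0.0:
            raise ValueError("cannot plant a cross term with chi_ii = 0")
        c = 0.0
    else:
        c = (cov_wi_total / 3.0) / var_mi
    var_w_extra = var_mw_total / 3.0 - c**2 * var_mi
    if var_w_extra < -1e-12:
        raise ValueError(
            "inconsistent planted values: chi_ww too small for the "
            "requested cross term (Cauchy-Schwarz violated)"
        )
    var_w_extra = max(var_w_extra, 0.0)

    rng = np.random.default_rng(seed)
    n_burn = int(20 * max(tau_water, tau_ion) / dt)
    n_tot = n_steps + n_burn

    # critically damped oscillator for (M_I, J): gamma = 2 omega = 2/tau_ion
    omega = 1.0 / tau_ion
    gamma = 2.0 * omega
    mi = np.zeros((n_steps, 3))
    j = np.zeros((n_steps, 3))
    if var_mi > 0:
        a_mat = np.array([[0.0, 1.0], [-(omega**2), -gamma]])
        f_mat = expm(a_mat * dt)
        sigma_inf = np.diag([var_mi, var_mi * omega**2])
        cov_step = sigma_inf - f_mat @ sigma_inf @ f_mat.T
        cov_step = 0.5 * (cov_step + cov_step.T)
        chol = np.linalg.cholesky(cov_step + 1e-300 * np.eye(2))
        for k in range(3):
            x = np.zeros(2)
            out = np.empty((n_tot, 2))
            noise = rng.standard_normal((n_tot, 2))
            for t in range(n_tot):
                x = f_mat @ x + chol @ noise[t]
                out[t] = x
            mi[:, k] = out[n_burn:, 0]
            j[:, k] = out[n_burn:, 1]

    # independent OU part of the water dipole
    w = np.zeros((n_steps, 3))
    if var_w_extra > 0:
        decay = np.exp(-dt / tau_water)
        step_std = np.sqrt(var_w_extra * (1.0 - decay**2))
        for k in range(3):
            noise = rng.standard_normal(n_tot)
            x = 0.0
            out = np.empty(n_tot)
            for t in range(n_tot):
                x = decay * x + step_std * noise[t]
                out[t] = x
            w[:, k] = out[n_burn:]

    m_w = c * mi + w
    planted = {"chi_ww": chi_ww, "chi_wi": chi_wi, "chi_ii": chi_ii,
               "volume_nm3": volume, "temperature_K": temperature,
               "tau_water_ps": tau_water, "tau_ion_ps": tau_ion}
    return DipoleProcessResult(
        M=ScalarSeries(m_w, dt, name="water_dipole"),
        J=ScalarSeries(j, dt, name="ion_current"),
        M_ion=ScalarSeries(mi, dt, name="ion_dipole"),
        planted=planted, volume=volume, temperature=temperature,
    )


# ---------------------------------------------------------------------------
# mock observable backend with planted optimum

@dataclass
class MockBackend:
    """Analytic observable backend with a planted optimal parameter set.

    Maps ion (sigma, epsilon) to pair solvation free energies and
    activity-derivative curves.  Single-ion free energies are linear in
    (sigma, epsilon) so that solvation-free-energy isolines are straight
    lines in parameter space; activity curves deviate from the reference
    by a quadratic penalty in the distance of each ion from its planted
    optimum, so the global objective minimum sits exactly at the planted
    parameters.  Optional Gaussian observation noise emulates sampling
    error.
    """

    optima: dict[str, tuple[float, float]]
    sigma_range: tuple[float, float] = (0.15, 0.60)
    epsilon_range: tuple[float, float] = (0.05, 1.50)
    noise: float = 0.0
    seed: int = 0
    f_slope_sigma: float = 400.0  # kJ/mol per nm
    f_slope_epsilon: float = 40.0  # kJ/mol per (kJ/mol)
    penalty_sigma: float = 0.05  # nm scale of the activity penalty
    penalty_epsilon: float = 0.5  # kJ/mol scale of the activity penalty

    def __post_init__(self):
        self._rng = np.random.default_rng(self.seed)

    def _check_domain(self, p: SpeciesParams) -> None:
        lo_s, hi_s = self.sigma_range
        lo_e, hi_e = self.epsilon_range
        if not (lo_s <= p.sigma <= hi_s and lo_e <= p.epsilon <= hi_e):
            raise ValueError(
                f"parameters ({p.sigma:.3f} nm, {p.epsilon:.3f} kJ/mol) for "
                f"{p.name} outside backend domain sigma {self.sigma_range}, "
                f"epsilon {self.epsilon_range}"
            )

    def _single_ion_f(self, p: SpeciesParams) -> float:
        # linear map; cations and anions share the form, offset by name
        base = -250.0 if p.charge > 0 else -180.0
        return (base - self.f_slope_sigma * (p.sigma - 0.3)
                - self.f_slope_epsilon * (p.epsilon - 0.5))

    def pair_free_energy(self, cation: SpeciesParams,
                         anion: SpeciesParams) -> float:
        """Salt pair solvation free energy, kJ/mol."""
        self._check_domain(cation)
        self._check_domain(anion)
        return self._single_ion_f(cation) + self._single_ion_f(anion)

    def target_pair_free_energy(self, cation_name: str, anion_name: str) -> float:
        """The 'experimental' pair free energy: the value at the planted set."""
        return self.pair_free_energy(self.planted_params(cation_name),
                                     self.planted_params(anion_name))

    def planted_params(self, name: str) -> SpeciesParams:
        s, e = self.optima[name]
        charge = 1.0 if name in ("Na", "K") else -1.0
        return SpeciesParams(name=name, sigma=s, epsilon=e, charge=charge)

    def _distance(self, p: SpeciesParams) -> float:
        s_star, e_star = self.optima[p.name]
        return (((p.sigma - s_star) / self.penalty_sigma) ** 2
                + ((p.epsilon - e_star) / self.penalty_epsilon) ** 2)

    def reference_curve(self, molalities) -> np.ndarray:
        """The 'experimental' activity derivative (the planted optimum curve)."""
        m = np.asarray(molalities, dtype=float)
        return 1.0 - 0.35 * np.sqrt(m) / (1.0 + np.sqrt(m)) + 0.06 * m

    def activity_curve(self, salt: tuple[str, str], cation: SpeciesParams,
                       anion: SpeciesParams, molalities) -> np.ndarray:
        """Simulated a_cc(m) for the given parameter set."""
        self._check_domain(cation)
        self._check_domain(anion)
        m = np.asarray(molalities, dtype=float)
        penalty = self._distance(cation) + self._distance(anion)
        curve = self.reference_curve(m) + penalty * (0.1 + 0.05 * m)
        if self.noise > 0:
            curve = curve + self._rng.normal(0.0, self.noise, size=m.shape)
        return curve


def mock_backend(optima: dict[str, tuple[float, float]] | None = None,
                 noise: float = 0.0, seed: int = 0, **kwargs) -> MockBackend:
    """Build a :class:`MockBackend`; default optima mimic the shipped table."""
    if optima is None:
        optima = {"K": (0.283, 0.90), "Na": (0.231, 0.45),
                  "Cl": (0.43, 0.42), "Br": (0.443, 0.75)}
    return MockBackend(optima=optima, noise=noise, seed=seed, **kwargs)
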