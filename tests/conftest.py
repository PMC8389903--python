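"""Shared fixtures and oracle helpers for the kbff test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kbff.forcefield import ForceField, SpeciesParams, table1_ions
from kbff.solvation import TIRecord, ti_integrate
from kbff.stats import block_average_error

settings.register_profile(
    "kbff",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("kbff")


@pytest.fixture(scope="session")
def ions() -> ForceField:
    """The bundled optimized alkali-halide parameter table."""
    return table1_ions()


@pytest.fixture(scope="session")
def lj_fluid_ff() -> ForceField:
    """A single-species neutral LJ fluid used by MC fixtures."""
    return ForceField([SpeciesParams("A", 0.34, 0.8)])


def toy_charging_ti(spring_k: float, coupling_c: float, temperature: float,
                    n_lambdas: int, n_samples: int, seed: int,
                    ) -> tuple[float, float, float]:
    """Sampled TI estimate of a closed-form charging free energy.

    A particle in a 1-D harmonic well, H(lam) = k x^2/2 + lam c x
    (charging against a fixed linear external potential).  At coupling
    lam the coordinate is Gaussian with mean -lam c/k and variance
    kT/k, so <dH/dlam> = c <x> = -lam c^2/k and the exact free-energy
    difference is dF = -c^2/(2k), independent of temperature.

    Draws exact Boltzmann samples at each of ``n_lambdas`` states,
    estimates <dH/dlam> with 5-block errors, and integrates.  Returns
    (estimate, propagated error, exact value).
    """
    from kbff import constants

    rng = np.random.default_rng(seed)
    kt = constants.thermal_energy(temperature)
    lambdas = np.linspace(0.0, 1.0, n_lambdas)
    means, errors = [], []
    for lam in lambdas:
        x = rng.normal(-lam * coupling_c / spring_k,
                       np.sqrt(kt / spring_k), size=n_samples)
        dhdl = coupling_c * x
        means.append(dhdl.mean())
        errors.append(block_average_error(dhdl, 5))
    record = TIRecord(lambdas, means, errors, stage="charging")
    value, error = ti_integrate(record, scheme="trapezoid")
    exact = -coupling_c**2 / (2.0 * spring_k)
    return value, error, exact


def brute_force_rdf_counts(positions: np.ndarray, idx_a, idx_b, same: bool,
                           box_length: float, edges: np.ndarray) -> np.ndarray:
    """Triple-loop minimum-image pair histogram (independent RDF oracle)."""
    counts = np.zeros(len(edges) - 1)
    for frame in positions:
        for ii, i in enumerate(idx_a):
            for j in idx_b:
                if same and j <= i:
                    continue
                d = frame[i] - frame[j]
                d -= box_length * np.round(d / box_length)
                r = np.sqrt(np.sum(d * d))
                if r >= edges[-1]:
                    continue
                b = int(np.searchsorted(edges, r, side="right")) - 1
                if 0 <= b < len(counts):
                    counts[b] += 1
    return counts


def brute_force_msd(pos: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Double-loop all-origins MSD (independent transport oracle)."""
    n_frames = pos.shape[0]
    out = np.zeros(len(lags))
    for k, lag in enumerate(lags):
        if lag == 0:
            continue
        acc, count = 0.0, 0
        for t0 in range(n_frames - lag):
            d = pos[t0 + lag] - pos[t0]
            acc += np.sum(d * d)
            count += d.shape[0]
        out[k] = acc / count
    return out
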