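"""Generators: determinism, planted-truth recovery, sampling oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from kbff import constants
from kbff.forcefield import SpeciesParams, lj_potential_shifted
from kbff.structure import radial_distribution
from kbff.synthetic import (
    brownian,
    dipole_process,
    ideal_gas,
    mc_fluid,
    mock_backend,
)
from kbff.trajectory import unwrap


class TestDeterminism:
    def test_ideal_gas_bit_identical(self):
        a = ideal_gas({"A": 30}, 3.0, 10, seed=9)
        b = ideal_gas({"A": 30}, 3.0, 10, seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_brownian_bit_identical(self):
        a = brownian({"A": 1e-3}, {"A": 8}, 4.0, 100, 1.0, seed=9)
        b = brownian({"A": 1e-3}, {"A": 8}, 4.0, 100, 1.0, seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_mc_fluid_bit_identical(self, lj_fluid_ff):
        kwargs = dict(composition={"A": 10}, box_length=1.5,
                      temperature=300.0, seed=9, n_sweeps=120,
                      equilibration=40, stride=10)
        a = mc_fluid(lj_fluid_ff, **kwargs)
        b = mc_fluid(lj_fluid_ff, **kwargs)
        np.testing.assert_array_equal(a.trajectory.positions,
                                      b.trajectory.positions)

    def test_dipole_process_bit_identical(self):
        kwargs = dict(chi_ww=50.0, chi_wi=-2.0, chi_ii=1.0, volume=100.0,
                      temperature=300.0, n_steps=500, dt=0.5, seed=9)
        a = dipole_process(**kwargs)
        b = dipole_process(**kwargs)
        np.testing.assert_array_equal(a.M.values, b.M.values)
        np.testing.assert_array_equal(a.J.values, b.J.values)


class TestIdealGas:
    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            ideal_gas({"A": 1}, 3.0, 5, seed=0)
        with pytest.raises(ValueError):
            ideal_gas({"A": 10}, 0.0, 5, seed=0)

    def test_positions_inside_box(self):
        traj = ideal_gas({"A": 50}, 2.5, 20, seed=1)
        assert traj.positions.min() >= 0.0
        assert traj.positions.max() <= 2.5


class TestMCFluid:
    def test_excluded_volume(self, lj_fluid_ff):
        result = mc_fluid(lj_fluid_ff, {"A": 24}, box_length=1.8,
                          temperature=300.0, seed=13, n_sweeps=400,
                          equilibration=150, stride=10)
        rdf = radial_distribution(result.trajectory, ("A", "A"),
                                  bin_width=0.02)
        # hard repulsion empties g(r) well below sigma = 0.34 nm
        assert np.all(rdf.g[rdf.r_mid < 0.25] == 0.0)
        assert 0.05 < result.acceptance_rate < 0.95

    def test_two_particle_boltzmann_quadrature_oracle(self, lj_fluid_ff):
        """N=2 radial distribution against direct numerical integration.

        For two particles the distance distribution is
        p(r) dr  prop.  exp(-beta u(r)) 4 pi r^2 dr (minimum image,
        r < L/2), so binned probabilities follow from 1-D quadrature.
        """
        L, T = 1.5, 300.0
        result = mc_fluid(lj_fluid_ff, {"A": 2}, box_length=L, temperature=T,
                          seed=17, n_sweeps=12000, equilibration=500,
                          stride=2)
        traj = result.trajectory
        rdf = radial_distribution(traj, ("A", "A"), bin_width=0.05)
        beta = 1.0 / constants.thermal_energy(T)
        pair = lj_fluid_ff.pair("A", "A")

        def w(r):
            return np.exp(-beta * lj_potential_shifted(r, pair)) * r**2

        norm = quad(w, 1e-3, L / 2, limit=200)[0]
        probs = np.array([
            quad(w, lo, hi, limit=200)[0] / norm
            for lo, hi in zip(rdf.bin_edges[:-1], rdf.bin_edges[1:])
        ])
        observed = rdf.counts / rdf.counts.sum()
        n = rdf.counts.sum()
        se = np.sqrt(probs * (1 - probs) / n)
        # correlated samples inflate errors; allow a generous factor
        pulls = np.abs(observed - probs) / np.maximum(se, 1e-4)
        assert np.mean(pulls < 5.0) > 0.9
        assert abs(observed[probs > 0.01] - probs[probs > 0.01]).max() < 0.02

    def test_histogram_reweighting_consistency(self, lj_fluid_ff):
        """Energy histogram at T reweights onto the histogram at T'."""
        L = 1.8
        common = dict(composition={"A": 16}, box_length=L, n_sweeps=900,
                      equilibration=300, stride=3)
        cold = mc_fluid(lj_fluid_ff, temperature=290.0, seed=23, **common)
        hot = mc_fluid(lj_fluid_ff, temperature=310.0, seed=29, **common)
        beta_c = 1.0 / constants.thermal_energy(290.0)
        beta_h = 1.0 / constants.thermal_energy(310.0)
        e_c, e_h = cold.energies, hot.energies
        # reweight cold-sample mean energy to the hot temperature
        log_w = -(beta_h - beta_c) * e_c
        log_w -= log_w.max()
        w = np.exp(log_w)
        reweighted = np.sum(w * e_c) / np.sum(w)
        direct = e_h.mean()
        spread = max(e_c.std(), e_h.std())
        assert abs(reweighted - direct) < spread

    def test_oversized_system_rejected(self, lj_fluid_ff):
        with pytest.raises(ValueError, match="desk-scale"):
            mc_fluid(lj_fluid_ff, {"A": 1000}, 5.0, 300.0, seed=0)


class TestBrownian:
    def test_zero_diffusion_is_immobile(self):
        traj = brownian({"A": 0.0}, {"A": 5}, 4.0, 50, 1.0, seed=3)
        assert np.all(traj.positions == traj.positions[0])

    def test_two_species_diffusivity_ratio(self):
        d_minus = 8e-4
        traj = brownian({"P": 2 * d_minus, "M": d_minus},
                        {"P": 40, "M": 40}, 6.0, 6000, 1.0, seed=31)
        u = unwrap(traj)
        from kbff.transport import fit_self_diffusion, mean_squared_displacement

        d_p = fit_self_diffusion(
            mean_squared_displacement(u, "P")).D_sim
        d_m = fit_self_diffusion(
            mean_squared_displacement(u, "M")).D_sim
        assert d_p / d_m == pytest.approx(2.0, rel=0.15)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            brownian({"A": 1e-3}, {"A": 4}, 4.0, 10, 0.0, seed=0)

    def test_unwrappable_by_construction(self):
        traj = brownian({"A": 2e-3}, {"A": 10}, 3.0, 500, 1.0, seed=5)
        u = unwrap(traj)
        from kbff.trajectory import wrap

        np.testing.assert_allclose(wrap(u).positions, traj.positions,
                                   atol=1e-9)


class TestDipoleProcess:
    def test_zero_current_when_no_ion_term(self):
        res = dipole_process(chi_ww=50.0, chi_wi=0.0, chi_ii=0.0,
                             volume=100.0, temperature=300.0, n_steps=1000,
                             dt=0.5, seed=7)
        assert np.all(res.J.values == 0.0)
        assert np.all(res.M_ion.values == 0.0)

    def test_water_variance_matches_planted_static(self):
        chi_ww, vol, T = 60.0, 200.0, 300.0
        res = dipole_process(chi_ww=chi_ww, chi_wi=0.0, chi_ii=0.0,
                             volume=vol, temperature=T, n_steps=60000,
                             dt=0.5, seed=19, tau_water=3.0)
        var = res.M.values.var(axis=0).sum()
        planted_var = chi_ww * 3 * constants.EPS0 * vol * \
            constants.thermal_energy(T)
        assert var == pytest.approx(planted_var, rel=0.1)

    def test_cross_term_requires_ion_term(self):
        with pytest.raises(ValueError, match="cross term"):
            dipole_process(chi_ww=50.0, chi_wi=-1.0, chi_ii=0.0,
                           volume=100.0, temperature=300.0, n_steps=100,
                           dt=0.5, seed=0)

    def test_invalid_correlation_time_rejected(self):
        with pytest.raises(ValueError, match="correlation times"):
            dipole_process(chi_ww=1.0, chi_wi=0.0, chi_ii=0.0, volume=10.0,
                           temperature=300.0, n_steps=10, dt=0.5, seed=0,
                           tau_water=-1.0)


class TestMockBackend:
    def test_objective_zero_at_planted_optimum(self):
        backend = mock_backend()
        m = np.arange(0.5, 5.0, 0.5)
        curve = backend.activity_curve(
            ("Na", "Cl"), backend.planted_params("Na"),
            backend.planted_params("Cl"), m)
        np.testing.assert_allclose(curve, backend.reference_curve(m))

    def test_pair_free_energy_additive_and_deterministic(self):
        backend = mock_backend()
        na, cl = backend.planted_params("Na"), backend.planted_params("Cl")
        assert backend.pair_free_energy(na, cl) == \
            backend.pair_free_energy(na, cl)

    def test_domain_violation_rejected(self):
        backend = mock_backend()
        bad = SpeciesParams("Na", sigma=0.7, epsilon=0.4, charge=1.0)
        with pytest.raises(ValueError, match="domain"):
            backend.pair_free_energy(bad, backend.planted_params("Cl"))

    def test_observation_noise_is_seeded(self):
        m = np.arange(0.5, 3.0, 0.5)
        a = mock_backend(noise=0.05, seed=3)
        b = mock_backend(noise=0.05, seed=3)
        na, cl = a.planted_params("Na"), a.planted_params("Cl")
        np.testing.assert_array_equal(
            a.activity_curve(("Na", "Cl"), na, cl, m),
            b.activity_curve(("Na", "Cl"), na, cl, m),
        )
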