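"""Objective algebra, isolines, landscape interpolation, staged recovery."""

import numpy as np
import pytest

from kbff.activity import ActivityCurve
from kbff.optimizer import (
    SALTS,
    Landscape,
    ObjectiveSpec,
    SaltFamilyOptimizer,
    _interpolate_minimum,
    free_energy_isoline,
    objective_k,
)
from kbff.synthetic import mock_backend

MOLS = np.arange(0.5, 5.0, 0.5)


def make_spec(backend, molalities=MOLS):
    reference = {
        salt: ActivityCurve(molalities, backend.reference_curve(molalities),
                            label=salt)
        for salt in SALTS
    }
    return ObjectiveSpec(reference=reference, molality_grid=molalities)


def make_targets(backend):
    return {salt: backend.target_pair_free_energy(*pair)
            for salt, pair in SALTS.items()}


class TestObjective:
    def setup_method(self):
        self.backend = mock_backend()
        self.spec = make_spec(self.backend)

    def curves(self, offsets):
        return {
            salt: ActivityCurve(
                MOLS, self.backend.reference_curve(MOLS) + off, label=salt)
            for salt, off in offsets.items()
        }

    def test_identical_curves_give_zero(self):
        sim = self.curves({s: 0.0 for s in SALTS})
        assert objective_k(sim, self.spec) == 0.0

    def test_uniform_offset_gives_delta_squared(self):
        delta = 0.07
        sim = self.curves({s: delta for s in SALTS})
        assert objective_k(sim, self.spec) == pytest.approx(delta**2)

    def test_two_salt_offsets_average(self):
        d1, d2 = 0.1, -0.04
        sim = self.curves({"NaCl": d1, "KCl": d2})
        k = objective_k(sim, self.spec, salts=("NaCl", "KCl"))
        assert k == pytest.approx((d1**2 + d2**2) / 2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        sim = self.curves({s: rng.uniform(-0.1, 0.1) for s in SALTS})
        a = objective_k(sim, self.spec, salts=("NaCl", "KCl", "NaBr", "KBr"))
        b = objective_k(sim, self.spec, salts=("KBr", "NaCl", "KCl", "NaBr"))
        assert a == pytest.approx(b)

    def test_reference_interpolated_onto_simulated_grid(self):
        # simulated curves sitting exactly on the linear interpolant of
        # the reference must give k = 0 on a mismatched grid
        other = np.arange(0.75, 4.5, 0.75)
        sim = {
            s: ActivityCurve(other, self.spec.reference[s].interpolate(other))
            for s in SALTS
        }
        assert objective_k(sim, self.spec) == pytest.approx(0.0, abs=1e-15)

    def test_missing_salt_curve_rejected(self):
        sim = self.curves({"NaCl": 0.0})
        with pytest.raises(KeyError, match="KCl"):
            objective_k(sim, self.spec, salts=("NaCl", "KCl"))

    def test_noise_floor_equals_noise_variance(self):
        """At the true optimum the expected objective is the observation
        noise variance s^2 (averaged over seeds)."""
        s = 0.05
        ks = []
        for seed in range(30):
            backend = mock_backend(noise=s, seed=seed)
            sim = {
                salt: ActivityCurve(MOLS, backend.activity_curve(
                    pair, backend.planted_params(pair[0]),
                    backend.planted_params(pair[1]), MOLS))
                for salt, pair in SALTS.items()
            }
            ks.append(objective_k(sim, self.spec))
        assert np.mean(ks) == pytest.approx(s**2, rel=0.25)

    def test_molality_grid_range_enforced(self):
        backend = mock_backend()
        with pytest.raises(ValueError, match="strictly inside"):
            make_spec(backend, molalities=np.array([0.5, 5.0]))


class TestIsoline:
    def setup_method(self):
        self.backend = mock_backend()
        self.anion = self.backend.planted_params("Cl")
        self.eps_grid = np.arange(0.1, 1.31, 0.05)

    def test_candidates_hit_target(self):
        target = self.backend.target_pair_free_energy("K", "Cl")
        candidates = free_energy_isoline(
            self.anion, "K", target, self.backend, self.eps_grid,
            (0.16, 0.59))
        assert candidates
        for cand in candidates:
            f = self.backend.pair_free_energy(cand, self.anion)
            assert abs(f - target) < 0.5  # within root tolerance in F units

    def test_contains_planted_point(self):
        target = self.backend.target_pair_free_energy("K", "Cl")
        candidates = free_energy_isoline(
            self.anion, "K", target, self.backend,
            self.eps_grid, (0.16, 0.59), tol=1e-6)
        planted = self.backend.planted_params("K")
        best = min(candidates,
                   key=lambda c: abs(c.epsilon - planted.epsilon))
        assert best.epsilon == pytest.approx(planted.epsilon, abs=1e-9)
        assert best.sigma == pytest.approx(planted.sigma, abs=1e-4)

    def test_unattainable_target_raises(self):
        with pytest.raises(ValueError, match="unattainable"):
            free_energy_isoline(self.anion, "K", -10000.0, self.backend,
                                self.eps_grid, (0.16, 0.59))


class TestLandscapeInterpolation:
    def test_quadratic_minimum_recovered(self):
        s0, e0 = 0.425, 0.47
        sig = np.linspace(0.40, 0.46, 7)
        eps = np.linspace(0.35, 0.55, 7)
        grid = np.array([(s, e) for s in sig for e in eps])
        k = 3.0 * (grid[:, 0] - s0) ** 2 + 0.8 * (grid[:, 1] - e0) ** 2
        (p_sig, p_eps), _, method = _interpolate_minimum(grid, k)
        assert method == "cubic"
        assert p_sig == pytest.approx(s0, abs=np.diff(sig)[0])
        assert p_eps == pytest.approx(e0, abs=np.diff(eps)[0])

    def test_minimum_inside_convex_hull(self):
        rng = np.random.default_rng(8)
        grid = rng.uniform([0.4, 0.3], [0.46, 0.6], size=(30, 2))
        k = (grid[:, 0] - 0.43) ** 2 + (grid[:, 1] - 0.42) ** 2
        (p_sig, p_eps), _, _ = _interpolate_minimum(grid, k)
        assert grid[:, 0].min() <= p_sig <= grid[:, 0].max()
        assert grid[:, 1].min() <= p_eps <= grid[:, 1].max()

    def test_degenerate_grid_warns(self):
        grid = np.array([[0.43, 0.42]])
        with pytest.warns(UserWarning, match="interpolation"):
            p, k, method = _interpolate_minimum(grid, np.array([1.0]))
        assert method == "none" and p == (0.43, 0.42)


def cl_grid():
    return [(round(s, 3), round(e, 2))
            for s in np.arange(0.41, 0.4501, 0.01)
            for e in np.arange(0.32, 0.5201, 0.05)]


def br_grid():
    return [(round(s, 3), round(e, 2))
            for s in np.arange(0.423, 0.4631, 0.01)
            for e in np.arange(0.65, 0.8501, 0.05)]


class TestStagedOptimization:
    def test_noiseless_recovery_of_planted_set(self):
        backend = mock_backend()
        model = SaltFamilyOptimizer(
            backend, make_spec(backend), make_targets(backend),
            chloride_grid=cl_grid(), bromide_grid=br_grid(),
            epsilon_grid=np.arange(0.10, 1.31, 0.05),
        )
        res = model.fit()
        for name, (s_true, e_true) in backend.optima.items():
            s = res.forcefield[name]
            assert s.sigma == pytest.approx(s_true, abs=0.011)
            assert s.epsilon == pytest.approx(e_true, abs=0.051)
        assert res.k_chloride < 1e-10
        assert res.k_bromide < 1e-10
        assert "sigma" in res.summary()

    def test_offgrid_optimum_interpolation_helps(self):
        # plant the chloride optimum between grid points: the
        # interpolated minimum must be closer to truth than the best
        # sampled point
        optima = {"K": (0.283, 0.90), "Na": (0.231, 0.45),
                  "Cl": (0.435, 0.445), "Br": (0.443, 0.75)}
        backend = mock_backend(optima=optima)
        model = SaltFamilyOptimizer(
            backend, make_spec(backend), make_targets(backend),
            chloride_grid=cl_grid(), bromide_grid=br_grid(),
            epsilon_grid=np.arange(0.10, 1.31, 0.05),
        )
        res = model.fit()
        land = res.landscape_chloride
        truth = np.array(optima["Cl"])
        d_interp = np.linalg.norm(np.array(land.interpolated_minimum) - truth)
        d_sampled = np.linalg.norm(np.array(land.best_sampled) - truth)
        assert d_interp < d_sampled

    def test_single_point_grid_warns_and_returns_it(self):
        backend = mock_backend()
        model = SaltFamilyOptimizer(
            backend, make_spec(backend), make_targets(backend),
            chloride_grid=[(0.43, 0.42)], bromide_grid=[(0.443, 0.75)],
            epsilon_grid=np.arange(0.10, 1.31, 0.05),
        )
        with pytest.warns(UserWarning):
            res = model.fit()
        assert res.landscape_chloride.best_sampled == (0.43, 0.42)

    def test_invalid_grid_points_are_skipped(self):
        backend = mock_backend()
        grid = cl_grid() + [(0.9, 0.42)]  # outside the backend domain
        model = SaltFamilyOptimizer(
            backend, make_spec(backend), make_targets(backend),
            chloride_grid=grid, bromide_grid=br_grid(),
            epsilon_grid=np.arange(0.10, 1.31, 0.05),
        )
        res = model.fit()
        bad = np.isnan(res.landscape_chloride.k_values)
        assert bad.sum() == 1
        assert res.forcefield["Cl"].sigma == pytest.approx(0.43)

    def test_landscape_dataclass_contract(self):
        land = Landscape(grid=np.array([[0.4, 0.4]]),
                         k_values=np.array([0.1]),
                         best_sampled=(0.4, 0.4),
                         interpolated_minimum=(0.4, 0.4))
        assert land.interpolation == "cubic"
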