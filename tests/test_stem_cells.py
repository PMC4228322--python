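"""Difference-equation stem-cell model: grid, sigmoids, update rules,
conservation, equilibrium and the dense linear-operator oracle."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myelosim.params import ScParams, SigmoidAnchors
from myelosim.stem_cells import (
    ScKill,
    ScModel,
    ScState,
    apply_kill_omega,
    build_affinity_grid,
    fit_sigmoid,
    sc_metrics,
    transition_alpha,
    transition_omega,
)


class TestAffinityGrid:
    def test_default_human_grid(self):
        grid = build_affinity_grid(0.0488, 0.002)
        assert grid.k_max == 127
        assert grid.affinities[0] == 1.0
        assert np.all(np.diff(grid.affinities) < 0)
        assert grid.affinities[-1] > 0.002

    def test_small_grid_brute_force(self):
        # independent enumeration oracle
        rho, a_min = math.log(2.0), 0.3
        expected = max(k for k in range(100)
                       if math.exp(-k * rho) > a_min)
        grid = build_affinity_grid(rho, a_min)
        assert grid.k_max == expected == 1

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            build_affinity_grid(0.0488, 1.5)


class TestSigmoid:
    @pytest.mark.parametrize("anchors", [
        (0.5, 0.45, 0.05, 0.0, 1e5),   # Omega -> Alpha characteristic
        (0.5, 0.3, 0.1, 0.0, 1e5),     # Alpha -> Omega characteristic
    ])
    def test_anchors_reproduced(self, anchors):
        f0, f_half, f_N, f_inf, N = anchors
        shape = fit_sigmoid(*anchors)
        assert shape(0.0) == pytest.approx(f0, abs=1e-10)
        assert shape(N / 2) == pytest.approx(f_half, abs=1e-10)
        assert shape(N) == pytest.approx(f_N, abs=1e-10)
        assert shape(1e12) == pytest.approx(f_inf, abs=1e-10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.2, 0.9), st.floats(0.05, 0.15), st.floats(0.005, 0.04))
    def test_random_decreasing_anchor_sets(self, f0, f_half_gap, f_N):
        f_half = f0 - f_half_gap
        shape = fit_sigmoid(f0, f_half, f_N, 0.0, 1e4)
        assert shape(0.0) == pytest.approx(f0, abs=1e-9)
        assert shape(5e3) == pytest.approx(f_half, abs=1e-9)
        assert shape(1e4) == pytest.approx(f_N, abs=1e-9)
        grid = np.linspace(0, 5e4, 200)
        vals = shape(grid)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError, match="f0"):
            fit_sigmoid(0.3, 0.2, 0.1, 0.3, 1e5)


class TestTransitionIntensities:
    PARAMS = ScParams()

    def test_alpha_at_equilibrium_anchor(self):
        shape = fit_sigmoid(0.5, 0.45, 0.05, 0.0, 1e5)
        assert transition_alpha(1.0, 1e5, shape) == pytest.approx(0.05,
                                                                  abs=1e-10)

    def test_omega_at_empty_target(self):
        shape = fit_sigmoid(0.5, 0.3, 0.1, 0.0, 1e5)
        assert transition_omega(0.002, 0.0, shape, a_min=0.002) == \
            pytest.approx(0.5, abs=1e-10)

    def test_alpha_decreasing_in_target_occupancy(self):
        shape = fit_sigmoid(0.5, 0.45, 0.05, 0.0, 1e5)
        vals = [transition_alpha(0.7, n, shape) for n in (0, 5e4, 1e5, 2e5)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_intensities_are_probabilities(self):
        model = ScModel()
        a = model.grid.affinities
        for n in (0.0, 1e4, 1e5, 1e7):
            assert np.all((0 <= transition_alpha(a, n, model.f_alpha))
                          & (transition_alpha(a, n, model.f_alpha) <= 1))
            om = transition_omega(a, n, model.f_omega,
                                  a_min=model.params.a_min)
            assert np.all((0 <= om) & (om <= 1))


class TestKill:
    def _state(self, model):
        rng = np.random.default_rng(7)
        s = model.empty_state()
        s.A[:] = rng.uniform(0, 100, s.A.shape)
        s.Omega[:] = rng.uniform(0, 10, s.Omega.shape)
        return s

    def test_psi_zero_is_identity(self, sc_model):
        s = self._state(sc_model)
        out = apply_kill_omega(s, 0.1951, psi=0.0)
        assert np.array_equal(out.Omega, s.Omega)
        assert out.deaths == 0.0

    def test_total_kill_spares_alpha(self, sc_model):
        s = self._state(sc_model)
        out = apply_kill_omega(s, 1.0, psi=1.0)
        assert np.all(out.Omega == 0.0)
        assert np.array_equal(out.A, s.A)
        assert out.deaths == pytest.approx(s.Omega.sum())

    def test_first_cycle_survival_factor(self, sc_model):
        # CHOP first cycle: survival 1 - 0.1951 * 1.3 per step
        s = self._state(sc_model)
        out = apply_kill_omega(s, 0.1951, psi=1.3)
        np.testing.assert_allclose(out.Omega, s.Omega * (1 - 0.1951 * 1.3))

    def test_excess_kill_clamped_with_warning(self, sc_model):
        s = self._state(sc_model)
        with pytest.warns(UserWarning, match="clamped"):
            out = apply_kill_omega(s, 1.5, psi=1.0)
        assert np.all(out.Omega == 0.0)


class TestStepRules:
    def test_empty_state_stays_empty(self, sc_model):
        out = sc_model.step(sc_model.empty_state())
        assert out.N_S == 0.0
        assert out.efflux == 0.0

    def test_mitotic_cohort_progresses_without_switching(self, sc_model):
        s = sc_model.empty_state()
        s.Omega[5, 40] = 123.0
        out = sc_model.step(s)
        assert out.Omega[6, 41] == pytest.approx(123.0)
        assert out.Omega.sum() == pytest.approx(123.0)
        assert out.N_A == 0.0

    def test_division_doubles_into_next_affinity(self, sc_model):
        s = sc_model.empty_state()
        s.Omega[10, 48] = 7.0
        out = sc_model.step(s)
        assert out.Omega[11, 0] == pytest.approx(14.0)
        assert out.divisions == pytest.approx(7.0)

    def test_mitotic_cells_never_enter_alpha(self, sc_model):
        s = sc_model.empty_state()
        s.Omega[:, 32:] = 5.0
        out = sc_model.step(s)
        assert out.N_A == 0.0

    def test_switch_from_alpha_enters_mitosis(self, sc_model):
        s = sc_model.empty_state()
        s.A[3] = 50.0
        out = sc_model.step(s)
        # switched cells appear at (k = 3, c = 32); the rest regenerated to A_1
        assert out.Omega[3, 32] > 0
        assert out.Omega.sum() == pytest.approx(out.Omega[3, 32])
        assert out.A[1] == pytest.approx(50.0 - out.Omega[3, 32])

    def test_boundary_efflux_composition(self, sc_model):
        k_max = sc_model.grid.k_max
        s = sc_model.empty_state()
        s.Omega[k_max, 48] = 3.0    # daughters leave
        s.Omega[k_max, 40] = 2.0    # progression past the grid
        out = sc_model.step(s)
        assert out.efflux == pytest.approx(2 * 3.0 + 2.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(0.0, 0.9))
    def test_conservation_ledger(self, sc_model, seed, kill):
        """Cell count changes only through divisions, efflux and deaths."""
        rng = np.random.default_rng(seed)
        s = sc_model.empty_state()
        s.A[:] = rng.uniform(0, 1e3, s.A.shape)
        s.Omega[:] = rng.uniform(0, 1e2, s.Omega.shape)
        n_before = s.N_S
        out = sc_model.step(s, ScKill(omega=kill))
        divisions_after_kill = float(s.Omega[:, -1].sum()) * (1 - kill)
        expected = n_before - out.deaths + divisions_after_kill - out.efflux
        assert out.N_S == pytest.approx(expected, rel=1e-12)
        assert out.divisions == pytest.approx(divisions_after_kill, rel=1e-12)


class TestEquilibrium:
    def test_summary_values(self, sc_eq, sc_model):
        mets = sc_metrics(sc_eq, sc_model.params.dt)
        assert mets["relative_efflux"] == pytest.approx(0.003, rel=0.02)
        assert mets["fraction_A"] == pytest.approx(0.82, abs=0.02)
        assert 0.13 <= mets["proliferative_fraction"] <= 0.20

    def test_is_fixed_point(self, sc_eq, sc_model):
        out = sc_model.step(sc_eq)
        assert out.N_A == pytest.approx(sc_eq.N_A, rel=1e-9)
        assert out.N_Omega == pytest.approx(sc_eq.N_Omega, rel=1e-9)
        assert out.efflux == pytest.approx(sc_eq.efflux, rel=1e-8)

    def test_seed_size_does_not_matter(self, sc_model, sc_eq):
        other = sc_model.equilibrium(seed=2e3)
        assert other.N_S == pytest.approx(sc_eq.N_S, rel=1e-6)
        assert other.efflux / other.N_S == pytest.approx(
            sc_eq.efflux / sc_eq.N_S, rel=1e-6)

    def test_equilibrium_attracts_perturbations(self, sc_model, sc_eq):
        s = sc_eq.copy()
        s.A = s.A * 1.5
        s.Omega = s.Omega * 0.5
        for _ in range(30000):
            s = sc_model.step(s)
        assert s.N_A == pytest.approx(sc_eq.N_A, rel=0.01)
        assert s.N_Omega == pytest.approx(sc_eq.N_Omega, rel=0.01)

    def test_extinction_raises(self):
        model = ScModel()
        with pytest.raises(RuntimeError):
            model.equilibrium(seed=0.0, max_steps=5000)


class TestMetrics:
    def test_empty_state_flagged(self, sc_model):
        mets = sc_metrics(sc_model.empty_state())
        assert mets["empty"] == 1.0
        assert mets["proliferative_fraction"] == 0.0

    def test_scaling_homogeneity(self, sc_eq):
        scaled = sc_eq.copy()
        scaled.A = scaled.A * 3.0
        scaled.Omega = scaled.Omega * 3.0
        scaled.efflux = sc_eq.efflux * 3.0
        m1, m3 = sc_metrics(sc_eq), sc_metrics(scaled)
        assert m3["N_S"] == pytest.approx(3 * m1["N_S"])
        for frac in ("fraction_A", "proliferative_fraction",
                     "relative_efflux"):
            assert m3[frac] == pytest.approx(m1[frac], rel=1e-12)


class TestDenseOperatorOracle:
    """With the transition characteristics frozen to constants the update is
    linear; a dense matrix assembled from unit impulses must reproduce the
    engine exactly, and trajectories must scale with initial mass."""

    @staticmethod
    def _small_model():
        params = dataclasses.replace(
            ScParams(), rho=0.5, a_min=math.exp(-5.5 * 0.5), tau_c=4,
            c_mitosis_start=2,
            anchors_A=SigmoidAnchors(0.3, 0.29, 0.28, 0.0, 100.0),
            anchors_O=SigmoidAnchors(0.4, 0.39, 0.38, 0.0, 100.0),
        )
        model = ScModel(params)
        assert model.grid.k_max == 5
        # freeze the capacity feedback: constant characteristics
        model.f_alpha = lambda n: 0.3
        model.f_omega = lambda n: 0.4
        return model

    def _pack(self, state):
        return np.concatenate([state.A, state.Omega.ravel()])

    def _unpack(self, model, vec):
        s = model.empty_state()
        n = model.grid.n
        s.A = vec[:n].copy()
        s.Omega = vec[n:].reshape(n, model.tau_c).copy()
        return s

    def _dense_matrix(self, model):
        dim = model.grid.n * (1 + model.tau_c)
        M = np.zeros((dim, dim))
        for j in range(dim):
            e = np.zeros(dim)
            e[j] = 1.0
            out = model.step(self._unpack(model, e))
            M[:, j] = self._pack(out)
        return M

    def test_matrix_power_matches_engine(self):
        model = self._small_model()
        M = self._dense_matrix(model)
        rng = np.random.default_rng(42)
        vec = rng.uniform(0, 10, M.shape[0])
        state = self._unpack(model, vec)
        for _ in range(25):
            state = model.step(state)
        expected = np.linalg.matrix_power(M, 25) @ vec
        np.testing.assert_allclose(self._pack(state), expected, rtol=1e-10,
                                   atol=1e-12)

    def test_trajectories_scale_with_initial_mass(self):
        model = self._small_model()
        rng = np.random.default_rng(3)
        vec = rng.uniform(0, 10, model.grid.n * (1 + model.tau_c))
        s1 = self._unpack(model, vec)
        s2 = self._unpack(model, 4.0 * vec)
        for _ in range(10):
            s1 = model.step(s1)
            s2 = model.step(s2)
        np.testing.assert_allclose(self._pack(s2), 4.0 * self._pack(s1),
                                   rtol=1e-12)
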