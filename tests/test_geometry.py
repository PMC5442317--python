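import math

import numpy as np
import pytest

from spindlesim.engine import initialize_side_by_side, run_simulation
from spindlesim.fixtures import FixtureSpec, make_fixture
from spindlesim.geometry import (ForceAccumulator, brownian_step,
                                 compute_steric_forces,
                                 compute_tether_forces, compute_wall_force)
from spindlesim.params import (SimulationControl, WallForceParams,
                               build_reference_params)


def _wall_force_oracle(L, wf, r_tip):
    """Independent re-implementation of the wall-force law (plain python)."""
    if wf.asymptotic_force <= 0.0:
        return 0.0
    b = math.sqrt(2.0) * wf.tube_radius
    slope = wf.asymptotic_force / (
        2.0 * wf.tube_radius * (math.log(2.0 * b / r_tip) - wf.euler_gamma))
    linear = slope * L * math.exp(-L / b)
    tube = wf.asymptotic_force * (1.0 + wf.const_a * math.exp(
        -wf.const_c * L / b))
    return linear + (1.0 - math.exp(-L / wf.blend_scale)) * tube


class TestWallForce:
    @pytest.mark.parametrize("fw,rtube", [(1.0, 0.05), (7.4, 0.05),
                                          (14.8, 0.08), (0.3, 0.12)])
    def test_boundary_condition_and_asymptote(self, fw, rtube):
        wf = WallForceParams(asymptotic_force=fw, tube_radius=rtube)
        wf.validate()
        assert compute_wall_force(0.0, wf) == 0.0
        far = compute_wall_force(100.0 * rtube, wf)
        assert abs(far - fw) < 0.01 * fw

    def test_zero_scale(self):
        wf = WallForceParams(asymptotic_force=0.0)
        wf.validate()
        L = np.linspace(0.0, 5.0, 50)
        assert np.all(compute_wall_force(L, wf) == 0.0)

    def test_monotone_approach_beyond_ten_tube_radii(self):
        wf = WallForceParams(asymptotic_force=7.4, tube_radius=0.05)
        wf.validate()
        L = np.linspace(10.0 * wf.tube_radius, 100.0 * wf.tube_radius, 200)
        F = compute_wall_force(L, wf)
        assert np.all(np.diff(F) > 0.0)
        assert np.all(F <= 7.4 * 1.01)

    def test_negative_protrusion_rejected(self):
        wf = WallForceParams(asymptotic_force=1.0)
        wf.validate()
        with pytest.raises(ValueError):
            compute_wall_force(-0.1, wf)

    def test_matches_independent_implementation(self):
        params = build_reference_params()
        params.wall_force.asymptotic_force = 5.0
        params.wall_force.validate()
        r_tip = 0.5 * params.geometry.mt_diameter
        grid = np.linspace(0.0, 3.0, 301)
        ours = compute_wall_force(grid, params)
        oracle = np.array([_wall_force_oracle(L, params.wall_force, r_tip)
                           for L in grid])
        assert np.max(np.abs(ours - oracle)) < 1e-6


class TestTetherForces:
    def test_zero_at_rest(self, reference_params):
        state = initialize_side_by_side(reference_params, seed=0)
        acc = compute_tether_forces(state)
        # pivot mode: minus ends coincide with their sites
        assert np.allclose(acc.mt_force, 0.0)

    def test_hookes_law_on_displaced_minus_end(self):
        state = make_fixture(FixtureSpec("frozen_antiparallel_pair", seed=0))
        k = state.params.geometry.tether_spring_constant
        state.params.geometry.tether_rest_length = 0.0
        sites = state.nucleation_sites()[state.mt_spb, state.mt_site]
        d = 0.07
        state.explicit_minus = sites.copy()
        state.explicit_minus[0, 0] -= d
        acc = compute_tether_forces(state)
        assert acc.mt_force[0, 0] == pytest.approx(k * d, rel=1e-9)
        assert np.allclose(acc.mt_force[1], 0.0)

    def test_newtons_third_law_over_spb_and_mts(self, reference_params, rng):
        state = initialize_side_by_side(reference_params, seed=3)
        sites = state.nucleation_sites()[state.mt_spb, state.mt_site]
        state.explicit_minus = sites + 0.02 * rng.standard_normal(sites.shape)
        acc = compute_tether_forces(state)
        total = acc.mt_force.sum(axis=0) + acc.spb_force.sum(axis=0)
        assert np.allclose(total, 0.0, atol=1e-12)


class TestStericForces:
    def _two_rod_state(self, separation, crossing=True):
        state = make_fixture(FixtureSpec("frozen_antiparallel_pair",
                                         kwargs={"n_crosslinkers": 0}))
        # perpendicular crossing rods: rod 0 along x, rod 1 along y
        state.explicit_minus = np.array([[-0.5, 0.0, 0.0],
                                         [0.0, -0.5, separation]])
        state.mt_u = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        state.mt_len = np.array([1.0, 1.0])
        return state

    def test_out_of_range_pair_has_no_force(self):
        diam = build_reference_params().geometry.mt_diameter
        state = self._two_rod_state(3.0 * diam)
        acc = compute_steric_forces(state)
        assert np.all(acc.mt_force == 0.0)

    def test_perpendicular_crossing_rods_repel_along_common_normal(self):
        params = build_reference_params()
        diam = params.geometry.mt_diameter
        d = 0.8 * diam
        state = self._two_rod_state(d)
        acc = compute_steric_forces(state)
        # equal and opposite, directed along +z/-z (the common normal)
        assert np.allclose(acc.mt_force[0] + acc.mt_force[1], 0.0,
                           atol=1e-12)
        assert acc.mt_force[0][2] < 0.0  # rod 0 sits below rod 1: pushed -z
        assert abs(acc.mt_force[0][0]) < 1e-12
        assert abs(acc.mt_force[0][1]) < 1e-12
        # magnitude matches the capped WCA law at separation d
        eps = state.params.kT
        q6 = (diam / d) ** 6
        expected = min(24.0 * eps * (2.0 * q6 * q6 - q6) / d,
                       params.geometry.steric_cap_force)
        assert np.linalg.norm(acc.mt_force[0]) == pytest.approx(expected,
                                                                rel=1e-9)

    def test_coincident_rods_never_nan(self):
        state = self._two_rod_state(0.0)
        state.mt_u[1] = state.mt_u[0]
        state.explicit_minus[1] = state.explicit_minus[0]
        acc = compute_steric_forces(state)
        assert np.all(np.isfinite(acc.mt_force))
        assert np.linalg.norm(acc.mt_force[0]) > 0.0


class TestBrownianStep:
    def test_no_drivers_leaves_state_unchanged(self, reference_params):
        params = reference_params.copy()
        params.kT = 0.0  # zero temperature
        params.geometry.spb_rotational_diffusion = 0.0
        state = initialize_side_by_side(reference_params, seed=1)
        state.params = params
        before_u = state.mt_u.copy()
        before_spb = state.spb_u.copy()
        acc = ForceAccumulator.zeros(state.n_mts)
        rng = np.random.Generator(np.random.PCG64(0))
        brownian_step(state, acc, 1e-3, rng)
        assert np.array_equal(state.mt_u, before_u)
        assert np.array_equal(state.spb_u, before_spb)

    def test_sphere_constraint_under_forces(self, reference_params, rng):
        state = initialize_side_by_side(reference_params, seed=2)
        R = state.envelope_radius
        for _ in range(200):
            acc = ForceAccumulator.zeros(state.n_mts)
            acc.spb_force[:] = 5.0 * rng.standard_normal((2, 3))
            acc.mt_torque[:] = 0.5 * rng.standard_normal((state.n_mts, 3))
            brownian_step(state, acc, 1e-3, rng)
            radii = np.linalg.norm(state.spb_u * R, axis=1)
            assert np.all(np.abs(radii - R) < 1e-9)
            assert np.allclose(np.linalg.norm(state.mt_u, axis=1), 1.0,
                               atol=1e-9)

    def test_non_finite_force_aborts_with_diagnostic(self, reference_params,
                                                     rng):
        state = initialize_side_by_side(reference_params, seed=2)
        acc = ForceAccumulator.zeros(state.n_mts)
        acc.mt_torque[3, 0] = np.nan
        with pytest.raises(FloatingPointError, match="3"):
            brownian_step(state, acc, 1e-3, rng)


class TestEngineDiffusion:
    """Sampled diffusion of each mobile object matches its input coefficient.

    Runs the full engine with all deterministic forces absent and compares
    mean-squared displacements against the configured coefficients.
    """

    def _bare_state(self, params, n_mts=0, n_xl=0, seed=0):
        state = initialize_side_by_side(params, seed=seed)
        state.mt_u = state.mt_u[:n_mts].copy()
        state.mt_len = state.mt_len[:n_mts].copy()
        state.mt_grow = state.mt_grow[:n_mts].copy()
        state.mt_spb = state.mt_spb[:n_mts].copy()
        state.mt_site = state.mt_site[:n_mts].copy()
        state.xl_state = np.zeros(n_xl, dtype=np.uint8)
        state.xl_pos = state.xl_pos[:n_xl].copy() if n_xl else np.zeros((0, 3))
        state.xl_mt = np.zeros((n_xl, 2), dtype=np.int64)
        state.xl_arc = np.zeros((n_xl, 2))
        return state

    def test_spb_membrane_diffusion_coefficient(self, batch_params):
        params = batch_params.copy()
        params.control.total_time = 2000.0
        params.control.frame_interval = 1.0
        D = params.geometry.spb_diffusion_coefficient
        state = self._bare_state(params, n_mts=0, n_xl=0)
        traj, _ = run_simulation(params, seed=7, state=state)
        pos = traj.spb_positions  # (F, 2, 3)
        msds = []
        for lag in (2, 5, 10):
            dx = pos[lag:] - pos[:-lag]
            msds.append(np.mean(np.sum(dx ** 2, axis=2)) / lag)
        # short-time in-membrane diffusion: MSD = 4 D t
        measured_D = np.mean(msds) / 4.0
        assert measured_D == pytest.approx(D, rel=0.10)

    def test_mt_pivot_rotational_diffusion(self, batch_params):
        params = batch_params.copy()
        # freeze length dynamics at L = 1 um
        params.geometry.initial_mt_length = 1.0
        params.geometry.min_mt_length = 1.0
        params.geometry.max_mt_length = 1.0
        params.geometry.spb_repulsion_constant = 0.0  # pure diffusion
        # inert dynamic instability: a catastrophe would hit the length
        # floor and renucleate, re-pointing the rod at the template
        params.dynamic_instability.catastrophe_frequency = 1e-12
        params.dynamic_instability.rescue_frequency = 1e-12
        params.control.total_time = 120.0
        g = params.geometry
        L = 1.0
        gamma = (4.0 * math.pi * g.viscosity * L ** 3
                 / (3.0 * (math.log(L / g.mt_diameter) + 0.84)))
        D_rot = params.kT / gamma
        state = self._bare_state(params, n_mts=1, n_xl=0)
        # collect many short trajectories of the orientation vector
        us = []
        for rep in range(40):
            st = state.copy()
            traj, _ = run_simulation(params, seed=100 + rep, state=st)
            us.append(st.mt_u[0].copy())
        u0 = state.mt_u[0]
        # angular MSD from independent endpoints is slow; instead use the
        # stationary decay  <u(t).u(0)> = exp(-2 D_rot t)
        dots = np.clip([u @ u0 for u in us], -1.0, 1.0)
        implied = -np.log(np.mean(dots)) / (2.0 * params.control.total_time)
        assert implied == pytest.approx(D_rot, rel=0.35)

    def test_free_crosslinker_diffusion_and_confinement(self, batch_params):
        params = batch_params.copy()
        params.control.total_time = 200.0
        params.crosslinkers.number = 100
        params.crosslinkers.one_head_on_rate = 0.0  # never binds
        state = self._bare_state(params, n_mts=0, n_xl=100, seed=1)
        run_simulation(params, seed=5, state=state)
        assert np.all(np.linalg.norm(state.xl_pos, axis=1)
                      <= state.envelope_radius + 1e-9)
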