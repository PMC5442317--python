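import numpy as np
import pytest

from spindlesim.crosslink import (binding_kmc_step, compute_crosslink_forces,
                                  crosslink_diffusion_step, crosslink_force,
                                  is_antiparallel, pair_partition_weight,
                                  sample_frozen_equilibrium)
from spindlesim.fixtures import FixtureSpec, make_fixture


def _frozen_pair(antiparallel=True, **kwargs):
    name = ("frozen_antiparallel_pair" if antiparallel
            else "frozen_parallel_pair")
    return make_fixture(FixtureSpec(name, seed=2, kwargs=kwargs))


def _slow_rates(state):
    """Binding rates small enough that rate * interval << 1."""
    xl = state.params.crosslinkers
    xl.one_head_on_rate = 180.0
    xl.one_head_off_rate = 0.5
    xl.two_head_on_rate_scale = 90.0
    xl.two_head_off_rate = 0.5
    return state


class TestAntiparallelRule:
    def test_perfectly_antiparallel(self):
        u = np.array([0.3, -0.5, 0.8])
        u /= np.linalg.norm(u)
        assert is_antiparallel(u, -u)

    def test_parallel(self):
        u = np.array([1.0, 0.0, 0.0])
        assert not is_antiparallel(u, u)

    def test_threshold_semantics(self):
        # dot = -0.05 counts as antiparallel under the default threshold 0
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([-0.05, np.sqrt(1 - 0.05 ** 2), 0.0])
        assert float(a @ b) == pytest.approx(-0.05)
        assert is_antiparallel(a, b, threshold=0.0)
        assert not is_antiparallel(a, b, threshold=-0.3)

    def test_parallel_pair_never_doubly_binds(self):
        state = _slow_rates(_frozen_pair(antiparallel=False,
                                         n_crosslinkers=20))
        for i in range(2000):
            binding_kmc_step(state, 0.01, seed=3 if i == 0 else None)
            crosslink_diffusion_step(state, 0.01)
        assert np.all(state.xl_state < 2)
        assert np.any(state.xl_state == 1)  # single-head binding still occurs

    def test_no_crosslinkers_no_events(self):
        state = _frozen_pair(n_crosslinkers=0)
        binding_kmc_step(state, 0.01, seed=1)  # must not raise
        assert state.xl_state.size == 0


class TestCrosslinkForce:
    def _bound_pair(self, arc0, arc1):
        state = _frozen_pair(n_crosslinkers=1)
        state.xl_state[0] = 2
        state.xl_mt[0] = (0, 1)
        state.xl_arc[0] = (arc0, arc1)
        return state

    def test_zero_at_rest_length(self):
        # arcs chosen so head separation equals the rest length exactly
        state = self._bound_pair(0.25, 0.25)
        x0 = state.head_position(0, 0)
        x1 = state.head_position(0, 1)
        assert np.linalg.norm(x1 - x0) == pytest.approx(
            state.params.crosslinkers.rest_length)
        f0, f1, *_ = crosslink_force(state, 0)
        assert np.allclose(f0, 0.0, atol=1e-9)

    def test_hookes_law_attractive_when_stretched(self):
        d = 0.02
        state = self._bound_pair(0.25 - 0.5 * 0.0, 0.25)
        # stretch axially by moving head 0 along its MT
        state.xl_arc[0, 0] = 0.25 + d  # axial offset stretches the spring
        f0, f1, x0, x1 = crosslink_force(state, 0)
        xl = state.params.crosslinkers
        sep = np.linalg.norm(x1 - x0)
        expected = xl.spring_constant * (sep - xl.rest_length)
        assert np.linalg.norm(f0) == pytest.approx(expected, rel=1e-9)
        # attractive: force on head 0 points toward head 1
        assert f0 @ (x1 - x0) > 0.0
        assert np.allclose(f0 + f1, 0.0, atol=1e-12)

    def test_force_and_torque_closure_on_random_states(self):
        state = make_fixture(FixtureSpec("randomized_force_closure", seed=8))
        acc = compute_crosslink_forces(state)
        assert np.allclose(acc.mt_force.sum(axis=0), 0.0, atol=1e-10)
        # total torque about the origin: pivot x F + torque-about-pivot
        minus = state.minus_ends()
        total = np.zeros(3)
        for m in range(state.n_mts):
            total += np.cross(minus[m], acc.mt_force[m]) + acc.mt_torque[m]
        assert np.allclose(total, 0.0, atol=1e-10)

    def test_requires_doubly_bound(self):
        state = _frozen_pair(n_crosslinkers=1)
        with pytest.raises(ValueError):
            crosslink_force(state, 0)


class TestDiffusion:
    def test_free_crosslinker_confined_to_envelope(self):
        state = _frozen_pair(n_crosslinkers=50)
        R = state.envelope_radius
        crosslink_diffusion_step(state, 0.01, seed=4)
        for _ in range(500):
            crosslink_diffusion_step(state, 0.01)
        assert np.all(np.linalg.norm(state.xl_pos, axis=1) <= R + 1e-12)

    def test_single_bound_head_pure_diffusion(self):
        state = _frozen_pair(n_crosslinkers=200, length=4.0,
                             envelope_radius=2.5)
        D = 0.1
        state.params.crosslinkers.bound_diffusion_coefficient = D
        state.xl_state[:] = 1
        state.xl_mt[:, 0] = 0
        state.xl_arc[:, 0] = 2.0  # mid-lattice, away from the clamps
        t = 0.5
        n_steps = 50
        crosslink_diffusion_step(state, t / n_steps, seed=5)
        for _ in range(n_steps - 1):
            crosslink_diffusion_step(state, t / n_steps)
        msd = np.mean((state.xl_arc[:, 0] - 2.0) ** 2)
        assert msd == pytest.approx(2.0 * D * t, rel=0.25)

    def test_stretched_crosslink_relaxes(self):
        state = _frozen_pair(n_crosslinkers=1, length=2.0,
                             envelope_radius=1.5)
        state.params.crosslinkers.bound_diffusion_coefficient = 0.1
        state.xl_state[0] = 2
        state.xl_mt[0] = (0, 1)
        # axially offset heads: strongly stretched spring
        state.xl_arc[0] = (0.6, 0.9)
        x0 = state.head_position(0, 0)
        x1 = state.head_position(0, 1)
        ext0 = np.linalg.norm(x1 - x0)
        exts = []
        crosslink_diffusion_step(state, 2e-3, seed=6)
        for _ in range(400):
            crosslink_diffusion_step(state, 2e-3)
            exts.append(np.linalg.norm(state.head_position(0, 1)
                                       - state.head_position(0, 0)))
        assert np.mean(exts[-100:]) < ext0

    def test_zero_rate_zero_mobility_state_is_frozen(self):
        state = _frozen_pair(n_crosslinkers=10)
        xl = state.params.crosslinkers
        xl.one_head_on_rate = 0.0
        xl.one_head_off_rate = 0.0
        xl.two_head_on_rate_scale = 0.0
        xl.two_head_off_rate = 0.0
        xl.bound_diffusion_coefficient = 0.0
        xl.free_diffusion_coefficient = 0.0
        before = (state.xl_state.copy(), state.xl_pos.copy(),
                  state.xl_arc.copy())
        for _ in range(100):
            binding_kmc_step(state, 0.01, seed=7)
            crosslink_diffusion_step(state, 0.01)
        assert np.array_equal(state.xl_state, before[0])
        assert np.array_equal(state.xl_pos, before[1])
        assert np.array_equal(state.xl_arc, before[2])

    def test_count_conservation(self):
        state = _slow_rates(_frozen_pair(n_crosslinkers=30))
        n = state.n_crosslinkers
        binding_kmc_step(state, 0.01, seed=8)
        for _ in range(1000):
            binding_kmc_step(state, 0.01)
            crosslink_diffusion_step(state, 0.01)
            counts = np.bincount(state.xl_state, minlength=3)
            assert counts.sum() == n
            assert np.all(state.xl_state <= 2)


class TestPartitionWeight:
    def test_zero_beyond_reach(self):
        state = _frozen_pair(separation=0.5)
        head = state.head_position
        state.xl_state[0] = 1
        state.xl_mt[0, 0] = 0
        state.xl_arc[0, 0] = 0.25
        w = pair_partition_weight(head(0, 0), state.minus_ends()[1],
                                  state.mt_u[1], state.mt_len[1],
                                  state.params)
        assert w == 0.0

    def test_matches_direct_integration(self):
        state = _frozen_pair(separation=0.053, length=0.5)
        state.xl_state[0] = 1
        state.xl_mt[0, 0] = 0
        state.xl_arc[0, 0] = 0.25
        head = state.head_position(0, 0)
        params = state.params
        xl = params.crosslinkers
        w = pair_partition_weight(head, state.minus_ends()[1],
                                  state.mt_u[1], state.mt_len[1], params)
        # independent fine-grid integration of the same Boltzmann factor
        t = np.linspace(xl.minus_end_exclusion, state.mt_len[1], 200_001)
        pts = state.minus_ends()[1] + t[:, None] * state.mt_u[1]
        d = np.linalg.norm(pts - head, axis=1)
        integrand = np.exp(-0.5 * xl.spring_constant
                           * (d - xl.rest_length) ** 2 / params.kT)
        oracle = np.trapezoid(integrand, t)
        assert w == pytest.approx(oracle, rel=5e-3)


_N_EQ_SAMPLES = 100_000


@pytest.fixture(scope="module")
def sampled():
    """Long chain of crosslinker states on a frozen antiparallel pair."""
    state = make_fixture(FixtureSpec(
        "frozen_antiparallel_pair", seed=9,
        kwargs={"separation": 0.053, "length": 0.4,
                "envelope_radius": 0.3, "n_crosslinkers": 1}))
    xl = state.params.crosslinkers
    # rates small enough that rate * interval stays well below one
    xl.one_head_on_rate = 60.0
    xl.one_head_off_rate = 0.5
    xl.two_head_on_rate_scale = 60.0
    xl.two_head_off_rate = 0.5
    occ, arcs = sample_frozen_equilibrium(
        state, dt=0.01, n_samples=_N_EQ_SAMPLES, stride=120, seed=11)
    return state, occ, arcs[arcs >= 0.0]


class TestFrozenEquilibrium:
    """Long-run crosslinker statistics on static filaments match the
    Gibbs distribution computed by direct numerical integration."""

    @pytest.fixture()
    def oracle(self, sampled):
        state, _, _ = sampled
        params = state.params
        xl = params.crosslinkers
        kT = params.kT
        R = state.envelope_radius
        lo = xl.minus_end_exclusion
        L = float(state.mt_len[0])
        minus = state.minus_ends()
        u = state.mt_u
        # statistical weights of the kinetic scheme (single crosslinker):
        # free          : Z0 = V(envelope)
        # one head bound: Z1 = chi * (accessible lattice), chi = k_on1 Vc/koff1
        # two heads     : Z2 = Z1-density * (k_on2/koff2) * pair integral
        V = 4.0 / 3.0 * np.pi * R ** 3
        Vc = 4.0 / 3.0 * np.pi * xl.capture_radius ** 3
        chi = xl.one_head_on_rate * Vc / xl.one_head_off_rate
        kappa = (xl.two_head_on_rate_scale
                 * np.exp(xl.characteristic_binding_energy)
                 / xl.two_head_off_rate)
        s = np.linspace(lo, L, 801)
        t = np.linspace(lo, L, 801)
        xs = minus[0] + s[:, None] * u[0]
        xt = minus[1] + t[:, None] * u[1]
        d = np.linalg.norm(xs[:, None, :] - xt[None, :, :], axis=2)
        boltz = np.exp(-0.5 * xl.spring_constant
                       * (d - xl.rest_length) ** 2 / kT)
        pair = np.trapezoid(np.trapezoid(boltz, t, axis=1), s)
        Z0 = V
        Z1 = chi * 2.0 * (L - lo)
        Z2 = chi * kappa * pair
        Ztot = Z0 + Z1 + Z2
        marg = np.trapezoid(boltz, t, axis=1)  # density of the MT-0 head
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (marg[1:] + marg[:-1]) * np.diff(s))])
        cdf /= cdf[-1]
        return np.array([Z0, Z1, Z2]) / Ztot, s, cdf

    def test_occupancy_matches_gibbs_weights(self, sampled, oracle):
        _, occ, _ = sampled
        probs, _, _ = oracle
        frac = occ / occ.sum()
        # correlated time series: compare at the 0.02 scale of the
        # attachment-density criterion rather than iid multinomial error
        assert np.all(np.abs(frac - probs) < 0.02)

    def test_attachment_position_density_matches_boltzmann(self, sampled,
                                                           oracle):
        _, _, arcs = sampled
        _, s, cdf = oracle
        assert arcs.size > 5000
        emp = np.sort(arcs)
        model_cdf = np.interp(emp, s, cdf)
        ks = np.max(np.abs(model_cdf - (np.arange(emp.size) + 1.0)
                           / emp.size))
        assert ks < 0.02
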