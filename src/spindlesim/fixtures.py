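"""Programmatic test fixtures: hand-constructed states and IF series.

Every scenario is deterministic given its parameters and seed and is built
without running any simulation.  Frozen scenarios set all mobilities to
zero so binding-kinetics oracles see static filaments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import initialize_side_by_side
from .geometry import SystemState
from .params import SimulationParameters, build_reference_params

SCENARIOS = ("frozen_antiparallel_pair", "frozen_parallel_pair",
             "single_mt_ensemble", "engineered_if_series",
             "randomized_force_closure")


@dataclass
class FixtureSpec:
    """A named fixture scenario with its parameters."""

    scenario: str
    seed: int = 0
    kwargs: dict = field(default_factory=dict)


def _frozen_pair(antiparallel: bool, separation: float, length: float,
                 n_crosslinkers: int, envelope_radius: float,
                 params: SimulationParameters, seed: int) -> SystemState:
    """Two static MTs at the given axis separation, centred in a sphere."""
    if params is None:
        params = build_reference_params()
    params = params.copy()
    params.geometry.envelope_diameter = 2.0 * envelope_radius
    params.crosslinkers.number = n_crosslinkers
    # static filaments: zero every mobility of the frozen objects so the
    # binding-kinetics oracles see exactly static lattices
    params.geometry.spb_diffusion_coefficient = 1e-30
    params.geometry.spb_rotational_diffusion = 0.0
    params.crosslinkers.bound_diffusion_coefficient = 0.0
    params.validate()
    rng = np.random.Generator(np.random.PCG64(seed))
    minus = np.array([
        [-0.5 * length, -0.5 * separation, 0.0],
        [0.5 * length if antiparallel else -0.5 * length,
         0.5 * separation, 0.0]])
    mt_u = np.array([[1.0, 0.0, 0.0],
                     [-1.0, 0.0, 0.0] if antiparallel else [1.0, 0.0, 0.0]])
    n = n_crosslinkers
    pos = rng.standard_normal((n, 3))
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    pos *= envelope_radius * rng.random(n)[:, None] ** (1.0 / 3.0)
    return SystemState(
        params=params, time=0.0,
        spb_u=np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]),
        spb_phi=np.zeros(2),
        mt_u=mt_u, mt_len=np.full(2, float(length)),
        mt_grow=np.ones(2, dtype=np.uint8),
        mt_spb=np.array([0, 1]), mt_site=np.array([0, 0]),
        xl_state=np.zeros(n, dtype=np.uint8), xl_pos=pos,
        xl_mt=np.zeros((n, 2), dtype=np.int64), xl_arc=np.zeros((n, 2)),
        explicit_minus=minus, frozen=True)


def make_fixture(spec: FixtureSpec):
    """Build the requested scenario; returns a SystemState or an array."""
    kw = dict(spec.kwargs)
    if spec.scenario == "frozen_antiparallel_pair":
        return _frozen_pair(True, kw.pop("separation", 0.053),
                            kw.pop("length", 0.5),
                            kw.pop("n_crosslinkers", 1),
                            kw.pop("envelope_radius", 0.4),
                            kw.pop("params", None), spec.seed)
    if spec.scenario == "frozen_parallel_pair":
        return _frozen_pair(False, kw.pop("separation", 0.053),
                            kw.pop("length", 0.5),
                            kw.pop("n_crosslinkers", 1),
                            kw.pop("envelope_radius", 0.4),
                            kw.pop("params", None), spec.seed)
    if spec.scenario == "single_mt_ensemble":
        # the ensemble itself is event-driven; the fixture supplies its spec
        params = kw.pop("params", None) or build_reference_params()
        return {"di": params.dynamic_instability,
                "n_mt": kw.pop("n_mt", 500),
                "t_total": kw.pop("t_total", 1.0e4),
                "seed": spec.seed}
    if spec.scenario == "engineered_if_series":
        total = kw.pop("total_time", 600.0)
        fi = kw.pop("frame_interval", 1.0)
        start = kw.pop("start_time", 300.0)
        plateau = kw.pop("plateau", 0.5)
        dip = kw.pop("dip", 0.0)           # dip duration, s
        dip_at = kw.pop("dip_at", 400.0)
        dip_value = kw.pop("dip_value", 0.1)
        t = np.arange(0.0, total + 0.5 * fi, fi)
        f = np.where(t >= start, plateau, 0.0)
        if dip > 0.0:
            f[(t >= dip_at) & (t < dip_at + dip)] = dip_value
        return f
    if spec.scenario == "randomized_force_closure":
        params = kw.pop("params", None) or build_reference_params()
        state = initialize_side_by_side(params, spec.seed)
        rng = np.random.Generator(np.random.PCG64(spec.seed + 1))
        state.mt_len[:] = rng.uniform(0.3, 1.2, size=state.n_mts)
        u = rng.standard_normal((state.n_mts, 3))  # isotropic orientations
        state.mt_u = u / np.linalg.norm(u, axis=1, keepdims=True)
        # bind a handful of crosslinkers across antiparallel pairs
        n_bound = kw.pop("n_bound", 10)
        bound = 0
        for i in range(state.n_crosslinkers):
            if bound >= n_bound:
                break
            a = rng.integers(0, state.n_mts)
            b = rng.integers(0, state.n_mts)
            if a == b or state.mt_u[a] @ state.mt_u[b] >= 0.0:
                continue
            state.xl_state[i] = 2
            state.xl_mt[i] = (a, b)
            state.xl_arc[i, 0] = rng.uniform(0.0, state.mt_len[a])
            state.xl_arc[i, 1] = rng.uniform(0.0, state.mt_len[b])
            bound += 1
        return state
    raise ValueError(f"unknown fixture scenario {spec.scenario!r}; "
                     f"known: {SCENARIOS}")
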