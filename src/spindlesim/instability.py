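"""Dynamic instability: switching, force-dependent growth, stabilization.

MT plus ends switch stochastically between growth and shrinkage with the
four-parameter model (growth speed v_g, shrinking speed v_s, catastrophe
frequency f_c, rescue frequency f_r).  A crosslink bound within the
stabilization length of a plus end rescales that MT's parameters toward
stability, modelling CLASP-family rescue factors recruited by the
crosslinker.  Growth against a compressive tip load follows the shared-load
multi-filament Brownian ratchet for a 13-protofilament lattice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .params import (DynamicInstabilityParams, RatchetParams,
                     StabilizationFactors)


@dataclass(frozen=True)
class EffectiveDIParams:
    """The four DI parameters after stabilization scaling."""

    growth_speed: float
    shrinking_speed: float
    catastrophe_frequency: float
    rescue_frequency: float

    @classmethod
    def from_base(cls, base: DynamicInstabilityParams) -> "EffectiveDIParams":
        return cls(base.growth_speed, base.shrinking_speed,
                   base.catastrophe_frequency, base.rescue_frequency)


def stabilization_scaling(mt_length: float, crosslink_arcs,
                          base: DynamicInstabilityParams,
                          factors: StabilizationFactors,
                          enabled: bool = True) -> EffectiveDIParams:
    """Effective DI parameters for one MT given its bound crosslink arcs.

    If stabilization is enabled and any doubly bound crosslink head lies
    within the stabilization length of the plus end (arc distance
    ``mt_length - arc <= s``), all four parameters are rescaled toward
    stability: f_c / s_fc, f_r * s_fr, v_g * s_vg, v_s / s_vs.  Multiple
    nearby crosslinks do not stack (the factors saturate).  Otherwise the
    base parameters are returned unchanged.
    """
    arcs = np.asarray(crosslink_arcs, dtype=float)
    if arcs.size and (np.any(arcs < -1e-9) or np.any(arcs > mt_length + 1e-9)):
        raise ValueError("crosslink arc coordinate outside [0, L]")
    stabilized = (enabled and arcs.size > 0
                  and bool(np.any(mt_length - arcs <= factors.stabilization_length)))
    if not stabilized:
        return EffectiveDIParams.from_base(base)
    return EffectiveDIParams(
        growth_speed=base.growth_speed * factors.growth_factor,
        shrinking_speed=base.shrinking_speed / factors.shrink_factor,
        catastrophe_frequency=base.catastrophe_frequency / factors.catastrophe_factor,
        rescue_frequency=base.rescue_frequency * factors.rescue_factor)


def di_switch_step(growing: bool, eff: EffectiveDIParams, dt: float,
                   rng: np.random.Generator) -> bool:
    """One kinetic Monte Carlo switching draw; returns the new state.

    Growing plus ends undergo catastrophe with probability 1 - e^(-f_c dt),
    shrinking ends are rescued with probability 1 - e^(-f_r dt); exactly one
    Bernoulli draw is consumed per call.
    """
    rate = eff.catastrophe_frequency if growing else eff.rescue_frequency
    if rate * dt > 0.1:
        import warnings
        warnings.warn(f"switching rate * dt = {rate * dt:.3g} > 0.1; "
                      "timestep too coarse for accurate kinetics",
                      RuntimeWarning, stacklevel=2)
    if rng.random() < 1.0 - math.exp(-rate * dt):
        return not growing
    return growing


def force_dependent_growth_speed(F: float, eff: EffectiveDIParams,
                                 ratchet: RatchetParams) -> float:
    """Growth speed (um/s) under a compressive axial tip load F (pN).

    Shared-load Brownian ratchet for N = 13 protofilaments, each subunit
    addition advancing the tip by sigma = 8/13 nm against the load:
    v(F) = v_g (alpha e^-beta - 1)/(alpha - 1) with alpha = e^(F_s sigma/kT)
    and beta = F sigma/kT, so v(0) = v_g, v is strictly decreasing in F and
    stalls at F = F_s (clamped at zero beyond stall).
    """
    if F < 0.0:
        raise ValueError("compressive load must be >= 0 (tension clamps to 0)")
    return eff.growth_speed * K.ratchet_speed_factor(
        F, ratchet.stall_scale, ratchet.subunit_increment,
        ratchet.thermal_energy)


def update_mt_length(length: float, growing: bool, eff: EffectiveDIParams,
                     v_growth_effective: float, dt: float,
                     min_length: float = 0.1) -> tuple[float, bool]:
    """Advance one MT's length over dt; returns (new_length, new_growing).

    Growth uses the (possibly load-reduced) effective growth speed;
    shrinkage uses the effective shrinking speed; a shrinking MT hitting the
    minimum length renucleates: it is floored there and switched to growth.
    """
    if growing:
        return length + v_growth_effective * dt, True
    length -= eff.shrinking_speed * dt
    if length <= min_length:
        return min_length, True
    return length, False


def simulate_single_mt_ensemble(di: DynamicInstabilityParams, n_mt: int,
                                t_total: float, seed: int,
                                burn_in: float = 500.0,
                                initial_length: float = 0.1,
                                min_length: float = 0.0) -> float:
    """Ensemble/time-averaged length of isolated dynamic MTs (um).

    Event-driven simulation of ``n_mt`` independent plus ends with no
    forces and no boundary; shrinkage renucleates at ``min_length`` (zero by
    default, matching the classic bounded-growth boundary condition whose
    stationary mean is v_g v_s / (f_c v_s - f_r v_g)).
    """
    return float(K.di_ensemble_mean_length(
        seed, n_mt, t_total, burn_in, di.growth_speed, di.shrinking_speed,
        di.catastrophe_frequency, di.rescue_frequency, initial_length,
        min_length))


def simulate_protofilament_ratchet(F: float, ratchet: RatchetParams,
                                   v_g: float, n_events: int,
                                   seed: int) -> float:
    """Stochastic 13-protofilament ratchet tip speed at load F (um/s).

    Independent oracle for :func:`force_dependent_growth_speed`: Gillespie
    simulation of subunit addition/loss events with ratchet-gated on-rates.
    """
    return float(K.ratchet_gillespie_speed(
        seed, n_events, F, ratchet.stall_scale, ratchet.subunit_increment,
        ratchet.thermal_energy, v_g))
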