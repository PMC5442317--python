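"""Crosslinker binding kinetics, spring forces and bound-head diffusion.

Crosslinkers (Ase1/PRC1-like) have two heads and three states: free,
one head bound, two heads bound.  Double binding is restricted to strictly
antiparallel MT pairs.  The one-to-two-head transition rate integrates the
Boltzmann factor of the spring stretch energy along each candidate partner
(the filament-pair partition function), and the landing position is drawn
from that density, so that static filaments recover the exact equilibrium
distribution of bound crosslinkers.  Doubly bound crosslinkers act as
harmonic springs between their attachment points.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K
from .geometry import ForceAccumulator, SystemState


def is_antiparallel(u_a, u_b, threshold: float = 0.0) -> bool:
    """True iff the orientations' dot product is below ``threshold``."""
    return float(np.dot(u_a, u_b)) < threshold


def pair_partition_weight(head_pos, minus, u, length, params,
                          kT: float = None) -> float:
    """Integral over one candidate MT of the spring-stretch Boltzmann factor.

    ``head_pos`` is the anchored head's position; the integral
    int_0^L exp(-k (d(t) - r0)^2 / 2 kT) dt is evaluated with the
    configured quadrature bin width over the arc window where the energy is
    below ~12 kT (zero outside).  Units: um.
    """
    xl = getattr(params, "crosslinkers", params)
    if kT is None:
        kT = getattr(params, "kT", 4.11e-3)
    head_pos = np.asarray(head_pos, dtype=float)
    minus = np.asarray(minus, dtype=float)
    u = np.asarray(u, dtype=float)
    k, r0 = xl.spring_constant, xl.rest_length
    dE = np.sqrt(24.0 * kT / k) if k > 0 else xl.capture_radius
    reach = r0 + dE
    w = head_pos - minus
    tc = float(w @ u)
    dperp2 = max(float(w @ w) - tc * tc, 0.0)
    if dperp2 >= reach * reach:
        return 0.0
    h = np.sqrt(reach * reach - dperp2)
    lo, hi = max(xl.minus_end_exclusion, tc - h), min(float(length), tc + h)
    if hi <= lo:
        return 0.0
    nb = int((hi - lo) / xl.partition_bin_width) + 1
    t = lo + (np.arange(nb) + 0.5) * (hi - lo) / nb
    pts = minus[None, :] + t[:, None] * u[None, :]
    d = np.linalg.norm(pts - head_pos[None, :], axis=1)
    return float(np.sum(np.exp(-0.5 * k * (d - r0) ** 2 / kT))
                 * (hi - lo) / nb)


def binding_kmc_step(state: SystemState, dt: float, seed: int = None) -> None:
    """One kinetic Monte Carlo binding/unbinding interval (in place).

    At most one transition per crosslinker per interval; transition
    probabilities are 1 - e^(-rate dt).  Pass ``seed`` to (re)seed the
    kernel RNG; omit it to continue the current stream.
    """
    if seed is not None:
        K.seed_kernel_rng(seed)
    P = K.pack_params(state.params)
    K.kmc_crosslinkers(P, state.minus_ends(), state.mt_u, state.mt_len,
                       state.xl_state, state.xl_pos, state.xl_mt,
                       state.xl_arc, dt)


def crosslink_diffusion_step(state: SystemState, dt: float,
                             seed: int = None) -> None:
    """Diffusive crosslinker motion over one interval (in place).

    Free crosslinkers diffuse in 3-D confined to the envelope interior;
    singly bound heads diffuse along their MT; doubly bound heads drift
    down the axial spring force with an Ornstein-Uhlenbeck update and are
    clamped at the MT ends.
    """
    if seed is not None:
        K.seed_kernel_rng(seed)
    P = K.pack_params(state.params)
    K.xl_diffusion(P, state.minus_ends(), state.mt_u, state.mt_len,
                   state.xl_state, state.xl_pos, state.xl_mt, state.xl_arc,
                   dt)


def crosslink_force(state: SystemState, xl_index: int):
    """Force pair (on head-0's MT, on head-1's MT) of one doubly bound link.

    Magnitude k (extension - rest length) along the head-to-head vector;
    equal and opposite.  Returns (f0, f1, x0, x1) with application points.
    """
    if state.xl_state[xl_index] != 2:
        raise ValueError(f"crosslinker {xl_index} is not doubly bound")
    xl = state.params.crosslinkers
    x0 = state.head_position(xl_index, 0)
    x1 = state.head_position(xl_index, 1)
    dvec = x1 - x0
    d = float(np.linalg.norm(dvec))
    if d < 1e-12:
        z = np.zeros(3)
        return z, z, x0, x1
    f0 = xl.spring_constant * (d - xl.rest_length) * dvec / d
    return f0, -f0, x0, x1


def compute_crosslink_forces(state: SystemState) -> ForceAccumulator:
    """Spring forces and pivot torques from all doubly bound crosslinkers."""
    acc = ForceAccumulator.zeros(state.n_mts)
    for i in np.nonzero(state.xl_state == 2)[0]:
        f0, f1, x0, x1 = crosslink_force(state, int(i))
        m0, m1 = state.xl_mt[i]
        acc.mt_force[m0] += f0
        acc.mt_force[m1] += f1
        acc.mt_torque[m0] += state.xl_arc[i, 0] * np.cross(state.mt_u[m0], f0)
        acc.mt_torque[m1] += state.xl_arc[i, 1] * np.cross(state.mt_u[m1], f1)
        acc.spb_force[state.mt_spb[m0]] += f0
        acc.spb_force[state.mt_spb[m1]] += f1
    return acc


def sample_frozen_equilibrium(state: SystemState, dt: float, n_samples: int,
                              stride: int, seed: int):
    """Long-run occupancy and attachment-position sampling on frozen MTs.

    Runs ``n_samples * stride`` kMC+diffusion intervals on a static-filament
    state, recording every ``stride``-th interval.  Returns
    ``(occupancy_counts[3], arc_samples)`` where ``arc_samples`` holds, for
    doubly bound samples, the arc coordinate of the head attached to MT 0
    (-1 where not doubly bound).
    """
    P = K.pack_params(state.params)
    occ = np.zeros(3, dtype=np.int64)
    arcs = np.empty(n_samples)
    K.equilibrium_sampler(P, state.minus_ends(), state.mt_u, state.mt_len,
                          state.xl_state, state.xl_pos, state.xl_mt,
                          state.xl_arc, dt, n_samples, stride, seed, occ,
                          arcs)
    return occ, arcs
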