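"""System state, nuclear-envelope geometry and deterministic mechanics.

The nuclear envelope is a fixed sphere.  Spindle pole bodies (SPBs) are thin
disks living in the envelope, described by their outward unit normal (their
centre is ``R * u``) and an in-plane rotation angle; each carries a ring of
MT nucleation sites.  Microtubules are rigid rods whose minus ends pivot at
their nucleation site (the tether is a pivot constraint; the harmonic-tether
force law is available through :func:`compute_tether_forces` for states with
explicitly placed minus ends, e.g. frozen test fixtures).

Forces are collected in a :class:`ForceAccumulator`: net force and torque
about the pivot per MT, net force per SPB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .params import SimulationParameters


@dataclass
class SystemState:
    """Full configuration of the system at one time point."""

    params: SimulationParameters
    time: float
    spb_u: np.ndarray       # (2, 3) outward unit normals
    spb_phi: np.ndarray     # (2,) in-plane angles
    mt_u: np.ndarray        # (M, 3) unit orientations (minus -> plus)
    mt_len: np.ndarray      # (M,) lengths, um
    mt_grow: np.ndarray     # (M,) uint8: 1 growing, 0 shrinking
    mt_spb: np.ndarray      # (M,) parent SPB index
    mt_site: np.ndarray     # (M,) nucleation-site index
    xl_state: np.ndarray    # (N,) uint8: 0 free, 1 one-bound, 2 two-bound
    xl_pos: np.ndarray      # (N, 3) positions of free crosslinkers
    xl_mt: np.ndarray       # (N, 2) attached MT ids per head
    xl_arc: np.ndarray      # (N, 2) arc coordinate of each head, um
    explicit_minus: np.ndarray | None = None  # (M, 3) override (fixtures)
    frozen: bool = False    # fixture flag: filaments held static

    # -- geometry helpers ---------------------------------------------------

    @property
    def n_mts(self) -> int:
        return self.mt_len.shape[0]

    @property
    def n_crosslinkers(self) -> int:
        return self.xl_state.shape[0]

    @property
    def envelope_radius(self) -> float:
        return 0.5 * self.params.geometry.envelope_diameter

    def spb_positions(self) -> np.ndarray:
        return self.envelope_radius * self.spb_u

    def spb_separation(self) -> float:
        p = self.spb_positions()
        return float(np.linalg.norm(p[0] - p[1]))

    def nucleation_sites(self) -> np.ndarray:
        g = self.params.geometry
        out = np.empty((2, g.sites_per_spb, 3))
        K.site_positions(self.spb_u, self.spb_phi, self.envelope_radius,
                         0.5 * g.spb_diameter, g.sites_per_spb, out)
        return out

    def minus_ends(self) -> np.ndarray:
        if self.explicit_minus is not None:
            return self.explicit_minus
        sites = self.nucleation_sites()
        return sites[self.mt_spb, self.mt_site]

    def plus_ends(self) -> np.ndarray:
        return self.minus_ends() + self.mt_len[:, None] * self.mt_u

    def head_position(self, xl_index: int, head: int) -> np.ndarray:
        m = self.xl_mt[xl_index, head]
        return (self.minus_ends()[m]
                + self.xl_arc[xl_index, head] * self.mt_u[m])

    def copy(self) -> "SystemState":
        return SystemState(
            params=self.params.copy(), time=self.time,
            spb_u=self.spb_u.copy(), spb_phi=self.spb_phi.copy(),
            mt_u=self.mt_u.copy(), mt_len=self.mt_len.copy(),
            mt_grow=self.mt_grow.copy(), mt_spb=self.mt_spb.copy(),
            mt_site=self.mt_site.copy(), xl_state=self.xl_state.copy(),
            xl_pos=self.xl_pos.copy(), xl_mt=self.xl_mt.copy(),
            xl_arc=self.xl_arc.copy(),
            explicit_minus=None if self.explicit_minus is None
            else self.explicit_minus.copy(),
            frozen=self.frozen)


@dataclass
class ForceAccumulator:
    """Per-step force/torque buffers (pN, pN um)."""

    mt_force: np.ndarray    # (M, 3) net force on each MT
    mt_torque: np.ndarray   # (M, 3) torque about the minus-end pivot
    spb_force: np.ndarray   # (2, 3)
    mt_axial_load: np.ndarray = field(default=None)  # (M,) compressive tip load

    @classmethod
    def zeros(cls, n_mts: int) -> "ForceAccumulator":
        return cls(mt_force=np.zeros((n_mts, 3)),
                   mt_torque=np.zeros((n_mts, 3)),
                   spb_force=np.zeros((2, 3)),
                   mt_axial_load=np.zeros(n_mts))

    def __iadd__(self, other: "ForceAccumulator") -> "ForceAccumulator":
        self.mt_force += other.mt_force
        self.mt_torque += other.mt_torque
        self.spb_force += other.spb_force
        self.mt_axial_load += other.mt_axial_load
        return self


class InternalConsistencyError(RuntimeError):
    """The state violates a structural invariant (e.g. an orphan MT)."""


# ---------------------------------------------------------------------------
# deterministic forces
# ---------------------------------------------------------------------------

def compute_tether_forces(state: SystemState) -> ForceAccumulator:
    """Harmonic minus-end tether forces toward each nucleation site.

    Zero when the minus-end/site separation equals the tether rest length
    (identically zero in the default pivot mode, where minus ends coincide
    with their sites).  The reaction acts on the parent SPB, so tether
    forces sum to zero over each SPB plus its MTs.
    """
    g = state.params.geometry
    acc = ForceAccumulator.zeros(state.n_mts)
    if np.any(state.mt_spb < 0) or np.any(state.mt_spb > 1):
        raise InternalConsistencyError("MT with invalid parent SPB id")
    sites = state.nucleation_sites()[state.mt_spb, state.mt_site]
    minus = state.minus_ends()
    dvec = sites - minus
    dist = np.linalg.norm(dvec, axis=1)
    for m in range(state.n_mts):
        if dist[m] < 1e-12:
            continue
        fmag = g.tether_spring_constant * (dist[m] - g.tether_rest_length)
        f = fmag * dvec[m] / dist[m]
        acc.mt_force[m] += f
        acc.spb_force[state.mt_spb[m]] -= f
    return acc


def compute_steric_forces(state: SystemState) -> ForceAccumulator:
    """Capped WCA repulsion between every MT pair closer than the cutoff.

    Forces act along the minimum-distance vector at the closest points,
    are equal and opposite, and are finite everywhere (coincident rods are
    separated by a deterministic tie-break direction).
    """
    g = state.params.geometry
    acc = ForceAccumulator.zeros(state.n_mts)
    minus = state.minus_ends()
    u = state.mt_u
    L = state.mt_len
    eps = state.params.kT
    diam = g.mt_diameter
    for a in range(state.n_mts):
        for b in range(a + 1, state.n_mts):
            s, t, dx, dy, dz, dist = K._seg_closest(
                minus[a, 0], minus[a, 1], minus[a, 2],
                u[a, 0], u[a, 1], u[a, 2], L[a],
                minus[b, 0], minus[b, 1], minus[b, 2],
                u[b, 0], u[b, 1], u[b, 2], L[b])
            if dist >= 1.1224620483093730 * diam:
                continue
            if dist < 1e-8:
                n = np.cross(u[a], [1.0, 0.0, 0.0])
                if np.linalg.norm(n) < 1e-6:
                    n = np.cross(u[a], [0.0, 1.0, 0.0])
                n /= np.linalg.norm(n)
                dist = 1e-8
            else:
                n = np.array([dx, dy, dz]) / dist
            fmag = K._wca_force_mag(dist, diam, eps, g.steric_cap_force)
            if fmag <= 0.0:
                continue
            f = fmag * n
            acc.mt_force[a] += f
            acc.mt_force[b] -= f
            acc.mt_torque[a] += s * np.cross(u[a], f)
            acc.mt_torque[b] -= t * np.cross(u[b], f)
            acc.spb_force[state.mt_spb[a]] += f
            acc.spb_force[state.mt_spb[b]] -= f
    return acc


def compute_wall_force(L, params) -> np.ndarray | float:
    """Inward envelope force (pN) on a plus tip protruding ``L`` (um).

    F(0) = 0 exactly; F -> asymptotic_force as L -> infinity.  ``params``
    may be a WallForceParams or full SimulationParameters.  ``L`` may be a
    scalar or array; negative protrusions raise ``ValueError``.
    """
    wf = getattr(params, "wall_force", params)
    r_tip = 0.0125
    if hasattr(params, "geometry"):
        r_tip = 0.5 * params.geometry.mt_diameter
    arr = np.asarray(L, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError("protrusion distance must be >= 0")
    out = np.empty(arr.shape)
    flat = arr.ravel()
    oflat = out.ravel()
    for i in range(flat.size):
        oflat[i] = K.wall_force_scalar(
            flat[i], wf.asymptotic_force, wf.tube_radius, wf.const_b,
            wf.euler_gamma, wf.const_a, wf.const_c, wf.blend_scale, r_tip)
    return float(out) if np.isscalar(L) or arr.ndim == 0 else out


def compute_forces(state: SystemState) -> ForceAccumulator:
    """All deterministic forces of the model (tether/steric/wall/crosslink)."""
    from .crosslink import compute_crosslink_forces
    acc = compute_steric_forces(state)
    acc += compute_crosslink_forces(state)
    if state.explicit_minus is not None:
        acc += compute_tether_forces(state)
    wf = state.params.wall_force
    if wf.asymptotic_force > 0.0:
        plus = state.plus_ends()
        r = np.linalg.norm(plus, axis=1)
        prot = r - state.envelope_radius
        for m in np.nonzero(prot > 0.0)[0]:
            fmag = compute_wall_force(float(prot[m]), state.params)
            f = -fmag * plus[m] / r[m]
            acc.mt_force[m] += f
            acc.mt_torque[m] += state.mt_len[m] * np.cross(state.mt_u[m], f)
            acc.spb_force[state.mt_spb[m]] += f
            comp = -float(f @ state.mt_u[m])
            if comp > 0.0:
                acc.mt_axial_load[m] += comp
    return acc


# ---------------------------------------------------------------------------
# Brownian move (single step, explicit-python mirror of the engine move)
# ---------------------------------------------------------------------------

def _rod_rotational_drag(L: float, diam: float, eta: float) -> float:
    """Slender-body drag coefficient for pivoting about the minus end."""
    return 4.0 * math.pi * eta * L ** 3 / (3.0 * (math.log(L / diam) + 0.84))


def _rod_translational_drag(L: float, diam: float, eta: float) -> float:
    """Orientation-averaged slender-body translational drag."""
    lp = math.log(L / diam)
    gpar = 2.0 * math.pi * eta * L / max(lp - 0.2, 0.1)
    gper = 4.0 * math.pi * eta * L / (lp + 0.84)
    return (gpar + 2.0 * gper) / 3.0


def _tangent_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def brownian_step(state: SystemState, forces: ForceAccumulator, dt: float,
                  rng: np.random.Generator) -> SystemState:
    """One overdamped Brownian-dynamics move (in place; returns the state).

    MTs pivot about their nucleation sites with length-dependent slender-body
    rotational mobility; SPBs take tangent-plane steps (driven by the net
    force on themselves plus their aster, with the aster's drag added) and
    are reprojected onto the envelope sphere; SPB frames diffuse in-plane.
    Noise variance follows fluctuation-dissipation, 2 kT/drag per DOF.
    """
    if not np.all(np.isfinite(forces.mt_torque)) or not np.all(
            np.isfinite(forces.spb_force)):
        bad = np.nonzero(~np.isfinite(forces.mt_torque).all(axis=1))[0]
        raise FloatingPointError(
            f"non-finite force/torque on MT(s) {bad.tolist()} at "
            f"t={state.time:.6f}")
    g = state.params.geometry
    kT = state.params.kT
    R = state.envelope_radius
    for m in range(state.n_mts):
        if state.frozen:
            break
        gam = _rod_rotational_drag(state.mt_len[m], g.mt_diameter, g.viscosity)
        u = state.mt_u[m]
        tq = forces.mt_torque[m]
        w = (tq - (tq @ u) * u) / gam * dt
        e1, e2 = _tangent_basis(u)
        sn = math.sqrt(2.0 * kT / gam * dt)
        w = w + sn * rng.standard_normal() * e1 + sn * rng.standard_normal() * e2
        wmag = np.linalg.norm(w)
        if wmag == 0.0:
            continue
        if wmag > 0.3:
            w *= 0.3 / wmag
        u = u + np.cross(w, u)
        state.mt_u[m] = u / np.linalg.norm(u)
    if not state.frozen:
        for i in range(2):
            gtot = kT / g.spb_diffusion_coefficient
            for m in range(state.n_mts):
                if state.mt_spb[m] == i:
                    gtot += _rod_translational_drag(
                        state.mt_len[m], g.mt_diameter, g.viscosity)
            u = state.spb_u[i]
            f = forces.spb_force[i]
            ft = f - (f @ u) * u
            e1, e2 = _tangent_basis(u)
            sn = math.sqrt(2.0 * kT / gtot * dt)
            step = (ft / gtot * dt + sn * rng.standard_normal() * e1
                    + sn * rng.standard_normal() * e2)
            if np.any(step != 0.0):
                u = u + step / R
                state.spb_u[i] = u / np.linalg.norm(u)
            state.spb_phi[i] += math.sqrt(
                2.0 * g.spb_rotational_diffusion * dt) * rng.standard_normal()
    state.time += dt
    return state
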