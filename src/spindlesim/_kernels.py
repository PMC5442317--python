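"""Numba kernels: vector geometry, force laws, kMC updates and the engine loop.

Everything here operates on flat numpy arrays; the public modules wrap these
kernels with the documented object interfaces.  All stochastic kernels draw
from numba's internal np.random state, which is seeded explicitly by the
callers through :func:`seed_kernel_rng` (or by the engine loop itself), so
that every run is bitwise reproducible from its seed.

Parameter packing: the full :class:`~spindlesim.params.SimulationParameters`
object is flattened into a float64 vector ``P`` indexed by the ``IP_*``
constants below before entering compiled code.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# parameter vector layout
# ---------------------------------------------------------------------------

(IP_RENV, IP_RSPB, IP_DSPB, IP_DSPBROT, IP_MTDIAM, IP_LMIN, IP_LMAX,
 IP_ETA, IP_FCAP, IP_KSPBREP, IP_KT,
 IP_VG, IP_VS, IP_FC, IP_FR,
 IP_SVG, IP_SVS, IP_SFC, IP_SFR, IP_SLEN,
 IP_XLK, IP_XLR0, IP_K1ON, IP_K1OFF, IP_K2ON, IP_K2OFF,
 IP_DBOUND, IP_DFREE, IP_APTHRESH, IP_EBIND, IP_RCAP, IP_BELL, IP_BINW,
 IP_FW, IP_RTUBE, IP_WGAMMA, IP_WA, IP_WC, IP_WBLEND, IP_WB,
 IP_SIGMA, IP_FSTALL,
 IP_DT, IP_KMCI, IP_STAB, IP_RATCHET, IP_TILT, IP_MEXCL,
 NP_PARAMS) = range(49)


def pack_params(sp) -> np.ndarray:
    """Flatten a SimulationParameters object into the kernel vector."""
    g, di, st = sp.geometry, sp.dynamic_instability, sp.stabilization
    xl, wf, rt, ct = sp.crosslinkers, sp.wall_force, sp.ratchet, sp.control
    P = np.zeros(NP_PARAMS)
    P[IP_RENV] = 0.5 * g.envelope_diameter
    P[IP_RSPB] = 0.5 * g.spb_diameter
    P[IP_DSPB] = g.spb_diffusion_coefficient
    P[IP_DSPBROT] = g.spb_rotational_diffusion
    P[IP_MTDIAM] = g.mt_diameter
    P[IP_LMIN] = g.min_mt_length
    P[IP_LMAX] = g.max_mt_length
    P[IP_ETA] = g.viscosity
    P[IP_FCAP] = g.steric_cap_force
    P[IP_KSPBREP] = g.spb_repulsion_constant
    P[IP_KT] = sp.kT
    P[IP_VG] = di.growth_speed
    P[IP_VS] = di.shrinking_speed
    P[IP_FC] = di.catastrophe_frequency
    P[IP_FR] = di.rescue_frequency
    P[IP_SVG] = st.growth_factor
    P[IP_SVS] = st.shrink_factor
    P[IP_SFC] = st.catastrophe_factor
    P[IP_SFR] = st.rescue_factor
    P[IP_SLEN] = st.stabilization_length
    P[IP_XLK] = xl.spring_constant
    P[IP_XLR0] = xl.rest_length
    P[IP_K1ON] = xl.one_head_on_rate
    P[IP_K1OFF] = xl.one_head_off_rate
    P[IP_K2ON] = xl.two_head_on_rate_scale
    P[IP_K2OFF] = xl.two_head_off_rate
    P[IP_DBOUND] = xl.bound_diffusion_coefficient
    P[IP_DFREE] = xl.free_diffusion_coefficient
    P[IP_APTHRESH] = xl.antiparallel_dot_threshold
    P[IP_EBIND] = xl.characteristic_binding_energy
    P[IP_RCAP] = xl.capture_radius
    P[IP_BELL] = xl.bell_length
    P[IP_BINW] = xl.partition_bin_width
    P[IP_FW] = wf.asymptotic_force
    P[IP_RTUBE] = wf.tube_radius
    P[IP_WGAMMA] = wf.euler_gamma
    P[IP_WA] = wf.const_a
    P[IP_WC] = wf.const_c
    P[IP_WBLEND] = wf.blend_scale
    P[IP_WB] = wf.const_b
    P[IP_SIGMA] = rt.subunit_increment
    P[IP_FSTALL] = rt.stall_scale
    P[IP_DT] = ct.timestep
    P[IP_KMCI] = float(ct.kmc_interval)
    P[IP_STAB] = 1.0 if ct.stabilization_enabled else 0.0
    P[IP_RATCHET] = 1.0 if ct.ratchet_load_source == "boundary" else 0.0
    P[IP_TILT] = g.nucleation_tilt_sigma
    P[IP_MEXCL] = xl.minus_end_exclusion
    return P


@njit(cache=False)
def seed_kernel_rng(seed):
    np.random.seed(seed)


# ---------------------------------------------------------------------------
# scalar force laws
# ---------------------------------------------------------------------------

@njit(inline="always")
def wall_force_scalar(L, F_w, R_tube, b, gamma_e, a, c, blend, r_tip):
    """Inward wall force (pN) on a plus tip protruding a distance L (um).

    Sum of the small-deformation linear response of a tensed membrane to a
    point load (slope set by the tube radius and Euler's constant, damped
    beyond the tension length b = sqrt(2) R_tube) and the membrane-tube
    regime relaxing to the asymptotic tube force F_w, gated by the
    (1 - e^-L) blending factor so that F(0) = 0 exactly.
    """
    if F_w <= 0.0:
        return 0.0
    slope = F_w / (2.0 * R_tube * (math.log(2.0 * b / r_tip) - gamma_e))
    lin = slope * L * math.exp(-L / b)
    tube = F_w * (1.0 + a * math.exp(-c * L / b))
    return lin + (1.0 - math.exp(-L / blend)) * tube


@njit(inline="always")
def ratchet_speed_factor(F, F_s, sigma, kT):
    """Growth-speed reduction v(F)/v(0) of the N-protofilament ratchet.

    alpha = exp(F_s sigma / kT), beta = F sigma / kT; the shared-load
    multi-filament ratchet gives v(F) = v+ (alpha e^-beta - 1) with v+
    normalized so v(0) equals the zero-force growth speed, i.e.
    v(F)/v_g = (alpha e^-beta - 1)/(alpha - 1), clamped at stall.
    """
    if F <= 0.0:
        return 1.0
    alpha = math.exp(F_s * sigma / kT)
    if alpha - 1.0 < 1e-12:
        return 0.0
    val = (alpha * math.exp(-F * sigma / kT) - 1.0) / (alpha - 1.0)
    if val < 0.0:
        return 0.0
    return val


@njit(inline="always")
def _seg_closest(p1x, p1y, p1z, u1x, u1y, u1z, L1,
                 p2x, p2y, p2z, u2x, u2y, u2z, L2):
    """Closest points between two segments (minus end p, unit direction u).

    Returns (s, t, dx, dy, dz, dist): arc coordinates of the closest points
    and the vector from segment 2's point to segment 1's point.
    """
    rx = p1x - p2x
    ry = p1y - p2y
    rz = p1z - p2z
    b = u1x * u2x + u1y * u2y + u1z * u2z
    c1 = u1x * rx + u1y * ry + u1z * rz
    f = u2x * rx + u2y * ry + u2z * rz
    den = 1.0 - b * b
    if den > 1e-12:
        s = (b * f - c1) / den
    else:
        s = 0.0
    if s < 0.0:
        s = 0.0
    elif s > L1:
        s = L1
    t = s * b + f
    if t < 0.0:
        t = 0.0
    elif t > L2:
        t = L2
    s = t * b - c1
    if s < 0.0:
        s = 0.0
    elif s > L1:
        s = L1
    dx = rx + s * u1x - t * u2x
    dy = ry + s * u1y - t * u2y
    dz = rz + s * u1z - t * u2z
    dist = math.sqrt(dx * dx + dy * dy + dz * dz)
    return s, t, dx, dy, dz, dist


@njit(inline="always")
def _wca_force_mag(dist, sigma, eps, fcap):
    """Capped WCA repulsion magnitude at separation ``dist``."""
    rc = 1.1224620483093730 * sigma
    if dist >= rc or dist <= 0.0:
        return 0.0
    q = sigma / dist
    q6 = q * q * q
    q6 = q6 * q6
    fmag = 24.0 * eps * (2.0 * q6 * q6 - q6) / dist
    if fmag > fcap:
        fmag = fcap
    if fmag < 0.0:
        fmag = 0.0
    return fmag


@njit(inline="always")
def _point_seg(px, py, pz, qx, qy, qz, ux, uy, uz, L):
    """Distance info from point p to segment (q, u, L).

    Returns (tc, dperp2, dmin2): unclamped arc of the perpendicular foot,
    squared perpendicular distance to the infinite line, and squared
    distance to the clamped segment point.
    """
    wx = px - qx
    wy = py - qy
    wz = pz - qz
    tc = wx * ux + wy * uy + wz * uz
    w2 = wx * wx + wy * wy + wz * wz
    dperp2 = w2 - tc * tc
    if dperp2 < 0.0:
        dperp2 = 0.0
    t = tc
    if t < 0.0:
        t = 0.0
    elif t > L:
        t = L
    dx = wx - t * ux
    dy = wy - t * uy
    dz = wz - t * uz
    dmin2 = dx * dx + dy * dy + dz * dz
    return tc, dperp2, dmin2


# ---------------------------------------------------------------------------
# SPB nucleation-site layout
# ---------------------------------------------------------------------------

@njit(cache=False)
def site_positions(spb_u, spb_phi, R_env, r_spb, n_sites, out):
    """Nucleation-site positions on the envelope sphere, (2, n_sites, 3).

    Sites sit on a ring of radius 0.5*r_spb in the SPB's tangent plane,
    rotated by the SPB's in-plane angle, then projected onto the sphere.
    """
    for i in range(spb_u.shape[0]):
        ux, uy, uz = spb_u[i, 0], spb_u[i, 1], spb_u[i, 2]
        # tangent basis
        if abs(ux) < 0.9:
            ax, ay, az = 1.0, 0.0, 0.0
        else:
            ax, ay, az = 0.0, 1.0, 0.0
        e1x = uy * az - uz * ay
        e1y = uz * ax - ux * az
        e1z = ux * ay - uy * ax
        n1 = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        e1x /= n1
        e1y /= n1
        e1z /= n1
        e2x = uy * e1z - uz * e1y
        e2y = uz * e1x - ux * e1z
        e2z = ux * e1y - uy * e1x
        rr = 0.5 * r_spb
        for k in range(n_sites):
            th = spb_phi[i] + 2.0 * math.pi * k / n_sites
            ox = rr * (math.cos(th) * e1x + math.sin(th) * e2x)
            oy = rr * (math.cos(th) * e1y + math.sin(th) * e2y)
            oz = rr * (math.cos(th) * e1z + math.sin(th) * e2z)
            sx = R_env * ux + ox
            sy = R_env * uy + oy
            sz = R_env * uz + oz
            nn = math.sqrt(sx * sx + sy * sy + sz * sz)
            out[i, k, 0] = R_env * sx / nn
            out[i, k, 1] = R_env * sy / nn
            out[i, k, 2] = R_env * sz / nn


# ---------------------------------------------------------------------------
# crosslinker kinetic Monte Carlo
# ---------------------------------------------------------------------------

@njit(cache=False)
def kmc_crosslinkers(P, minus, mt_u, mt_len, xl_state, xl_pos, xl_mt,
                     xl_arc, delta):
    """One kMC interval for every crosslinker (at most one event each).

    free -> one-bound at ``one_head_on_rate`` per um of MT lattice within the
    capture radius (landing uniform on the nearby lattice); one-bound ->
    two-bound with a rate density proportional to the Boltzmann factor of
    spring stretch over strictly antiparallel partners (landing drawn from
    that density); unbinding at the constant (optionally Bell force-
    dependent) off-rates.  Unbinding a single head repositions the free
    crosslinker uniformly in the capture sphere around the released head,
    the detailed-balance partner of the binding move.
    """
    M = mt_len.shape[0]
    N = xl_state.shape[0]
    kT = P[IP_KT]
    k_xl = P[IP_XLK]
    r0 = P[IP_XLR0]
    rcap = P[IP_RCAP]
    k1on = P[IP_K1ON]
    k1off = P[IP_K1OFF]
    k2on = P[IP_K2ON] * math.exp(P[IP_EBIND])
    k2off = P[IP_K2OFF]
    apthr = P[IP_APTHRESH]
    binw = P[IP_BINW]
    bell = P[IP_BELL]
    # reach of the spring Boltzmann factor (12 kT cutoff)
    if k_xl > 0.0:
        dE = math.sqrt(24.0 * kT / k_xl)
    else:
        dE = rcap
    reach = r0 + dE
    wlen = np.empty(M)
    tlo = np.empty(M)
    thi = np.empty(M)
    for i in range(N):
        st = xl_state[i]
        if st == 0:
            # --- free: first-head binding ---
            px, py, pz = xl_pos[i, 0], xl_pos[i, 1], xl_pos[i, 2]
            tot = 0.0
            for m in range(M):
                tc, dperp2, dmin2 = _point_seg(
                    px, py, pz, minus[m, 0], minus[m, 1], minus[m, 2],
                    mt_u[m, 0], mt_u[m, 1], mt_u[m, 2], mt_len[m])
                if dmin2 >= rcap * rcap:
                    wlen[m] = 0.0
                    continue
                h2 = rcap * rcap - dperp2
                h = math.sqrt(h2) if h2 > 0.0 else 0.0
                lo = tc - h
                hi = tc + h
                if lo < P[IP_MEXCL]:
                    lo = P[IP_MEXCL]
                if hi > mt_len[m]:
                    hi = mt_len[m]
                if hi <= lo:
                    wlen[m] = 0.0
                    continue
                wlen[m] = hi - lo
                tlo[m] = lo
                thi[m] = hi
                tot += hi - lo
            rate = k1on * tot
            if rate <= 0.0:
                continue
            if np.random.random() < 1.0 - math.exp(-rate * delta):
                pick = np.random.random() * tot
                acc = 0.0
                for m in range(M):
                    acc += wlen[m]
                    if pick <= acc and wlen[m] > 0.0:
                        xl_state[i] = 1
                        xl_mt[i, 0] = m
                        xl_arc[i, 0] = tlo[m] + np.random.random() * (
                            thi[m] - tlo[m])
                        break
        elif st == 1:
            # --- one head bound: unbind or bind second head ---
            m0 = xl_mt[i, 0]
            s0 = xl_arc[i, 0]
            hx = minus[m0, 0] + s0 * mt_u[m0, 0]
            hy = minus[m0, 1] + s0 * mt_u[m0, 1]
            hz = minus[m0, 2] + s0 * mt_u[m0, 2]
            tot2 = 0.0
            for n in range(M):
                wlen[n] = 0.0
                if n == m0:
                    continue
                dot = (mt_u[m0, 0] * mt_u[n, 0] + mt_u[m0, 1] * mt_u[n, 1]
                       + mt_u[m0, 2] * mt_u[n, 2])
                if dot >= apthr:
                    continue
                tc, dperp2, dmin2 = _point_seg(
                    hx, hy, hz, minus[n, 0], minus[n, 1], minus[n, 2],
                    mt_u[n, 0], mt_u[n, 1], mt_u[n, 2], mt_len[n])
                if dmin2 >= reach * reach:
                    continue
                h2 = reach * reach - dperp2
                h = math.sqrt(h2) if h2 > 0.0 else 0.0
                lo = tc - h
                hi = tc + h
                if lo < P[IP_MEXCL]:
                    lo = P[IP_MEXCL]
                if hi > mt_len[n]:
                    hi = mt_len[n]
                if hi <= lo:
                    continue
                nb = int((hi - lo) / binw) + 1
                w = (hi - lo) / nb
                acc = 0.0
                for ib in range(nb):
                    t = lo + (ib + 0.5) * w
                    dx = hx - (minus[n, 0] + t * mt_u[n, 0])
                    dy = hy - (minus[n, 1] + t * mt_u[n, 1])
                    dz = hz - (minus[n, 2] + t * mt_u[n, 2])
                    dist = math.sqrt(dx * dx + dy * dy + dz * dz)
                    stretch = dist - r0
                    acc += math.exp(-0.5 * k_xl * stretch * stretch / kT) * w
                wlen[n] = acc
                tlo[n] = lo
                thi[n] = hi
                tot2 += acc
            rate2 = k2on * tot2
            rtot = k1off + rate2
            if rtot <= 0.0:
                continue
            if np.random.random() < 1.0 - math.exp(-rtot * delta):
                if np.random.random() * rtot < k1off:
                    # release: uniform in the capture sphere around the head
                    xl_state[i] = 0
                    rr = rcap * np.random.random() ** (1.0 / 3.0)
                    gx = np.random.normal()
                    gy = np.random.normal()
                    gz = np.random.normal()
                    gn = math.sqrt(gx * gx + gy * gy + gz * gz)
                    if gn < 1e-12:
                        gn = 1.0
                    xl_pos[i, 0] = hx + rr * gx / gn
                    xl_pos[i, 1] = hy + rr * gy / gn
                    xl_pos[i, 2] = hz + rr * gz / gn
                else:
                    pick = np.random.random() * tot2
                    acc = 0.0
                    for n in range(M):
                        if wlen[n] <= 0.0:
                            continue
                        if pick <= acc + wlen[n]:
                            # resample the landing bin within partner n
                            nb = int((thi[n] - tlo[n]) / binw) + 1
                            w = (thi[n] - tlo[n]) / nb
                            target = np.random.random() * wlen[n]
                            acc2 = 0.0
                            t_land = 0.5 * (tlo[n] + thi[n])
                            for ib in range(nb):
                                t = tlo[n] + (ib + 0.5) * w
                                dx = hx - (minus[n, 0] + t * mt_u[n, 0])
                                dy = hy - (minus[n, 1] + t * mt_u[n, 1])
                                dz = hz - (minus[n, 2] + t * mt_u[n, 2])
                                dist = math.sqrt(dx * dx + dy * dy + dz * dz)
                                stretch = dist - r0
                                acc2 += math.exp(
                                    -0.5 * k_xl * stretch * stretch / kT) * w
                                if target <= acc2:
                                    t_land = tlo[n] + (
                                        ib + np.random.random()) * w
                                    break
                            xl_state[i] = 2
                            xl_mt[i, 1] = n
                            xl_arc[i, 1] = t_land
                            break
                        acc += wlen[n]
        else:
            # --- two heads bound: one head may unbind ---
            m0 = xl_mt[i, 0]
            m1 = xl_mt[i, 1]
            off0 = k2off
            off1 = k2off
            if bell > 0.0:
                ax = minus[m0, 0] + xl_arc[i, 0] * mt_u[m0, 0]
                ay = minus[m0, 1] + xl_arc[i, 0] * mt_u[m0, 1]
                az = minus[m0, 2] + xl_arc[i, 0] * mt_u[m0, 2]
                bx = minus[m1, 0] + xl_arc[i, 1] * mt_u[m1, 0]
                by = minus[m1, 1] + xl_arc[i, 1] * mt_u[m1, 1]
                bz = minus[m1, 2] + xl_arc[i, 1] * mt_u[m1, 2]
                d = math.sqrt((ax - bx) ** 2 + (ay - by) ** 2 + (az - bz) ** 2)
                fmag = abs(k_xl * (d - r0))
                off0 = off1 = k2off * math.exp(fmag * bell / kT)
            rtot = off0 + off1
            if rtot <= 0.0:
                continue
            if np.random.random() < 1.0 - math.exp(-rtot * delta):
                if np.random.random() * rtot < off0:
                    # head 0 releases; keep head 1 as the bound head
                    xl_mt[i, 0] = xl_mt[i, 1]
                    xl_arc[i, 0] = xl_arc[i, 1]
                xl_state[i] = 1


@njit(cache=False)
def xl_diffusion(P, minus, mt_u, mt_len, xl_state, xl_pos, xl_mt, xl_arc,
                 delta):
    """Diffusive motion of crosslinkers over one interval ``delta``.

    Free crosslinkers take 3-D Gaussian steps reflected into the envelope
    sphere.  Singly bound heads diffuse force-free along their MT.  Both
    heads of a doubly bound crosslinker take 1-D steps along their MTs with
    drift from the axial component of the spring force, integrated with an
    Ornstein-Uhlenbeck update (exact for a linear force of stiffness equal
    to the spring constant), which keeps stiff springs stable at any step.
    Heads are clamped at the MT ends.
    """
    N = xl_state.shape[0]
    kT = P[IP_KT]
    k_xl = P[IP_XLK]
    r0 = P[IP_XLR0]
    Dfree = P[IP_DFREE]
    Dbound = P[IP_DBOUND]
    R = P[IP_RENV]
    mexcl = P[IP_MEXCL]
    sfree = math.sqrt(2.0 * Dfree * delta)
    sbound = math.sqrt(2.0 * Dbound * delta)
    if k_xl > 0.0 and Dbound > 0.0:
        mob = Dbound / kT
        efold = math.exp(-mob * k_xl * delta)
        drift_fac = (1.0 - efold) / k_xl
        noise_ou = math.sqrt(kT / k_xl * (1.0 - efold * efold))
    else:
        drift_fac = 0.0
        noise_ou = sbound
    for i in range(N):
        st = xl_state[i]
        if st == 0:
            if Dfree <= 0.0:
                continue
            x = xl_pos[i, 0] + sfree * np.random.normal()
            y = xl_pos[i, 1] + sfree * np.random.normal()
            z = xl_pos[i, 2] + sfree * np.random.normal()
            # hard-wall confinement by rejection: preserves the uniform
            # stationary measure exactly at any step size
            if x * x + y * y + z * z <= R * R:
                xl_pos[i, 0] = x
                xl_pos[i, 1] = y
                xl_pos[i, 2] = z
        elif st == 1:
            if Dbound <= 0.0:
                continue
            m0 = xl_mt[i, 0]
            s = xl_arc[i, 0] + sbound * np.random.normal()
            if s < mexcl:
                s = mexcl
            if s > mt_len[m0]:
                s = mt_len[m0]
            xl_arc[i, 0] = s
        else:
            if Dbound <= 0.0:
                continue
            m0 = xl_mt[i, 0]
            m1 = xl_mt[i, 1]
            ax = minus[m0, 0] + xl_arc[i, 0] * mt_u[m0, 0]
            ay = minus[m0, 1] + xl_arc[i, 0] * mt_u[m0, 1]
            az = minus[m0, 2] + xl_arc[i, 0] * mt_u[m0, 2]
            bx = minus[m1, 0] + xl_arc[i, 1] * mt_u[m1, 0]
            by = minus[m1, 1] + xl_arc[i, 1] * mt_u[m1, 1]
            bz = minus[m1, 2] + xl_arc[i, 1] * mt_u[m1, 2]
            dx = bx - ax
            dy = by - ay
            dz = bz - az
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d > 1e-12:
                fmag = k_xl * (d - r0)
                # axial spring force on each head (toward partner if stretched)
                f0 = fmag * (dx * mt_u[m0, 0] + dy * mt_u[m0, 1]
                             + dz * mt_u[m0, 2]) / d
                f1 = -fmag * (dx * mt_u[m1, 0] + dy * mt_u[m1, 1]
                              + dz * mt_u[m1, 2]) / d
            else:
                f0 = 0.0
                f1 = 0.0
            s = xl_arc[i, 0] + f0 * drift_fac + noise_ou * np.random.normal()
            if s < mexcl:
                s = mexcl
            if s > mt_len[m0]:
                s = mt_len[m0]
            xl_arc[i, 0] = s
            s = xl_arc[i, 1] + f1 * drift_fac + noise_ou * np.random.normal()
            if s < mexcl:
                s = mexcl
            if s > mt_len[m1]:
                s = mt_len[m1]
            xl_arc[i, 1] = s


@njit(cache=False)
def equilibrium_sampler(P, minus, mt_u, mt_len, xl_state, xl_pos, xl_mt,
                        xl_arc, delta, n_samples, stride, seed,
                        occ_counts, arc_samples):
    """Sample the crosslinker state chain on frozen filaments.

    Runs ``n_samples * stride`` kMC+diffusion intervals, recording at every
    ``stride``-th interval the (0/1/2)-bound occupancy and, when doubly
    bound, the arc coordinate of the head attached to MT 0 (-1 otherwise).
    Used by the statistical-mechanics validation against direct Boltzmann
    integration.
    """
    np.random.seed(seed)
    for k in range(n_samples):
        for _ in range(stride):
            kmc_crosslinkers(P, minus, mt_u, mt_len, xl_state, xl_pos,
                             xl_mt, xl_arc, delta)
            xl_diffusion(P, minus, mt_u, mt_len, xl_state, xl_pos, xl_mt,
                         xl_arc, delta)
        st = xl_state[0]
        occ_counts[st] += 1
        if st == 2:
            if xl_mt[0, 0] == 0:
                arc_samples[k] = xl_arc[0, 0]
            else:
                arc_samples[k] = xl_arc[0, 1]
        else:
            arc_samples[k] = -1.0


# ---------------------------------------------------------------------------
# single-MT dynamic-instability ensemble (event-driven)
# ---------------------------------------------------------------------------

@njit(cache=False)
def di_ensemble_mean_length(seed, n_mt, t_total, t_burn, v_g, v_s, f_c, f_r,
                            L0, L_min):
    """Time-and-ensemble-averaged length of isolated dynamic MTs.

    Event-driven two-state simulation (no forces, no boundary): exponential
    waiting times between catastrophe/rescue events, linear length change
    in between, renucleation (switch to growth) at the ``L_min`` floor.
    Lengths are integrated exactly over each linear segment after burn-in.
    """
    np.random.seed(seed)
    total_int = 0.0
    total_time = 0.0
    for _ in range(n_mt):
        t = 0.0
        L = L0
        growing = True
        while t < t_total:
            rate = f_c if growing else f_r
            if rate > 0.0:
                tau = -math.log(np.random.random()) / rate
            else:
                tau = t_total - t + 1.0
            t_end = t + tau
            if t_end > t_total:
                t_end = t_total
            v = v_g if growing else -v_s
            seg = t_end - t
            # handle hitting the floor mid-segment while shrinking
            if not growing and L + v * seg < L_min:
                t_hit = (L - L_min) / v_s
                # integrate shrink part
                a0 = t
                a1 = t + t_hit
                if a1 > t_burn:
                    lo = a0 if a0 > t_burn else t_burn
                    dtseg = a1 - lo
                    Llo = L - v_s * (lo - t)
                    total_int += dtseg * (Llo + (Llo - v_s * dtseg)) * 0.5
                    total_time += dtseg
                t = a1
                L = L_min
                growing = True  # renucleation
                continue
            if t_end > t_burn:
                lo = t if t > t_burn else t_burn
                dtseg = t_end - lo
                Llo = L + v * (lo - t)
                total_int += dtseg * (Llo + (Llo + v * dtseg)) * 0.5
                total_time += dtseg
            L += v * seg
            t = t_end
            growing = not growing
    return total_int / total_time


@njit(cache=False)
def ratchet_gillespie_speed(seed, n_events, F, F_s, sigma, kT, v_g):
    """Stochastic 13-protofilament ratchet speed at load F (um/s).

    Each protofilament adds subunits at rate k_plus * exp(-F sigma / kT)
    (thermal-ratchet gating of the work F*sigma per added subunit) and loses
    them at rate k_minus, with k_plus/k_minus = exp(F_s sigma / kT) and the
    zero-force net speed equal to ``v_g``.  Returns the measured mean tip
    speed over ``n_events`` stochastic events summed over protofilaments.
    """
    np.random.seed(seed)
    alpha = math.exp(F_s * sigma / kT)
    k_minus = v_g / (13.0 * sigma * (alpha - 1.0))
    k_plus = alpha * k_minus
    kon = 13.0 * k_plus * math.exp(-F * sigma / kT)
    koff = 13.0 * k_minus
    ktot = kon + koff
    t = 0.0
    x = 0.0
    for _ in range(n_events):
        t += -math.log(np.random.random()) / ktot
        if np.random.random() * ktot < kon:
            x += sigma
        else:
            x -= sigma
    return x / t


# ---------------------------------------------------------------------------
# full engine loop
# ---------------------------------------------------------------------------

@njit(cache=False)
def _mt_minus_ends(spb_u, spb_phi, mt_spb, mt_site, R_env, r_spb, n_sites,
                   sites, minus):
    site_positions(spb_u, spb_phi, R_env, r_spb, n_sites, sites)
    for m in range(mt_spb.shape[0]):
        minus[m, 0] = sites[mt_spb[m], mt_site[m], 0]
        minus[m, 1] = sites[mt_spb[m], mt_site[m], 1]
        minus[m, 2] = sites[mt_spb[m], mt_site[m], 2]


@njit(cache=False)
def run_engine(P, seed, n_steps, record_every, n_sites,
               spb_u, spb_phi, mt_u, mt_len, mt_grow, mt_spb, mt_site,
               xl_state, xl_pos, xl_mt, xl_arc,
               out_t, out_spb, out_sep, out_len, out_grow, out_eng, out_if,
               out_nb):
    """Advance the full system ``n_steps`` timesteps, recording frames.

    Per step: deterministic forces (steric, wall, crosslink springs, SPB
    exclusion) -> dynamic-instability switching and length update (with
    crosslink stabilization and ratchet load response) -> crosslinker kMC
    and diffusion (every ``kmc_interval`` steps) -> Brownian moves of MTs
    (pivoting about their nucleation sites) and SPBs (in-membrane).
    Returns 0 on success, 1 on a non-finite force (diagnosed by the caller).
    """
    np.random.seed(seed)
    M = mt_len.shape[0]
    N = xl_state.shape[0]
    dt = P[IP_DT]
    kmci = int(P[IP_KMCI])
    R = P[IP_RENV]
    r_spb = P[IP_RSPB]
    eta = P[IP_ETA]
    kT = P[IP_KT]
    diam = P[IP_MTDIAM]
    eps = kT
    fcap = P[IP_FCAP]
    k_xl = P[IP_XLK]
    r0 = P[IP_XLR0]
    slen = P[IP_SLEN]
    stab_on = P[IP_STAB] > 0.5
    ratchet_on = P[IP_RATCHET] > 0.5
    F_w = P[IP_FW]
    rtip = 0.5 * diam
    Lmin = P[IP_LMIN]
    Lmax = P[IP_LMAX]
    g_spb = kT / P[IP_DSPB]
    D_spb_rot = P[IP_DSPBROT]
    cutoff = 1.1224620483093730 * diam
    skin = 0.05
    nl_every = 20

    sites = np.empty((2, n_sites, 3))
    minus = np.empty((M, 3))
    torque = np.empty((M, 3))
    axload = np.empty(M)
    stab = np.empty(M, dtype=np.uint8)
    engaged = np.empty(M, dtype=np.uint8)
    spbF = np.empty((2, 3))
    spbTn = np.empty(2)
    pairs_i = np.empty(M * (M - 1) // 2, dtype=np.int64)
    pairs_j = np.empty(M * (M - 1) // 2, dtype=np.int64)
    n_pairs = 0
    frame = 0

    for step in range(n_steps + 1):
        _mt_minus_ends(spb_u, spb_phi, mt_spb, mt_site, R, r_spb, n_sites,
                       sites, minus)
        # ---- forces ----
        for m in range(M):
            torque[m, 0] = 0.0
            torque[m, 1] = 0.0
            torque[m, 2] = 0.0
            axload[m] = 0.0
            stab[m] = 0
            engaged[m] = 0
        for i2 in range(2):
            spbF[i2, 0] = 0.0
            spbF[i2, 1] = 0.0
            spbF[i2, 2] = 0.0
            spbTn[i2] = 0.0

        # steric neighbour list (centre-distance cull with skin)
        if step % nl_every == 0:
            n_pairs = 0
            for a in range(M):
                for b2 in range(a + 1, M):
                    cax = minus[a, 0] + 0.5 * mt_len[a] * mt_u[a, 0]
                    cay = minus[a, 1] + 0.5 * mt_len[a] * mt_u[a, 1]
                    caz = minus[a, 2] + 0.5 * mt_len[a] * mt_u[a, 2]
                    cbx = minus[b2, 0] + 0.5 * mt_len[b2] * mt_u[b2, 0]
                    cby = minus[b2, 1] + 0.5 * mt_len[b2] * mt_u[b2, 1]
                    cbz = minus[b2, 2] + 0.5 * mt_len[b2] * mt_u[b2, 2]
                    dd = math.sqrt((cax - cbx) ** 2 + (cay - cby) ** 2
                                   + (caz - cbz) ** 2)
                    if dd < 0.5 * (mt_len[a] + mt_len[b2]) + cutoff + skin:
                        pairs_i[n_pairs] = a
                        pairs_j[n_pairs] = b2
                        n_pairs += 1

        for ip in range(n_pairs):
            a = pairs_i[ip]
            b2 = pairs_j[ip]
            s, t, dx, dy, dz, dist = _seg_closest(
                minus[a, 0], minus[a, 1], minus[a, 2],
                mt_u[a, 0], mt_u[a, 1], mt_u[a, 2], mt_len[a],
                minus[b2, 0], minus[b2, 1], minus[b2, 2],
                mt_u[b2, 0], mt_u[b2, 1], mt_u[b2, 2], mt_len[b2])
            if dist >= cutoff:
                continue
            if dist < 1e-8:
                # deterministic tie-break: push along a fixed perpendicular
                if abs(mt_u[a, 0]) < 0.9:
                    dx, dy, dz = (mt_u[a, 1] * 0.0 - mt_u[a, 2] * 0.0,
                                  mt_u[a, 2], -mt_u[a, 1])
                else:
                    dx, dy, dz = (-mt_u[a, 2], 0.0, mt_u[a, 0])
                nn = math.sqrt(dx * dx + dy * dy + dz * dz)
                dx /= nn
                dy /= nn
                dz /= nn
                dist = 1e-8
            fmag = _wca_force_mag(dist, diam, eps, fcap)
            if fmag <= 0.0:
                continue
            fx = fmag * dx / dist
            fy = fmag * dy / dist
            fz = fmag * dz / dist
            # force +f on a at arc s, -f on b at arc t
            torque[a, 0] += s * (mt_u[a, 1] * fz - mt_u[a, 2] * fy)
            torque[a, 1] += s * (mt_u[a, 2] * fx - mt_u[a, 0] * fz)
            torque[a, 2] += s * (mt_u[a, 0] * fy - mt_u[a, 1] * fx)
            torque[b2, 0] -= t * (mt_u[b2, 1] * fz - mt_u[b2, 2] * fy)
            torque[b2, 1] -= t * (mt_u[b2, 2] * fx - mt_u[b2, 0] * fz)
            torque[b2, 2] -= t * (mt_u[b2, 0] * fy - mt_u[b2, 1] * fx)
            sa = mt_spb[a]
            sb = mt_spb[b2]
            spbF[sa, 0] += fx
            spbF[sa, 1] += fy
            spbF[sa, 2] += fz
            spbF[sb, 0] -= fx
            spbF[sb, 1] -= fy
            spbF[sb, 2] -= fz

        # wall force on protruding plus tips
        if F_w > 0.0:
            for m in range(M):
                tx = minus[m, 0] + mt_len[m] * mt_u[m, 0]
                ty = minus[m, 1] + mt_len[m] * mt_u[m, 1]
                tz = minus[m, 2] + mt_len[m] * mt_u[m, 2]
                rr = math.sqrt(tx * tx + ty * ty + tz * tz)
                prot = rr - R
                if prot <= 0.0:
                    continue
                fmag = wall_force_scalar(prot, F_w, P[IP_RTUBE], P[IP_WB],
                                         P[IP_WGAMMA], P[IP_WA], P[IP_WC],
                                         P[IP_WBLEND], rtip)
                fx = -fmag * tx / rr
                fy = -fmag * ty / rr
                fz = -fmag * tz / rr
                torque[m, 0] += mt_len[m] * (mt_u[m, 1] * fz - mt_u[m, 2] * fy)
                torque[m, 1] += mt_len[m] * (mt_u[m, 2] * fx - mt_u[m, 0] * fz)
                torque[m, 2] += mt_len[m] * (mt_u[m, 0] * fy - mt_u[m, 1] * fx)
                sa = mt_spb[m]
                spbF[sa, 0] += fx
                spbF[sa, 1] += fy
                spbF[sa, 2] += fz
                comp = -(fx * mt_u[m, 0] + fy * mt_u[m, 1] + fz * mt_u[m, 2])
                if comp > 0.0:
                    axload[m] += comp

        # crosslink springs; stabilization flags; interpolar engagement
        for i in range(N):
            if xl_state[i] != 2:
                continue
            m0 = xl_mt[i, 0]
            m1 = xl_mt[i, 1]
            s0 = xl_arc[i, 0]
            s1 = xl_arc[i, 1]
            if mt_len[m0] - s0 <= slen:
                stab[m0] = 1
            if mt_len[m1] - s1 <= slen:
                stab[m1] = 1
            if mt_spb[m0] != mt_spb[m1]:
                engaged[m0] = 1
                engaged[m1] = 1
            ax = minus[m0, 0] + s0 * mt_u[m0, 0]
            ay = minus[m0, 1] + s0 * mt_u[m0, 1]
            az = minus[m0, 2] + s0 * mt_u[m0, 2]
            bx = minus[m1, 0] + s1 * mt_u[m1, 0]
            by = minus[m1, 1] + s1 * mt_u[m1, 1]
            bz = minus[m1, 2] + s1 * mt_u[m1, 2]
            dx = bx - ax
            dy = by - ay
            dz = bz - az
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d < 1e-9:
                continue
            fmag = k_xl * (d - r0)
            fx = fmag * dx / d
            fy = fmag * dy / d
            fz = fmag * dz / d
            torque[m0, 0] += s0 * (mt_u[m0, 1] * fz - mt_u[m0, 2] * fy)
            torque[m0, 1] += s0 * (mt_u[m0, 2] * fx - mt_u[m0, 0] * fz)
            torque[m0, 2] += s0 * (mt_u[m0, 0] * fy - mt_u[m0, 1] * fx)
            torque[m1, 0] -= s1 * (mt_u[m1, 1] * fz - mt_u[m1, 2] * fy)
            torque[m1, 1] -= s1 * (mt_u[m1, 2] * fx - mt_u[m1, 0] * fz)
            torque[m1, 2] -= s1 * (mt_u[m1, 0] * fy - mt_u[m1, 1] * fx)
            sa = mt_spb[m0]
            sb = mt_spb[m1]
            spbF[sa, 0] += fx
            spbF[sa, 1] += fy
            spbF[sa, 2] += fz
            spbF[sb, 0] -= fx
            spbF[sb, 1] -= fy
            spbF[sb, 2] -= fz

        # MT vs opposite SPB disk: soft exclusion; polymerization against the
        # disk pushes the poles apart, and tip contacts load the ratchet
        for m in range(M):
            jo = 1 - mt_spb[m]
            cx = R * spb_u[jo, 0]
            cy = R * spb_u[jo, 1]
            cz = R * spb_u[jo, 2]
            tc, dperp2, dmin2 = _point_seg(
                cx, cy, cz, minus[m, 0], minus[m, 1], minus[m, 2],
                mt_u[m, 0], mt_u[m, 1], mt_u[m, 2], mt_len[m])
            contact = r_spb + 0.5 * diam
            if dmin2 >= contact * contact:
                continue
            s = tc
            if s < 0.0:
                s = 0.0
            elif s > mt_len[m]:
                s = mt_len[m]
            dxs = (minus[m, 0] + s * mt_u[m, 0]) - cx
            dys = (minus[m, 1] + s * mt_u[m, 1]) - cy
            dzs = (minus[m, 2] + s * mt_u[m, 2]) - cz
            dd = math.sqrt(dxs * dxs + dys * dys + dzs * dzs)
            if dd < 1e-9:
                continue
            fmag = P[IP_KSPBREP] * (contact - dd)
            if fmag > 3.0 * fcap:
                fmag = 3.0 * fcap
            fx = fmag * dxs / dd
            fy = fmag * dys / dd
            fz = fmag * dzs / dd
            torque[m, 0] += s * (mt_u[m, 1] * fz - mt_u[m, 2] * fy)
            torque[m, 1] += s * (mt_u[m, 2] * fx - mt_u[m, 0] * fz)
            torque[m, 2] += s * (mt_u[m, 0] * fy - mt_u[m, 1] * fx)
            sa = mt_spb[m]
            spbF[sa, 0] += fx
            spbF[sa, 1] += fy
            spbF[sa, 2] += fz
            spbF[jo, 0] -= fx
            spbF[jo, 1] -= fy
            spbF[jo, 2] -= fz
            if s > mt_len[m] - 0.02:
                comp = -(fx * mt_u[m, 0] + fy * mt_u[m, 1] + fz * mt_u[m, 2])
                if comp > 0.0:
                    axload[m] += comp

        # SPB-SPB soft exclusion
        dxs = R * (spb_u[0, 0] - spb_u[1, 0])
        dys = R * (spb_u[0, 1] - spb_u[1, 1])
        dzs = R * (spb_u[0, 2] - spb_u[1, 2])
        ds = math.sqrt(dxs * dxs + dys * dys + dzs * dzs)
        if 1e-9 < ds < 2.0 * r_spb:
            fmag = P[IP_KSPBREP] * (2.0 * r_spb - ds)
            spbF[0, 0] += fmag * dxs / ds
            spbF[0, 1] += fmag * dys / ds
            spbF[0, 2] += fmag * dzs / ds
            spbF[1, 0] -= fmag * dxs / ds
            spbF[1, 1] -= fmag * dys / ds
            spbF[1, 2] -= fmag * dzs / ds

        # ---- record frame ----
        if step % record_every == 0:
            out_t[frame] = step * dt
            neng = 0
            for m in range(M):
                out_len[frame, m] = mt_len[m]
                out_grow[frame, m] = mt_grow[m]
                out_eng[frame, m] = engaged[m]
                if engaged[m] == 1:
                    neng += 1
            out_if[frame] = neng / M if M > 0 else 0.0
            for i2 in range(2):
                out_spb[frame, i2, 0] = R * spb_u[i2, 0]
                out_spb[frame, i2, 1] = R * spb_u[i2, 1]
                out_spb[frame, i2, 2] = R * spb_u[i2, 2]
            out_sep[frame] = math.sqrt(
                (R * (spb_u[0, 0] - spb_u[1, 0])) ** 2
                + (R * (spb_u[0, 1] - spb_u[1, 1])) ** 2
                + (R * (spb_u[0, 2] - spb_u[1, 2])) ** 2)
            nb0 = 0
            nb1 = 0
            nb2 = 0
            for i in range(N):
                if xl_state[i] == 0:
                    nb0 += 1
                elif xl_state[i] == 1:
                    nb1 += 1
                else:
                    nb2 += 1
            out_nb[frame, 0] = nb0
            out_nb[frame, 1] = nb1
            out_nb[frame, 2] = nb2
            frame += 1
        if step == n_steps:
            break

        # ---- dynamic instability ----
        for m in range(M):
            if stab_on and stab[m] == 1:
                vg = P[IP_VG] * P[IP_SVG]
                vs = P[IP_VS] / P[IP_SVS]
                fc = P[IP_FC] / P[IP_SFC]
                fr = P[IP_FR] * P[IP_SFR]
            else:
                vg = P[IP_VG]
                vs = P[IP_VS]
                fc = P[IP_FC]
                fr = P[IP_FR]
            if mt_grow[m] == 1:
                if np.random.random() < 1.0 - math.exp(-fc * dt):
                    mt_grow[m] = 0
                else:
                    v = vg
                    if ratchet_on and axload[m] > 0.0:
                        v *= ratchet_speed_factor(axload[m], P[IP_FSTALL],
                                                  P[IP_SIGMA], kT)
                    mt_len[m] += v * dt
                    if mt_len[m] > Lmax:
                        mt_len[m] = Lmax
            else:
                if np.random.random() < 1.0 - math.exp(-fr * dt):
                    mt_grow[m] = 1
                else:
                    mt_len[m] -= vs * dt
                    if mt_len[m] < Lmin:
                        # renucleation: a fresh MT grows from the nucleation
                        # template along the inward site normal (small tilt)
                        mt_len[m] = Lmin
                        mt_grow[m] = 1
                        sx = minus[m, 0]
                        sy = minus[m, 1]
                        sz = minus[m, 2]
                        sr = math.sqrt(sx * sx + sy * sy + sz * sz)
                        tilt = P[IP_TILT]
                        nx = -sx / sr + tilt * np.random.normal()
                        ny = -sy / sr + tilt * np.random.normal()
                        nz = -sz / sr + tilt * np.random.normal()
                        nn = math.sqrt(nx * nx + ny * ny + nz * nz)
                        mt_u[m, 0] = nx / nn
                        mt_u[m, 1] = ny / nn
                        mt_u[m, 2] = nz / nn

        # evict heads stranded past a shrunken plus end
        for i in range(N):
            if xl_state[i] == 1:
                m0 = xl_mt[i, 0]
                if xl_arc[i, 0] > mt_len[m0]:
                    xl_state[i] = 0
                    xl_pos[i, 0] = minus[m0, 0] + mt_len[m0] * mt_u[m0, 0]
                    xl_pos[i, 1] = minus[m0, 1] + mt_len[m0] * mt_u[m0, 1]
                    xl_pos[i, 2] = minus[m0, 2] + mt_len[m0] * mt_u[m0, 2]
            elif xl_state[i] == 2:
                if xl_arc[i, 0] > mt_len[xl_mt[i, 0]]:
                    xl_mt[i, 0] = xl_mt[i, 1]
                    xl_arc[i, 0] = xl_arc[i, 1]
                    xl_state[i] = 1
                elif xl_arc[i, 1] > mt_len[xl_mt[i, 1]]:
                    xl_state[i] = 1

        # ---- crosslinker kMC + diffusion ----
        if step % kmci == 0:
            delta = kmci * dt
            kmc_crosslinkers(P, minus, mt_u, mt_len, xl_state, xl_pos,
                             xl_mt, xl_arc, delta)
            xl_diffusion(P, minus, mt_u, mt_len, xl_state, xl_pos, xl_mt,
                         xl_arc, delta)

        # ---- Brownian moves ----
        # MTs pivot about their nucleation sites
        for m in range(M):
            L = mt_len[m]
            lp = math.log(L / diam) + 0.84
            gam = 4.0 * math.pi * eta * L * L * L / (3.0 * lp)
            Drot = kT / gam
            ux, uy, uz = mt_u[m, 0], mt_u[m, 1], mt_u[m, 2]
            # perpendicular component of torque / gamma * dt
            tdotu = torque[m, 0] * ux + torque[m, 1] * uy + torque[m, 2] * uz
            wx = (torque[m, 0] - tdotu * ux) / gam * dt
            wy = (torque[m, 1] - tdotu * uy) / gam * dt
            wz = (torque[m, 2] - tdotu * uz) / gam * dt
            # rotational noise about two perpendicular axes
            if abs(ux) < 0.9:
                axx, axy, axz = 1.0, 0.0, 0.0
            else:
                axx, axy, axz = 0.0, 1.0, 0.0
            e1x = uy * axz - uz * axy
            e1y = uz * axx - ux * axz
            e1z = ux * axy - uy * axx
            nn = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
            e1x /= nn
            e1y /= nn
            e1z /= nn
            e2x = uy * e1z - uz * e1y
            e2y = uz * e1x - ux * e1z
            e2z = ux * e1y - uy * e1x
            sn = math.sqrt(2.0 * Drot * dt)
            g1 = sn * np.random.normal()
            g2 = sn * np.random.normal()
            wx += g1 * e1x + g2 * e2x
            wy += g1 * e1y + g2 * e2y
            wz += g1 * e1z + g2 * e2z
            wmag = math.sqrt(wx * wx + wy * wy + wz * wz)
            if wmag > 0.3:
                sc = 0.3 / wmag
                wx *= sc
                wy *= sc
                wz *= sc
            nx = ux + (wy * uz - wz * uy)
            ny = uy + (wz * ux - wx * uz)
            nz = uz + (wx * uy - wy * ux)
            nn = math.sqrt(nx * nx + ny * ny + nz * nz)
            if not math.isfinite(nn) or nn < 1e-12:
                return 1
            mt_u[m, 0] = nx / nn
            mt_u[m, 1] = ny / nn
            mt_u[m, 2] = nz / nn

        # SPBs translate in the membrane (tangent step + reprojection)
        for i2 in range(2):
            # effective drag: envelope drag plus drag of the pivoting aster
            gtot = g_spb
            for m in range(M):
                if mt_spb[m] != i2:
                    continue
                L = mt_len[m]
                lpar = math.log(L / diam) - 0.2
                if lpar < 0.1:
                    lpar = 0.1
                lper = math.log(L / diam) + 0.84
                gpar = 2.0 * math.pi * eta * L / lpar
                gper = 4.0 * math.pi * eta * L / lper
                gtot += (gpar + 2.0 * gper) / 3.0
            ux, uy, uz = spb_u[i2, 0], spb_u[i2, 1], spb_u[i2, 2]
            fdotu = spbF[i2, 0] * ux + spbF[i2, 1] * uy + spbF[i2, 2] * uz
            ftx = spbF[i2, 0] - fdotu * ux
            fty = spbF[i2, 1] - fdotu * uy
            ftz = spbF[i2, 2] - fdotu * uz
            if not (math.isfinite(ftx) and math.isfinite(fty)
                    and math.isfinite(ftz)):
                return 1
            if abs(ux) < 0.9:
                axx, axy, axz = 1.0, 0.0, 0.0
            else:
                axx, axy, axz = 0.0, 1.0, 0.0
            e1x = uy * axz - uz * axy
            e1y = uz * axx - ux * axz
            e1z = ux * axy - uy * axx
            nn = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
            e1x /= nn
            e1y /= nn
            e1z /= nn
            e2x = uy * e1z - uz * e1y
            e2y = uz * e1x - ux * e1z
            e2z = ux * e1y - uy * e1x
            sn = math.sqrt(2.0 * kT / gtot * dt)
            g1 = sn * np.random.normal()
            g2 = sn * np.random.normal()
            sx = ftx / gtot * dt + g1 * e1x + g2 * e2x
            sy = fty / gtot * dt + g1 * e1y + g2 * e2y
            sz = ftz / gtot * dt + g1 * e1z + g2 * e2z
            nx = ux + sx / R
            ny = uy + sy / R
            nz = uz + sz / R
            nn = math.sqrt(nx * nx + ny * ny + nz * nz)
            spb_u[i2, 0] = nx / nn
            spb_u[i2, 1] = ny / nn
            spb_u[i2, 2] = nz / nn
            # in-plane rotational diffusion
            spb_phi[i2] += math.sqrt(2.0 * D_spb_rot * dt) * np.random.normal()

    return 0
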