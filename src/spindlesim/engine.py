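"""Simulation driver: initialization, the time-stepping loop, scans, sweeps.

A run is fully reproducible from (resolved parameters, seed).  Parameter
scans derive one independent sub-seed per (sample, replicate) pair from the
master seed with :func:`numpy.random.SeedSequence`, so scan results are
independent of execution order and of interruption/resumption.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .analysis import classify_success, late_time_separation
from .geometry import SystemState
from .params import (ParameterSample, SamplingRanges, SimulationParameters,
                     ValidationError, build_reference_params,
                     sample_parameter_sets, write_config)


class SimulationError(RuntimeError):
    """Numerical blow-up or internal failure during a run."""


@dataclass
class Trajectory:
    """Recorded frames of one run (arrays indexed frame-first)."""

    times: np.ndarray          # (F,)
    spb_positions: np.ndarray  # (F, 2, 3)
    separation: np.ndarray     # (F,)
    mt_lengths: np.ndarray     # (F, M)
    mt_growing: np.ndarray     # (F, M) uint8
    mt_engaged: np.ndarray     # (F, M) uint8
    interpolar_fraction: np.ndarray  # (F,)
    xl_counts: np.ndarray      # (F, 3) free / one-bound / two-bound

    def frame_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "separation": self.separation,
            "interpolar_fraction": self.interpolar_fraction,
            "mean_mt_length": self.mt_lengths.mean(axis=1),
            "n_free": self.xl_counts[:, 0],
            "n_one_bound": self.xl_counts[:, 1],
            "n_two_bound": self.xl_counts[:, 2],
        })

    def save_csv(self, path) -> None:
        self.frame_dataframe().to_csv(path, index=False)

    def save_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.create_dataset(f.name, data=getattr(self, f.name))


@dataclass
class RunSummary:
    """Per-run observables and the bipolarity outcome."""

    seed: int
    success: bool
    formation_start_time: float     # s; NaN on failure
    late_time_separation: float     # um, mean over the last 30 s
    mean_mt_length: float           # um, mean over MTs and frames
    final_interpolar_fraction: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def derive_seed(master: int, sample_index: int, replicate: int) -> int:
    """Deterministic, order-independent per-run seed below 2**31."""
    ss = np.random.SeedSequence(master, spawn_key=(sample_index, replicate))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def initialize_side_by_side(params: SimulationParameters,
                            seed: int = 0) -> SystemState:
    """Two adjacent SPBs on the envelope, short inward MTs, free crosslinkers.

    SPB centres sit one SPB diameter apart on the sphere; each nucleates
    ``sites_per_spb`` MTs of the initial length, oriented along the inward
    site normal with a small random tilt; all crosslinkers are free and
    uniformly placed in the envelope interior.
    """
    params = params.validate()
    g = params.geometry
    R = 0.5 * g.envelope_diameter
    if g.spb_diameter >= 0.5 * R:
        # flat-disk approximation needs the SPB small vs envelope curvature
        raise ValidationError(
            f"SPB diameter {g.spb_diameter} too large for an envelope of "
            f"radius {R}")
    rng = np.random.Generator(np.random.PCG64(seed))
    # adjacent SPBs: great-circle chord of one SPB diameter about +z
    half = math.asin(min(0.5 * g.spb_diameter / R, 1.0))
    spb_u = np.array([
        [math.sin(half), 0.0, math.cos(half)],
        [-math.sin(half), 0.0, math.cos(half)]])
    spb_phi = rng.uniform(0.0, 2.0 * math.pi, size=2)
    S = g.sites_per_spb
    M = 2 * S
    mt_spb = np.repeat(np.arange(2), S)
    mt_site = np.tile(np.arange(S), 2)
    state = SystemState(
        params=params, time=0.0, spb_u=spb_u, spb_phi=spb_phi,
        mt_u=np.zeros((M, 3)), mt_len=np.full(M, g.initial_mt_length),
        mt_grow=np.ones(M, dtype=np.uint8), mt_spb=mt_spb, mt_site=mt_site,
        xl_state=np.zeros(params.crosslinkers.number, dtype=np.uint8),
        xl_pos=np.zeros((params.crosslinkers.number, 3)),
        xl_mt=np.zeros((params.crosslinkers.number, 2), dtype=np.int64),
        xl_arc=np.zeros((params.crosslinkers.number, 2)))
    sites = state.nucleation_sites()
    for m in range(M):
        site = sites[mt_spb[m], mt_site[m]]
        inward = -site / np.linalg.norm(site)
        # fan outward from the SPB centre plus a small random tilt
        radial = site - R * spb_u[mt_spb[m]]
        u = inward + 8.0 * radial + 0.15 * rng.standard_normal(3)
        state.mt_u[m] = u / np.linalg.norm(u)
    # free crosslinkers uniform in the sphere
    n = params.crosslinkers.number
    pos = rng.standard_normal((n, 3))
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    pos *= R * rng.random(n)[:, None] ** (1.0 / 3.0)
    state.xl_pos[:] = pos
    return state


def run_simulation(params: SimulationParameters, seed: int,
                   state: SystemState = None
                   ) -> tuple[Trajectory, RunSummary]:
    """Run one full simulation; returns (trajectory, summary).

    The per-step sequence is: deterministic forces -> dynamic-instability
    switching and length update -> crosslinker kinetic Monte Carlo and
    diffusion -> Brownian moves.  Frames are recorded every
    ``frame_interval``; the run ends at ``total_time``.
    """
    params = params.validate()
    ct = params.control
    if state is None:
        state = initialize_side_by_side(params, seed)
    record_every = max(1, round(ct.frame_interval / ct.timestep))
    n_frames_m1 = max(1, round(ct.total_time / ct.frame_interval))
    n_steps = n_frames_m1 * record_every
    F = n_frames_m1 + 1
    M = state.n_mts
    P = K.pack_params(params)
    out_t = np.empty(F)
    out_spb = np.empty((F, 2, 3))
    out_sep = np.empty(F)
    out_len = np.empty((F, M))
    out_grow = np.empty((F, M), dtype=np.uint8)
    out_eng = np.empty((F, M), dtype=np.uint8)
    out_if = np.empty(F)
    out_nb = np.empty((F, 3), dtype=np.int64)
    status = K.run_engine(
        P, seed, n_steps, record_every, params.geometry.sites_per_spb,
        state.spb_u, state.spb_phi, state.mt_u, state.mt_len, state.mt_grow,
        state.mt_spb, state.mt_site, state.xl_state, state.xl_pos,
        state.xl_mt, state.xl_arc,
        out_t, out_spb, out_sep, out_len, out_grow, out_eng, out_if, out_nb)
    if status != 0:
        raise SimulationError(
            f"non-finite force encountered (seed={seed}); state at abort "
            f"retained on the passed-in SystemState for diagnosis")
    state.time = float(out_t[-1])
    traj = Trajectory(times=out_t, spb_positions=out_spb, separation=out_sep,
                      mt_lengths=out_len, mt_growing=out_grow,
                      mt_engaged=out_eng, interpolar_fraction=out_if,
                      xl_counts=out_nb)
    if ct.total_time >= 120.0:
        success, start = classify_success(out_if, ct.frame_interval)
    else:  # too short to classify bipolarity
        success, start = False, float("nan")
    summary = RunSummary(
        seed=seed, success=bool(success), formation_start_time=float(start),
        late_time_separation=late_time_separation(traj),
        mean_mt_length=float(out_len.mean()) if M > 0 else float("nan"),
        final_interpolar_fraction=float(out_if[-1]))
    return traj, summary


def _scan_record_path(out_dir, index: int) -> str:
    return os.path.join(out_dir, f"sample_{index:05d}.json")


def run_parameter_scan(ranges: SamplingRanges, n_sets: int, replicates: int,
                       stabilization_enabled: bool, seed: int,
                       base: SimulationParameters = None,
                       out_dir=None, progress: bool = False
                       ) -> list[ParameterSample]:
    """Random-sampling study: ``n_sets`` parameter sets x ``replicates`` runs.

    Per-replicate seeds derive from (seed, sample index, replicate index),
    so the scan is order-independent.  With ``out_dir`` set, each completed
    sample is written incrementally to ``sample_NNNNN.json`` (plus the
    resolved base config), and samples already present on disk are loaded
    instead of re-run, which makes an interrupted scan resumable with
    results identical to an uninterrupted one.  A replicate that fails
    numerically is logged and counted as an assembly failure.
    """
    if n_sets < 1 or replicates < 1:
        raise ValidationError("n_sets and replicates must be >= 1")
    samples = sample_parameter_sets(ranges, n_sets, seed,
                                    stabilization_enabled, base=base)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        if base is not None:
            write_config(base, os.path.join(out_dir, "base_config.yaml"))
    for s in samples:
        if out_dir is not None:
            path = _scan_record_path(out_dir, s.index)
            if os.path.exists(path):
                with open(path) as fh:
                    rec = json.load(fh)
                s.outcomes = [RunSummary(**o) for o in rec["outcomes"]]
                continue
        for rep in range(replicates):
            run_seed = derive_seed(seed, s.index, rep)
            try:
                _, summary = run_simulation(s.params, run_seed)
            except SimulationError:
                summary = RunSummary(seed=run_seed, success=False,
                                     formation_start_time=float("nan"),
                                     late_time_separation=float("nan"),
                                     mean_mt_length=float("nan"),
                                     final_interpolar_fraction=float("nan"))
            s.outcomes.append(summary)
        if out_dir is not None:
            with open(_scan_record_path(out_dir, s.index), "w") as fh:
                json.dump({"index": s.index, "sampled": s.sampled,
                           "outcomes": [o.to_dict() for o in s.outcomes]},
                          fh)
        if progress:
            print(f"sample {s.index + 1}/{n_sets}: "
                  f"{sum(o.success for o in s.outcomes)}/{replicates} "
                  "successes", flush=True)
    return samples


#: parameters addressable by run_single_parameter_sweep
SWEEPABLE = {
    "n_crosslinkers": ("crosslinkers", "number"),
    "wall_force": ("wall_force", "asymptotic_force"),
    "catastrophe_frequency": ("dynamic_instability", "catastrophe_frequency"),
    "rescue_frequency": ("dynamic_instability", "rescue_frequency"),
    "rescue_factor": ("stabilization", "rescue_factor"),
    "shrink_factor": ("stabilization", "shrink_factor"),
}


def run_single_parameter_sweep(parameter: str, values, replicates: int,
                               seed: int, base: SimulationParameters = None,
                               progress: bool = False) -> pd.DataFrame:
    """Vary one parameter over ``values``, all others at reference values.

    Returns a table with one row per value: success fraction and the mean
    late-time SPB separation over successful replicates (over all
    replicates in ``mean_separation_all``).
    """
    if parameter not in SWEEPABLE:
        raise ValidationError(
            f"unknown sweep parameter {parameter!r}; "
            f"choose from {sorted(SWEEPABLE)}")
    if base is None:
        base = build_reference_params()
    section, attr = SWEEPABLE[parameter]
    rows = []
    for iv, v in enumerate(values):
        p = base.copy()
        setattr(getattr(p, section), attr,
                int(round(v)) if parameter == "n_crosslinkers" else float(v))
        p.validate()
        outcomes = []
        for rep in range(replicates):
            run_seed = derive_seed(seed, iv, rep)
            try:
                _, summary = run_simulation(p, run_seed)
            except SimulationError:
                continue
            outcomes.append(summary)
        succ = [o for o in outcomes if o.success]
        rows.append({
            parameter: v,
            "n_replicates": len(outcomes),
            "success_fraction": (len(succ) / len(outcomes)
                                 if outcomes else np.nan),
            "mean_separation": (np.mean([o.late_time_separation
                                         for o in succ])
                                if succ else np.nan),
            "mean_separation_all": (np.mean([o.late_time_separation
                                             for o in outcomes])
                                    if outcomes else np.nan),
        })
        if progress:
            print(f"{parameter}={v}: {len(succ)}/{len(outcomes)} successes",
                  flush=True)
    return pd.DataFrame(rows)
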