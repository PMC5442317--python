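"""Observables and the bipolar-spindle success criterion.

The order parameter for bipolarity is the interpolar fraction (IF): the
fraction of spindle MTs currently engaged in at least one antiparallel
crosslink with an MT of the opposite pole.  A run is a successful bipolar
spindle if its IF exceeds 0.2 continuously (allowing brief dips) for at
least two minutes and lasting to the end of the simulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def interpolar_fraction(obj) -> float:
    """Fraction of MTs crosslinked to an MT of the opposite SPB, in [0, 1].

    Accepts a :class:`~spindlesim.geometry.SystemState`; engagement means
    at least one doubly bound crosslinker connecting the MT to an MT whose
    parent SPB differs.
    """
    n = obj.n_mts
    if n == 0:
        return 0.0
    engaged = np.zeros(n, dtype=bool)
    for i in np.nonzero(obj.xl_state == 2)[0]:
        m0, m1 = obj.xl_mt[i]
        if obj.mt_spb[m0] != obj.mt_spb[m1]:
            engaged[m0] = True
            engaged[m1] = True
    return float(engaged.sum()) / n


def classify_success(if_series, frame_interval: float,
                     threshold: float = 0.2, min_duration: float = 120.0,
                     max_dip: float = 12.0) -> tuple[bool, float]:
    """Apply the bipolarity success criterion to an IF time series.

    Success iff there is a crossing above ``threshold`` after which the IF
    stays above threshold until the end of the series for at least
    ``min_duration`` seconds, where individual sub-threshold dips of up to
    ``max_dip`` seconds each are tolerated (the duration clock is not reset
    by a tolerated dip).  Returns ``(success, formation_start_time)``;
    the start time is the first crossing of the qualifying epoch (NaN on
    failure).
    """
    f = np.asarray(if_series, dtype=float)
    n = f.size
    total = (n - 1) * frame_interval
    if total < min_duration:
        raise ValueError(
            f"series spans {total:.1f} s < the {min_duration:.0f} s "
            "required for classification")
    above = f > threshold
    # first index of each candidate epoch: an above-threshold frame from
    # which every below-threshold excursion to the end lasts <= max_dip
    max_dip_frames = int(max_dip / frame_interval)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        # scan dips from i to the end
        ok = True
        j = i
        while j < n:
            if above[j]:
                j += 1
                continue
            k = j
            while k < n and not above[k]:
                k += 1
            if (k - j) > max_dip_frames:
                ok = False
                break
            j = k
        if ok:
            start = i * frame_interval
            if total - start >= min_duration:
                return True, start
            return False, float("nan")
        i = j  # restart after the disqualifying dip
    return False, float("nan")


def late_time_separation(trajectory, window: float = 30.0) -> float:
    """Mean SPB separation (um) over the last ``window`` seconds of a run."""
    t = np.asarray(trajectory.times)
    sep = np.asarray(trajectory.separation)
    mask = t >= t[-1] - window
    return float(sep[mask].mean())


def aggregate_scan(samples) -> pd.DataFrame:
    """Summarize a list of ParameterSample with replicate outcomes.

    One row per sample: the sampled parameter values, replicate count,
    success fraction, and mean +/- s.d. of late-time separation over the
    successful replicates (NaN when no replicate succeeded).  The overall
    success percentage is stored in ``df.attrs['overall_success_percent']``.
    """
    rows = []
    n_runs = 0
    n_succ = 0
    for s in samples:
        succ = [o for o in s.outcomes if o.success]
        n_runs += len(s.outcomes)
        n_succ += len(succ)
        seps = np.array([o.late_time_separation for o in succ])
        row = dict(sample=s.index, **s.sampled)
        row["n_replicates"] = len(s.outcomes)
        row["success_fraction"] = (len(succ) / len(s.outcomes)
                                   if s.outcomes else np.nan)
        row["mean_separation"] = seps.mean() if len(succ) else np.nan
        row["sd_separation"] = seps.std(ddof=1) if len(succ) > 1 else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["overall_success_percent"] = (
        100.0 * n_succ / n_runs if n_runs else np.nan)
    return df
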