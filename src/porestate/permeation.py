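"""Directional permeation counting, occupancy maps and conductance arithmetic.

A water (or ion) passage scores one event under a two-plane hysteresis rule:
the counter arms when the particle crosses the entry plane in the stated
direction, fires when it reaches the exit plane, and disarms if it re-crosses
the entry plane backwards first.  Partial excursions that dip past the entry
plane but return before reaching the exit plane therefore score nothing, and
a completed passage cannot double-count.  Plane crossings are detected by
sign change between consecutive samples, so a passage that jumps both planes
within one stride still scores.  Displacements larger than a wrap threshold
(default 25 A, far above any physical per-stride motion) are treated as
periodic-boundary re-entry into the reservoir and reset the state machine.

Default planes follow the equilibrium water-counting convention: entry at
z = -6 A, exit at z = -16 A for downward flow, with density maps accumulated
over -45 A < z < 10 A.  Ion counts under an applied voltage convert to
conductance as G = N q e / (T V).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ParticleTraceSet

__all__ = [
    "CrossingLedger", "count_crossings", "permeation_rate",
    "RecalibrationFit", "interval_recalibration",
    "OccupancyMap", "occupancy_map", "open_intervals",
    "conductance_from_counts",
]

_E_CHARGE = 1.602176634e-19  # C


@dataclass
class CrossingLedger:
    """Completed directional passages with interpolated entry/exit times."""
    events: pd.DataFrame          # particle, direction, entry_time_ps, exit_time_ps
    total_time_ns: float
    entry_z: float
    exit_z: float
    direction: str = "down"

    @property
    def n_events(self) -> int:
        return len(self.events)


def _as_matrix(traces, times_ps):
    if isinstance(traces, ParticleTraceSet):
        return traces.z, traces.times_ps, traces.z.shape[1] * traces.stride_ps / 1000.0
    z = np.atleast_2d(np.asarray(traces, dtype=float))
    t = np.asarray(times_ps, dtype=float)
    if t.ndim != 1 or len(t) != z.shape[1]:
        raise ValueError("times_ps must match the trace length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("trace times must be strictly increasing")
    total = (t[-1] - t[0]) + (t[1] - t[0] if len(t) > 1 else 0.0)
    return z, t, total / 1000.0


def count_crossings(traces, entry_z: float = -6.0, exit_z: float = -16.0,
                    direction: str = "down", times_ps=None,
                    wrap_threshold: float = 25.0) -> CrossingLedger:
    """Count completed plane-to-plane passages in each trace.

    ``traces`` is a :class:`ParticleTraceSet` or a (n_particles, n_samples)
    array with ``times_ps``.  For ``direction='down'`` the entry plane must
    be above the exit plane; for ``'up'`` below it.
    """
    if entry_z == exit_z:
        raise ValueError("entry and exit planes must differ")
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    if direction == "down" and entry_z <= exit_z:
        raise ValueError("downward counting needs entry_z > exit_z")
    if direction == "up" and entry_z >= exit_z:
        raise ValueError("upward counting needs entry_z < exit_z")

    z, t, total_ns = _as_matrix(traces, times_ps)
    # y > 1: outside the entry plane; 0 < y <= 1: between; y <= 0: past exit
    y = (z - exit_z) / (entry_z - exit_z)
    region = np.full(y.shape, 1, dtype=np.int8)
    region[y > 1.0] = 0
    region[y <= 0.0] = 2
    wrap = np.abs(np.diff(z, axis=1)) > wrap_threshold
    change = (np.diff(region, axis=1) != 0) | wrap
    rows, cols = np.nonzero(change)

    events = []
    armed = {}
    prev_row = -1
    for r, k in zip(rows, cols):
        if r != prev_row:
            armed.clear()
            prev_row = r
        if wrap[r, k]:
            armed.pop(r, None)
            continue
        r_old, r_new = region[r, k], region[r, k + 1]
        if r_new == r_old:
            continue
        if r_old == 0 and r_new >= 1:
            # crossed the entry plane in the counting direction: arm
            frac = (y[r, k] - 1.0) / (y[r, k] - y[r, k + 1])
            armed[r] = t[k] + frac * (t[k + 1] - t[k])
        if r_new == 2 and r in armed:
            frac = y[r, k] / (y[r, k] - y[r, k + 1])
            exit_t = t[k] + frac * (t[k + 1] - t[k])
            events.append((r, direction, armed.pop(r), exit_t))
        elif r_new == 0:
            armed.pop(r, None)

    df = pd.DataFrame(events, columns=["particle", "direction",
                                       "entry_time_ps", "exit_time_ps"])
    return CrossingLedger(events=df, total_time_ns=total_ns,
                          entry_z=entry_z, exit_z=exit_z, direction=direction)


def permeation_rate(ledger: CrossingLedger, blocks=None):
    """Events per nanosecond, whole-trace or in repeated blocks.

    ``blocks=(length_ns, spacing_ns)`` returns one rate per block (default
    convention: 40-ns blocks every 200 ns); ``blocks=None`` returns the
    single whole-trace rate.  Block rates come back as a DataFrame.
    """
    if ledger.total_time_ns <= 0:
        raise ValueError("ledger has zero duration")
    if blocks is None:
        return ledger.n_events / ledger.total_time_ns
    length_ns, spacing_ns = blocks
    if length_ns <= 0 or spacing_ns <= 0:
        raise ValueError("block length and spacing must be positive")
    t_exit = ledger.events["exit_time_ps"].to_numpy() / 1000.0
    starts = np.arange(0.0, ledger.total_time_ns - length_ns + 1e-9, spacing_ns)
    rows = []
    for s in starts:
        n = int(np.sum((t_exit >= s) & (t_exit < s + length_ns)))
        rows.append({"block_start_ns": s, "events": n, "rate_per_ns": n / length_ns})
    return pd.DataFrame(rows)


@dataclass
class RecalibrationFit:
    """OLS map from coarse-stride counts to fine-stride counts.

    The through-origin slope is reported alongside the intercept fit because
    the functional form of the snapshot-interval recalibration is a free
    choice."""
    slope: float
    intercept: float
    r_squared: float
    slope_through_origin: float


def interval_recalibration(fine_counts, coarse_counts) -> RecalibrationFit:
    """Regress matched-segment fine-stride counts on coarse-stride counts.

    Rapid passages are missed at a coarse snapshot cadence; a linear map
    fitted on matched segments recalibrates coarse counts to the
    fine-equivalent scale.  Requires >= 3 segments and nonconstant
    coarse counts.
    """
    fine = np.asarray(fine_counts, dtype=float)
    coarse = np.asarray(coarse_counts, dtype=float)
    if fine.shape != coarse.shape or fine.ndim != 1:
        raise ValueError("fine and coarse counts must be matched 1-D vectors")
    if len(fine) < 3:
        raise ValueError("need at least 3 matched segments")
    if np.std(coarse) < 1e-12:
        raise ValueError("coarse counts have zero variance")
    res = stats.linregress(coarse, fine)
    s0 = float(np.dot(coarse, fine) / np.dot(coarse, coarse))
    return RecalibrationFit(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2),
                            slope_through_origin=s0)


@dataclass
class OccupancyMap:
    """Particle counts binned in (z, time)."""
    z_edges: np.ndarray
    t_edges_ns: np.ndarray
    counts: np.ndarray            # (n_z_bins, n_t_bins)

    @property
    def z_centres(self):
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])


def occupancy_map(z, times_ps, z_range=(-45.0, 10.0), z_bin: float = 1.0,
                  time_bin_ns: float = 1.0, xy=None,
                  cylinder_radius: float = 5.0) -> OccupancyMap:
    """Histogram particle samples over axial position and time.

    ``z`` is (n_particles, n_samples); when lateral coordinates ``xy``
    (n_particles, n_samples, 2) are given, only samples inside the stated
    cylinder about the pore axis are counted.  The column sums reproduce the
    per-time-bin in-cylinder sample totals exactly.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    t = np.asarray(times_ps, dtype=float) / 1000.0
    if z.shape[1] != len(t) or len(t) == 0:
        raise ValueError("empty frame range or mismatched times")
    mask = np.ones_like(z, dtype=bool)
    if xy is not None:
        xy = np.asarray(xy, dtype=float)
        mask &= np.hypot(xy[..., 0], xy[..., 1]) <= cylinder_radius
    n_z = int(np.ceil((z_range[1] - z_range[0]) / z_bin - 1e-9))
    n_t = int(np.floor((t[-1] - t[0]) / time_bin_ns + 1e-9)) + 1
    z_edges = z_range[0] + np.arange(n_z + 1) * z_bin
    t_edges = t[0] + np.arange(n_t + 1) * time_bin_ns
    # direct floor indexing (with a small slack) keeps samples that sit on a
    # bin boundary in a deterministic cell and conserves totals
    iz = np.floor((z - z_range[0]) / z_bin + 1e-9).astype(int)
    it = np.floor((np.broadcast_to(t, z.shape) - t[0]) / time_bin_ns
                  + 1e-9).astype(int)
    mask &= (iz >= 0) & (iz < n_z) & (it >= 0) & (it < n_t)
    counts = np.zeros((n_z, n_t))
    np.add.at(counts, (iz[mask], it[mask]), 1.0)
    return OccupancyMap(z_edges=z_edges, t_edges_ns=t_edges, counts=counts)


def open_intervals(occ: OccupancyMap, gate_window):
    """Maximal time intervals during which every z-cell of the gate window is
    occupied, plus the total open time in ns."""
    lo, hi = gate_window
    zc = occ.z_centres
    rows = (zc >= lo) & (zc <= hi)
    if not np.any(rows):
        raise ValueError(f"gate window {gate_window} outside the map range")
    open_t = np.all(occ.counts[rows] >= 1, axis=0)
    intervals = []
    start = None
    for j, o in enumerate(open_t):
        if o and start is None:
            start = occ.t_edges_ns[j]
        elif not o and start is not None:
            intervals.append((start, occ.t_edges_ns[j]))
            start = None
    if start is not None:
        intervals.append((start, occ.t_edges_ns[-1]))
    total = float(sum(b - a for a, b in intervals))
    return intervals, total


def conductance_from_counts(n_events: int, charge: float, total_time_ns: float,
                            voltage_mv: float) -> float:
    """Single-channel conductance in pS from permeation counts.

    G = N q e / (T V): N events of ``charge`` elementary charges in
    ``total_time_ns`` under ``voltage_mv`` of applied potential.
    """
    if total_time_ns <= 0:
        raise ValueError("total time must be positive")
    if voltage_mv == 0:
        raise ValueError("voltage must be nonzero")
    amps = n_events * charge * _E_CHARGE / (total_time_ns * 1e-9)
    return amps / (voltage_mv * 1e-3) * 1e12
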