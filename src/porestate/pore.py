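"""Pore-radius profiling along the channel axis and conductance classification.

At each axial position z the pore radius is the radius of the largest sphere,
centred anywhere in the perpendicular plane within a lateral search bound,
that touches no atom: radius = max over centres of [min over atoms of
(distance to atom centre - atom van der Waals radius)].  The centre search is
a deterministic 2-D grid refined by a Nelder-Mead polish, so repeated runs
give identical profiles.

The minimum radius over the gate window feeds the threshold rule that sorts
structures into conductance classes: non-conducting C when R_min <= 1.4 A
(the radius of a water molecule), the first open level O1 when
1.4 A < R_min <= 2.3 A, and O2 when R_min > 2.3 A.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .io import StructureModel

log = logging.getLogger(__name__)

__all__ = [
    "BONDI_RADII", "RadiusStateRule", "PoreProfile",
    "pore_radius_profile", "gate_filter_windows", "classify_conductance",
]

# Bondi van der Waals radii (Angstrom)
BONDI_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
               "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
               "K": 2.75, "NA": 2.27}
_DEFAULT_VDW = 1.70


@dataclass
class RadiusStateRule:
    """Radius thresholds separating the conductance classes (Angstrom)."""
    water_radius: float = 1.4
    o1_upper: float = 2.3

    def __post_init__(self):
        if not (0.0 < self.water_radius < self.o1_upper):
            raise ValueError("thresholds must satisfy 0 < water_radius < o1_upper")


@dataclass
class PoreProfile:
    """Pore radius as a function of the axial coordinate."""
    z: np.ndarray
    radius: np.ndarray
    rmin_gate: float | None = None
    rmin_filter: float | None = None
    gate_window: tuple | None = None
    filter_window: tuple | None = None
    capped: bool = False

    def rmin(self, window) -> float:
        lo, hi = window
        m = (self.z >= lo) & (self.z <= hi)
        if not np.any(m):
            raise ValueError(f"window {window} outside the profiled range")
        return float(np.min(self.radius[m]))


def _vdw_radii(model: StructureModel, vdw_table=None) -> np.ndarray:
    if model.vdw is not None:
        return model.vdw
    table = vdw_table or BONDI_RADII
    return np.array([table.get(str(e).upper(), _DEFAULT_VDW)
                     for e in model.element])


def _clearance(centres: np.ndarray, atoms: np.ndarray, vdw: np.ndarray) -> np.ndarray:
    """min over atoms of (|centre - atom| - vdw) for each centre."""
    d = np.linalg.norm(centres[:, None, :] - atoms[None, :, :], axis=2) - vdw[None, :]
    return d.min(axis=1)


def pore_radius_profile(model: StructureModel, z_range=None, step: float = 0.25,
                        lateral_bound: float = 2.5, grid_step: float = 0.1,
                        radius_cap: float = 10.0, vdw_table=None,
                        gate_window=None, filter_window=None) -> PoreProfile:
    """Largest-inscribed-sphere radius profile of an aligned structure.

    The model must already be in the gate-centred frame (pore axis on z).
    ``z_range`` defaults to the z-span of the model's C-alpha atoms.  When
    the sphere is locally unbounded (no atoms constrain it) the radius is
    capped at ``radius_cap`` and flagged.
    """
    if step <= 0 or grid_step <= 0:
        raise ValueError("step sizes must be positive")
    vdw = _vdw_radii(model, vdw_table)
    xyz = model.xyz
    if z_range is None:
        ca = model.name == "CA"
        z_range = (float(xyz[ca, 2].min()), float(xyz[ca, 2].max()))
    z_grid = np.arange(z_range[0], z_range[1] + 1e-9, step)

    g = np.arange(-lateral_bound, lateral_bound + 1e-9, grid_step)
    gx, gy = np.meshgrid(g, g)
    plane = np.column_stack([gx.ravel(), gy.ravel()])

    reach = radius_cap + float(vdw.max()) + 1.0
    radii = np.empty(len(z_grid))
    capped = False
    for i, z in enumerate(z_grid):
        slab = np.abs(xyz[:, 2] - z) <= reach
        if not np.any(slab):
            log.warning("no atoms within reach of z = %.2f; radius capped", z)
            radii[i] = radius_cap
            capped = True
            continue
        a, w = xyz[slab], vdw[slab]
        centres = np.column_stack([plane, np.full(len(plane), z)])
        clear = _clearance(centres, a, w)
        j = int(np.argmax(clear))

        # deterministic local polish of the best grid cell, clamped to the
        # lateral search bound so the sphere cannot drift out of the pore
        def neg_clear(p):
            q = np.clip(p, -lateral_bound, lateral_bound)
            return -float(_clearance(np.array([[q[0], q[1], z]]), a, w)[0])

        res = minimize(neg_clear, plane[j], method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200})
        best = max(float(clear[j]), -float(res.fun))
        if best >= radius_cap:
            best = radius_cap
            capped = True
        radii[i] = max(best, 0.0)

    prof = PoreProfile(z=z_grid, radius=radii, capped=capped,
                       gate_window=gate_window, filter_window=filter_window)
    if gate_window is not None:
        prof.rmin_gate = prof.rmin(gate_window)
    if filter_window is not None:
        prof.rmin_filter = prof.rmin(filter_window)
    return prof


def gate_filter_windows(model: StructureModel,
                        gate_residues=(617, 625),
                        filter_residues=(586, 590)):
    """Axial windows for the gate (T617-T625 C-alpha span) and selectivity
    filter (residue 586-590 backbone span) of an aligned structure."""
    ca = model.name == "CA"
    gate = ca & (model.resid >= gate_residues[0]) & (model.resid <= gate_residues[1])
    filt = (np.isin(model.name, ["N", "CA", "C", "O"])
            & (model.resid >= filter_residues[0])
            & (model.resid <= filter_residues[1]))
    if not np.any(gate) or not np.any(filt):
        raise ValueError("gate or filter residues missing from the model")
    gz = model.xyz[gate, 2]
    fz = model.xyz[filt, 2]
    return (float(gz.min()), float(gz.max())), (float(fz.min()), float(fz.max()))


def classify_conductance(rmin_gate: float,
                         rule: RadiusStateRule | None = None) -> str:
    """Threshold classification of the gate minimum radius.

    C when R_min <= water radius (1.4 A), O1 when in (1.4, 2.3] A,
    O2 when above 2.3 A.  Boundaries are inclusive on the lower class.
    """
    rule = rule or RadiusStateRule()
    if rmin_gate < 0:
        raise ValueError("a pore radius cannot be negative")
    if rmin_gate <= rule.water_radius:
        return "C"
    if rmin_gate <= rule.o1_upper:
        return "O1"
    return "O2"
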