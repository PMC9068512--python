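"""Per-frame geometric descriptors of the channel gate and LBD layer.

The descriptors mirror what the conformational clustering consumes: T617 chi1
side-chain dihedrals (atoms N-CA-CB-OG1, IUPAC sign), cross-tetramer C-alpha
distances at T625/T617, quadrilateral pore areas at the T617/A621/T625 rings,
the M3 bend angle at the A618 hinge, backbone RMSD of the gate residues
S614-T625 (atoms C, O, N, CA, CB) after optimal superposition, and clamshell
metrics of the ligand-binding domains (closure angle alpha, d635 separation,
horizontal L and vertical H positions of the D2 lobes).

Angles are encoded for clustering as (sin, cos) pairs with a joint scale that
gives every feature - distance or angle - unit total variance, so periodic
quantities never tear across the +-180 boundary.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geom import (circ_mean_deg, kabsch_rotation, rotation_angle_deg,
                    superposed_rmsd, unit)
from .io import SelectionError, StructureModel, select_atoms

log = logging.getLogger(__name__)

__all__ = [
    "dihedral", "cross_distance", "gate_rmsd", "bend_angle", "pore_area",
    "LbdConfig", "LbdMetrics", "lbd_metrics",
    "FeatureScaler", "compute_gate_features",
]


class DihedralError(ValueError):
    """The four points do not define a dihedral (collinear middle bond)."""


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC convention: looking down the p2->p3 bond, the angle is positive
    when the far bond is rotated clockwise from the near bond.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-10:
            raise DihedralError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DihedralError("three consecutive points are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), unit(b2)))
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 else float(ang)


def _atom_xyz(model: StructureModel, chain: str, resid: int, name: str) -> np.ndarray:
    m = ((model.chain == chain) & (model.resid == resid) & (model.name == name))
    idx = np.nonzero(m)[0]
    if idx.size == 0:
        raise SelectionError(f"atom {chain}/{resid}/{name} not found")
    return model.xyz[idx[0]]


def chi1(model: StructureModel, chain: str, resid: int = 617,
         gamma_atom: str = "OG1") -> float:
    """Side-chain chi1 dihedral N-CA-CB-<gamma atom> in degrees."""
    return dihedral(*(_atom_xyz(model, chain, resid, n)
                      for n in ("N", "CA", "CB", gamma_atom)))


def cross_distance(model: StructureModel, resid: int, atom: str = "CA",
                   chain_pair=("A", "C")) -> float:
    """Cross-tetramer Euclidean distance between one atom in each chain."""
    a = _atom_xyz(model, chain_pair[0], resid, atom)
    b = _atom_xyz(model, chain_pair[1], resid, atom)
    return float(np.linalg.norm(a - b))


_GATE_BACKBONE = "resid {lo}-{hi} and name C,O,N,CA,CB"


def gate_rmsd(frame: StructureModel, reference: StructureModel,
              residues=(614, 625), atoms=("C", "O", "N", "CA", "CB")) -> float:
    """Backbone RMSD of the gate residues after optimal rigid superposition."""
    spec = f"resid {residues[0]}-{residues[1]} and name {','.join(atoms)}"
    ia = select_atoms(frame, spec)
    ib = select_atoms(reference, spec)
    if len(ia) != len(ib):
        raise ValueError("frame and reference select different atom sets")
    return superposed_rmsd(frame.xyz[ia], reference.xyz[ib])


def _fit_direction(points: np.ndarray) -> np.ndarray:
    """Principal direction of a run of points, signed from first to last."""
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    d = vt[0]
    if np.dot(d, points[-1] - points[0]) < 0:
        d = -d
    return d


def bend_angle(model: StructureModel, chain: str, hinge_residue: int = 618,
               below_range=(614, 618), above_range=(618, 625)) -> float:
    """Kink angle of the M3 marker chain at the gating hinge, in degrees.

    Best-fit axes are computed for the C-alpha runs below and above the hinge
    (both directed towards increasing residue number); the bend is the angle
    between them, so a straight helix scores ~0 degrees.
    """
    def run(lo, hi):
        m = ((model.chain == chain) & (model.name == "CA")
             & (model.resid >= lo) & (model.resid <= hi))
        pts = model.xyz[m][np.argsort(model.resid[m])]
        if len(pts) < 3:
            raise ValueError(
                f"need >= 3 C-alpha atoms in residues {lo}-{hi} of chain {chain}")
        return pts

    d_lo = _fit_direction(run(*below_range))
    d_hi = _fit_direction(run(*above_range))
    c = np.clip(np.dot(d_lo, d_hi), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def pore_area(model: StructureModel, resid: int, axis=(0.0, 0.0, 1.0),
              chains=("A", "B", "C", "D")) -> float:
    """Area (A^2) of the quadrilateral through the four C-alpha atoms of a
    ring residue, projected onto the plane normal to the pore axis, with
    vertices ordered by azimuth (input order therefore does not matter)."""
    pts = np.array([_atom_xyz(model, c, resid, "CA") for c in chains])
    ez = unit(np.asarray(axis, dtype=float))
    # orthonormal basis of the projection plane
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, ez)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    ex = unit(ref - np.dot(ref, ez) * ez)
    ey = np.cross(ez, ex)
    uv = np.column_stack([pts @ ex, pts @ ey])
    uv = uv - uv.mean(axis=0)
    order = np.argsort(np.arctan2(uv[:, 1], uv[:, 0]))
    uv = uv[order]
    x, y = uv[:, 0], uv[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


# ---------------------------------------------------------------------------
# LBD clamshell metrics
# ---------------------------------------------------------------------------

@dataclass
class LbdConfig:
    """Residue partition of the LBD clamshell and the dimer pairing.

    ``d1_ranges`` / ``d2_ranges`` are lists of inclusive residue ranges for
    the upper (D1) and lower (D2) lobes; ``dimer_pairs`` names the chains of
    each back-to-back LBD dimer; ``d635_residue`` is the D2 marker whose
    C-alpha separation within a dimer reports lobe splaying."""
    d1_ranges: list = field(default_factory=lambda: [(394, 495), (732, 772)])
    d2_ranges: list = field(default_factory=lambda: [(496, 731)])
    dimer_pairs: tuple = (("A", "D"), ("C", "B"))
    d635_residue: int = 635


@dataclass
class LbdMetrics:
    alpha: dict        # chain -> clamshell closure angle vs apo reference, deg
    d635: dict         # dimer pair -> CA-CA distance, Angstrom
    L: dict            # chain -> horizontal distance of D2 COM from 2-fold axis
    H: dict            # chain -> z of D2 COM in the gate frame


def _range_ca(model: StructureModel, chain: str, ranges) -> np.ndarray:
    m = (model.chain == chain) & (model.name == "CA")
    sel = np.zeros(model.n_atoms, dtype=bool)
    for lo, hi in ranges:
        sel |= m & (model.resid >= lo) & (model.resid <= hi)
    idx = np.nonzero(sel)[0]
    if idx.size < 3:
        raise SelectionError(f"fewer than 3 CA atoms for chain {chain} in {ranges}")
    return model.xyz[idx[np.argsort(model.resid[idx])]]


def lbd_metrics(model: StructureModel, apo_reference: StructureModel,
                config: LbdConfig | None = None,
                chains=("A", "B", "C", "D")) -> LbdMetrics:
    """Clamshell closure angle and D2-lobe geometry per subunit.

    alpha is measured per subunit as the rigid rotation of the D2 lobe that
    remains after superposing the subunit's D1 lobe onto the apo reference's
    D1: an apo-identical model scores 0 degrees for every subunit.
    """
    cfg = config or LbdConfig()
    alpha, L, H = {}, {}, {}
    for ch in chains:
        d1_m = _range_ca(model, ch, cfg.d1_ranges)
        d1_r = _range_ca(apo_reference, ch, cfg.d1_ranges)
        d2_m = _range_ca(model, ch, cfg.d2_ranges)
        d2_r = _range_ca(apo_reference, ch, cfg.d2_ranges)
        if len(d1_m) != len(d1_r) or len(d2_m) != len(d2_r):
            raise ValueError(f"model/reference LBD atom counts differ in chain {ch}")
        # superpose model D1 onto reference D1, carry D2 along
        R1 = kabsch_rotation(d1_m, d1_r)
        d2_moved = (d2_m - d1_m.mean(axis=0)) @ R1.T + d1_r.mean(axis=0)
        # residual D2 rotation relative to the reference D2
        R2 = kabsch_rotation(d2_moved, d2_r)
        alpha[ch] = rotation_angle_deg(R2)
        com = d2_m.mean(axis=0)
        L[ch] = float(np.hypot(com[0], com[1]))
        H[ch] = float(com[2])
    d635 = {}
    for c1, c2 in cfg.dimer_pairs:
        a = _atom_xyz(model, c1, cfg.d635_residue, "CA")
        b = _atom_xyz(model, c2, cfg.d635_residue, "CA")
        d = float(np.linalg.norm(a - b))
        if d <= 0:
            raise ValueError("coincident d635 markers")
        d635[f"{c1}{c2}"] = d
    return LbdMetrics(alpha=alpha, d635=d635, L=L, H=H)


# ---------------------------------------------------------------------------
# equal-weight encoding of mixed angle/distance features
# ---------------------------------------------------------------------------

class FeatureScaler:
    """Encode a mixed table of distances and angles for clustering.

    Distances are standardised to unit variance.  Each angle column becomes a
    (sin, cos) pair scaled by a single factor chosen so the pair's total
    variance is 1, which weights angles and distances equally while keeping
    the encoding invertible (atan2 of the pair recovers the angle).
    Zero-variance columns are dropped with a warning.
    """

    def __init__(self, angle_cols=()):
        self.angle_cols = list(angle_cols)
        self.stats_: dict | None = None

    def fit(self, df: pd.DataFrame) -> "FeatureScaler":
        stats = {"cols": [], "dropped": []}
        for col in df.columns:
            x = df[col].to_numpy(dtype=float)
            if col in self.angle_cols:
                s, c = np.sin(np.radians(x)), np.cos(np.radians(x))
                v = float(np.var(s) + np.var(c))
                if v < 1e-12:
                    stats["dropped"].append(col)
                    continue
                stats["cols"].append((col, "angle",
                                      (1.0 / np.sqrt(v),
                                       float(np.mean(s)), float(np.mean(c)))))
            else:
                sd = float(np.std(x))
                if sd < 1e-12:
                    stats["dropped"].append(col)
                    continue
                stats["cols"].append((col, "dist", (float(np.mean(x)), sd)))
        for col in stats["dropped"]:
            warnings.warn(f"feature column {col!r} has zero variance and was dropped",
                          stacklevel=2)
            log.warning("dropped zero-variance feature column %r", col)
        self.stats_ = stats
        return self

    def transform(self, df: pd.DataFrame):
        """Return (X, column_names) with angles as scaled (sin, cos) pairs."""
        if self.stats_ is None:
            raise RuntimeError("fit the scaler before transforming")
        cols, names = [], []
        for col, kind, p in self.stats_["cols"]:
            x = df[col].to_numpy(dtype=float)
            if kind == "angle":
                scale, ms, mc = p
                cols.append((np.sin(np.radians(x)) - ms) * scale)
                cols.append((np.cos(np.radians(x)) - mc) * scale)
                names.extend([f"{col}:sin", f"{col}:cos"])
            else:
                mu, sd = p
                cols.append((x - mu) / sd)
                names.append(col)
        return np.column_stack(cols), names

    def fit_transform(self, df: pd.DataFrame):
        return self.fit(df).transform(df)

    def decode_angle(self, X: np.ndarray, names, col: str) -> np.ndarray:
        """Recover an angle column (degrees) from the encoded matrix."""
        i, j = names.index(f"{col}:sin"), names.index(f"{col}:cos")
        scale, ms, mc = dict((c, p) for c, k, p in self.stats_["cols"])[col]
        s = X[:, i] / scale + ms
        c = X[:, j] / scale + mc
        return np.degrees(np.arctan2(s, c))


def compute_gate_features(frames, reference: StructureModel | None = None,
                          chains=("A", "B", "C", "D")) -> pd.DataFrame:
    """Per-frame gate descriptor table for a FrameSeries.

    Columns: chi1_<chain>, d625_AC, d625_BD, d617_AC, area_617, area_621,
    area_625, bend_<chain>, gate_rmsd.  The RMSD reference defaults to the
    first frame.
    """
    rows = []
    ref = reference if reference is not None else frames.frame(0)
    for m in frames:
        row = {}
        for ch in chains:
            row[f"chi1_{ch}"] = chi1(m, ch)
        row["d625_AC"] = cross_distance(m, 625, chain_pair=("A", "C"))
        row["d625_BD"] = cross_distance(m, 625, chain_pair=("B", "D"))
        row["d617_AC"] = cross_distance(m, 617, chain_pair=("A", "C"))
        for r in (617, 621, 625):
            row[f"area_{r}"] = pore_area(m, r, chains=chains)
        for ch in chains:
            row[f"bend_{ch}"] = bend_angle(m, ch)
        row["gate_rmsd"] = gate_rmsd(m, ref)
        rows.append(row)
    return pd.DataFrame(rows)


GATE_ANGLE_COLUMNS = ("chi1_A", "chi1_B", "chi1_C", "chi1_D")
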