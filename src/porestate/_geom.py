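"""Internal geometry primitives shared across modules.

Coordinate arrays are float64 numpy arrays in Angstrom; angles are degrees
unless a name says otherwise.
"""
from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a near-zero vector")
    return v / n


def wrap_deg(a):
    """Wrap angle(s) to the interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -((( -a + 180.0) % 360.0) - 180.0)
    return w if w.ndim else float(w)


def circ_mean_deg(angles) -> float:
    a = np.radians(np.asarray(angles, dtype=float))
    return float(np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))))


def circ_sd_deg(angles) -> float:
    """Circular standard deviation sqrt(-2 ln Rbar), returned in degrees."""
    a = np.radians(np.asarray(angles, dtype=float))
    rbar = np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a)))
    if rbar <= 0.0:
        return float("inf")
    rbar = min(rbar, 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(rbar))))


def circ_diff_deg(a, b):
    """Signed circular difference a - b in (-180, 180]."""
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def place_zmatrix(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                  bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d so that |d-c| = bond, angle(b,c,d) = angle_deg and the
    torsion a-b-c-d equals torsion_deg (IUPAC sign convention).
    """
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d = bond * (-np.cos(ang) * bc
                + np.sin(ang) * (np.cos(tor) * m + np.sin(tor) * n))
    return c + d


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimising |R (P-Pc) - (Q-Qc)|."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superposed_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD between point sets after optimal rigid superposition."""
    if P.shape != Q.shape:
        raise ValueError("point sets must have identical shape")
    R = kabsch_rotation(P, Q)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    d = (R @ Pc.T).T - Qc
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def rotation_angle_deg(R: np.ndarray) -> float:
    """Angle of a proper rotation matrix, in degrees, in [0, 180]."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def minimal_rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Rotation with the smallest angle mapping unit vector v onto +z."""
    v = unit(np.asarray(v, dtype=float))
    ez = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, ez))
    axis = np.cross(v, ez)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about x
        return np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)
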