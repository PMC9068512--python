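"""Structure and trajectory I/O, atom selection and gate-frame alignment.

Structures are read with gemmi (PDB and mmCIF); the in-memory container is a
flat :class:`StructureModel` of parallel arrays, which is what every geometry
routine in this package consumes.  Multi-model files become a
:class:`FrameSeries`.

Residue numbering is taken verbatim from the file (rat GluA2 numbering in the
deposited structures: gate S614-T625, hinge A618, selectivity filter
586-QQGCD-590).  Chains map to subunit positions A/B/C/D by their chain IDs
unless a mapping is supplied.

The gate-centred coordinate frame places the centre of mass of the reference
residue's C-alpha atoms (T625 by default) at the origin, with the pore axis on
z and the selectivity filter at negative z (extracellular side positive).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._geom import minimal_rotation_to_z

log = logging.getLogger(__name__)

__all__ = [
    "StructureModel", "FrameSeries", "ParseError", "SelectionError",
    "read_structure", "read_frames", "write_pdb", "write_frames",
    "select_atoms", "align_to_gate_origin",
]


class ParseError(ValueError):
    """A structure file could not be parsed into coordinates."""


class SelectionError(ValueError):
    """An atom selection matched nothing or referenced missing atoms."""


# canonical atom-name order used for deterministic selection output
_ATOM_RANK = {n: i for i, n in enumerate(
    ["N", "CA", "C", "O", "CB", "CG", "CG1", "CG2", "OG", "OG1", "SG",
     "CD", "CD1", "CD2", "OD1", "OD2", "ND1", "ND2", "SD",
     "CE", "CE1", "CE2", "NE", "NE1", "NE2", "OE1", "OE2",
     "CZ", "NZ", "OH", "NH1", "NH2"])}


@dataclass
class StructureModel:
    """Flat atom table: chain / residue number / residue name / atom name /
    element and Cartesian positions in Angstrom."""
    chain: np.ndarray          # str array
    resid: np.ndarray          # int array
    resname: np.ndarray        # str array
    name: np.ndarray           # atom-name str array
    element: np.ndarray        # element symbol str array
    xyz: np.ndarray            # (n, 3) float
    vdw: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.resid)

    def subset(self, idx) -> "StructureModel":
        idx = np.asarray(idx)
        return StructureModel(
            chain=self.chain[idx], resid=self.resid[idx],
            resname=self.resname[idx], name=self.name[idx],
            element=self.element[idx], xyz=self.xyz[idx],
            vdw=None if self.vdw is None else self.vdw[idx])

    def with_xyz(self, xyz: np.ndarray) -> "StructureModel":
        return replace(self, xyz=np.asarray(xyz, dtype=float))

    def copy(self) -> "StructureModel":
        return StructureModel(self.chain.copy(), self.resid.copy(),
                              self.resname.copy(), self.name.copy(),
                              self.element.copy(), self.xyz.copy(),
                              None if self.vdw is None else self.vdw.copy())


@dataclass
class FrameSeries:
    """Ordered coordinate frames sharing one topology."""
    topology: StructureModel
    coords: np.ndarray          # (n_frames, n_atoms, 3)
    stride_ps: float = 250.0    # snapshot cadence
    source: str = "equilibrium"

    def __post_init__(self):
        if self.stride_ps <= 0:
            raise ValueError("frame stride must be positive")
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("coords shape does not match topology")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> StructureModel:
        return self.topology.with_xyz(self.coords[i])

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


def _gemmi_model_rows(gmodel, keep_altloc=True):
    rows = []
    for chain in gmodel:
        for res in chain:
            for atom in res:
                rows.append((chain.name, res.seqid.num, res.name,
                             atom.name, atom.element.name,
                             atom.pos.x, atom.pos.y, atom.pos.z,
                             atom.altloc if atom.altloc else "",
                             atom.occ))
    return rows


def _rows_to_model(rows, path=""):
    """Collapse alternate locations to the highest-occupancy conformer."""
    best: dict = {}
    n_alt_records = 0
    order = []
    for r in rows:
        key = (r[0], r[1], r[3])       # chain, resid, atom name
        if r[8]:
            n_alt_records += 1
        if key not in best:
            best[key] = r
            order.append(key)
        else:
            # keep highest occupancy; ties resolved by altloc identifier
            cur = best[key]
            if (r[9], -ord(r[8] or "A")) > (cur[9], -ord(cur[8] or "A")):
                best[key] = r
    n_discarded = len(rows) - len(best)
    if n_discarded:
        log.info("%s: discarded %d alternate-location atom records "
                 "(kept highest occupancy)", path, n_discarded)
    kept = [best[k] for k in order]
    return StructureModel(
        chain=np.array([r[0] for r in kept]),
        resid=np.array([r[1] for r in kept], dtype=int),
        resname=np.array([r[2] for r in kept]),
        name=np.array([r[3] for r in kept]),
        element=np.array([r[4] for r in kept]),
        xyz=np.array([[r[5], r[6], r[7]] for r in kept], dtype=float),
    ), n_discarded


def _read_gemmi(path):
    import gemmi
    p = Path(path)
    if not p.exists():
        raise ParseError(f"no such structure file: {p}")
    try:
        st = gemmi.read_structure(str(p))
    except Exception as exc:                  # noqa: BLE001
        raise ParseError(f"could not parse {p}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{p}: file contains no coordinate models")
    return st


def read_structure(path) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Identifiers are preserved verbatim; alternate locations collapse to the
    highest-occupancy conformer (the number discarded is logged).
    """
    st = _read_gemmi(path)
    model, _ = _rows_to_model(_gemmi_model_rows(st[0]), str(path))
    if model.n_atoms == 0:
        raise ParseError(f"{path}: no atom coordinates found")
    return model


def read_frames(path, stride_ps: float = 250.0, source: str = "equilibrium") -> FrameSeries:
    """Read a multi-model PDB/mmCIF file as a trajectory."""
    st = _read_gemmi(path)
    models = []
    for gm in st:
        m, _ = _rows_to_model(_gemmi_model_rows(gm), str(path))
        models.append(m)
    top = models[0]
    key0 = list(zip(top.chain, top.resid, top.name))
    coords = np.empty((len(models), top.n_atoms, 3))
    for i, m in enumerate(models):
        if list(zip(m.chain, m.resid, m.name)) != key0:
            raise ParseError(f"{path}: atom ordering differs between models")
        coords[i] = m.xyz
    return FrameSeries(topology=top, coords=coords, stride_ps=stride_ps, source=source)


def _pdb_atom_line(serial, name, resname, chain, resid, x, y, z, element):
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (f"ATOM  {serial:5d} {nm:<4s}{resname:<4s}{chain:1s}{resid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}\n")


def write_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as a single-model PDB file."""
    with open(path, "w") as fh:
        for i in range(model.n_atoms):
            fh.write(_pdb_atom_line(
                (i + 1) % 100000, str(model.name[i]), str(model.resname[i]),
                str(model.chain[i])[:1], int(model.resid[i]),
                *model.xyz[i], str(model.element[i])))
        fh.write("END\n")


def write_frames(frames: FrameSeries, path) -> None:
    """Write a FrameSeries as a multi-model PDB file."""
    top = frames.topology
    with open(path, "w") as fh:
        for f in range(frames.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i in range(top.n_atoms):
                fh.write(_pdb_atom_line(
                    (i + 1) % 100000, str(top.name[i]), str(top.resname[i]),
                    str(top.chain[i])[:1], int(top.resid[i]),
                    *frames.coords[f, i], str(top.element[i])))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _parse_clause(clause: str):
    parts = clause.strip().split(None, 1)
    if len(parts) != 2:
        raise SelectionError(f"malformed selection clause: {clause!r}")
    key, vals = parts[0].lower(), parts[1].replace(" ", "")
    if key not in ("chain", "resid", "resname", "name"):
        raise SelectionError(f"unknown selection keyword: {key!r}")
    items = vals.split(",")
    if key == "resid":
        out = []
        for it in items:
            if "-" in it[1:]:
                lo, hi = it.split("-", 1) if not it.startswith("-") else (
                    it[:it.index("-", 1)], it[it.index("-", 1) + 1:])
                out.append((int(lo), int(hi)))
            else:
                out.append((int(it), int(it)))
        return key, out
    return key, items


def select_atoms(model: StructureModel, spec: str) -> np.ndarray:
    """Select atoms with a conjunction mini-language.

    ``spec`` is clauses joined with ``and``; each clause is one of
    ``chain A,C``, ``resid 614-625,630``, ``resname THR`` or
    ``name C,O,N,CA,CB``.  Returns indices ordered deterministically by
    (chain, residue number, canonical atom-name rank).

    Raises :class:`SelectionError` when the selection is empty.
    """
    if not spec or not spec.strip():
        raise SelectionError("empty selection expression")
    mask = np.ones(model.n_atoms, dtype=bool)
    for clause in spec.split(" and "):
        key, items = _parse_clause(clause)
        if key == "chain":
            mask &= np.isin(model.chain, items)
        elif key == "resname":
            mask &= np.isin(model.resname, items)
        elif key == "name":
            mask &= np.isin(model.name, items)
        else:  # resid ranges
            m = np.zeros(model.n_atoms, dtype=bool)
            for lo, hi in items:
                m |= (model.resid >= lo) & (model.resid <= hi)
            mask &= m
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    rank = np.array([_ATOM_RANK.get(str(n), len(_ATOM_RANK)) for n in model.name[idx]])
    order = np.lexsort((model.name[idx], rank, model.resid[idx], model.chain[idx]))
    return idx[order]


def _gate_transform(model: StructureModel, reference_residue: int,
                    gate_range: tuple[int, int], filter_range: tuple[int, int],
                    chains=("A", "B", "C", "D")):
    ca = (model.name == "CA")
    ref = ca & (model.resid == reference_residue)
    for c in chains:
        if not np.any(ref & (model.chain == c)):
            raise SelectionError(
                f"reference residue {reference_residue} CA missing in chain {c}")
    origin = model.xyz[ref].mean(axis=0)
    gate = ca & (model.resid >= gate_range[0]) & (model.resid <= gate_range[1])
    pts = model.xyz[gate] - origin
    cov = np.cov(pts.T)
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]           # principal (largest-variance) axis
    filt = ((model.resid >= filter_range[0]) & (model.resid <= filter_range[1])
            & np.isin(model.name, ["N", "CA", "C", "O"]))
    if np.any(filt):
        fcom = model.xyz[filt].mean(axis=0) - origin
        if np.dot(axis, fcom) > 0:      # selectivity filter goes to negative z
            axis = -axis
    R = minimal_rotation_to_z(axis)
    return origin, R


def align_to_gate_origin(obj, reference_residue: int = 625,
                         gate_range: tuple[int, int] = (614, 625),
                         filter_range: tuple[int, int] = (586, 590),
                         chains=("A", "B", "C", "D")):
    """Place frame(s) in the gate-centred frame.

    The centre of mass of the reference residue's C-alpha atoms over the four
    chains moves to the origin; the pore axis (principal axis of the gate
    C-alpha atoms, residues ``gate_range``) becomes z, signed so the
    selectivity-filter backbone lies at negative z.  The transform is rigid
    (pure rotation + translation, det(R) = +1).

    Accepts a :class:`StructureModel` or a :class:`FrameSeries`; each frame of
    a series is aligned independently.
    """
    if isinstance(obj, FrameSeries):
        out = np.empty_like(obj.coords)
        for i in range(obj.n_frames):
            m = obj.frame(i)
            origin, R = _gate_transform(m, reference_residue, gate_range,
                                        filter_range, chains)
            out[i] = (m.xyz - origin) @ R.T
        return FrameSeries(obj.topology, out, obj.stride_ps, obj.source)
    origin, R = _gate_transform(obj, reference_residue, gate_range,
                                filter_range, chains)
    return obj.with_xyz((obj.xyz - origin) @ R.T)
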