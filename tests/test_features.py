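"""Gate descriptors against independent geometric oracles."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from porestate.features import (DihedralError, FeatureScaler, LbdConfig,
                                bend_angle, cross_distance, dihedral,
                                gate_rmsd, lbd_metrics, pore_area)
from porestate.io import StructureModel
from porestate.synthetic import ToyGateSpec, gen_gate_geometry


def _dihedral_oracle(p1, p2, p3, p4):
    """Independent formula: projections onto the plane normal to the middle
    bond (praxeolitic form), distinct from the cross-of-normals route."""
    b0, b1, b2 = p1 - p2, p3 - p2, p4 - p3
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return np.degrees(np.arctan2(y, x))


class TestDihedral:
    def test_cis_is_zero(self):
        pts = [np.array(p, float) for p in
               [(1, 1, 0), (0, 1, 0), (0, -1, 0), (1, -1, 0)]]
        assert dihedral(*pts) == pytest.approx(0.0, abs=1e-12)

    def test_trans_is_180(self):
        pts = [np.array(p, float) for p in
               [(1, 1, 0), (0, 1, 0), (0, -1, 0), (-1, -1, 0)]]
        assert abs(dihedral(*pts)) == pytest.approx(180.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_formula(self, seed):
        r = np.random.default_rng(seed)
        pts = r.normal(size=(4, 3)) * 3.0
        assert dihedral(*pts) == pytest.approx(_dihedral_oracle(*pts), abs=1e-9)

    def test_collinear_middle_bond_is_undefined(self):
        pts = [np.array(p, float) for p in
               [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0)]]
        with pytest.raises(DihedralError):
            dihedral(*pts)


class TestCrossDistance:
    def test_brute_force_norm(self, clean_gate):
        a = clean_gate.xyz[(clean_gate.chain == "A") & (clean_gate.resid == 621)
                           & (clean_gate.name == "CA")][0]
        c = clean_gate.xyz[(clean_gate.chain == "C") & (clean_gate.resid == 621)
                           & (clean_gate.name == "CA")][0]
        assert cross_distance(clean_gate, 621) == pytest.approx(
            np.linalg.norm(a - c), abs=1e-12)

    def test_translation_invariance(self, clean_gate):
        moved = clean_gate.with_xyz(clean_gate.xyz + [1.0, -2.0, 3.0])
        assert cross_distance(moved, 625) == pytest.approx(
            cross_distance(clean_gate, 625), abs=1e-12)


class TestGateRmsd:
    def test_self_is_zero(self, clean_gate):
        assert gate_rmsd(clean_gate, clean_gate) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_rotation_removed(self, clean_gate):
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        moved = clean_gate.with_xyz(clean_gate.xyz @ R.T + [3.0, 1.0, -2.0])
        assert gate_rmsd(moved, clean_gate) == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_superposition(self, clean_gate, rng):
        # asymmetric noisy frame; oracle uses scipy's Kabsch implementation
        noisy = clean_gate.with_xyz(
            clean_gate.xyz + rng.normal(0, 0.4, clean_gate.xyz.shape))
        from porestate.io import select_atoms
        spec = "resid 614-625 and name C,O,N,CA,CB"
        P = noisy.xyz[select_atoms(noisy, spec)]
        Q = clean_gate.xyz[select_atoms(clean_gate, spec)]
        rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        oracle = rssd / np.sqrt(len(P))
        assert gate_rmsd(noisy, clean_gate) == pytest.approx(oracle, abs=1e-9)


class TestBendAngle:
    def test_straight_chain_is_zero(self, clean_gate):
        for ch in "ABCD":
            assert bend_angle(clean_gate, ch) == pytest.approx(0.0, abs=1e-9)

    def test_generator_kink_recovered(self):
        # bend_offset chosen for an exact 30-degree kink over the 10.5 A run
        off = 10.5 * np.tan(np.radians(30.0))
        m = gen_gate_geometry(ToyGateSpec(bend_flags=(False, True, False, False),
                                          bend_offset=off))
        assert bend_angle(m, "B") == pytest.approx(30.0, abs=0.5)
        assert bend_angle(m, "A") == pytest.approx(0.0, abs=1e-9)

    def test_kink_outside_hinge_window_not_detected(self):
        # hand-built CA chain kinking at residue 623, straight at the hinge
        resids = np.arange(614, 626)
        xyz = []
        for r in resids:
            z = (r - 625) * 1.5
            x = 0.0 if r <= 623 else 1.5 * (r - 623)
            xyz.append([5.0 + x, 0.0, z])
        n = len(resids)
        m = StructureModel(chain=np.array(["A"] * n), resid=resids,
                           resname=np.array(["ALA"] * n),
                           name=np.array(["CA"] * n),
                           element=np.array(["C"] * n),
                           xyz=np.array(xyz))
        # the kink at 623 contaminates the upper-run fit only mildly
        assert bend_angle(m, "A") < 20.0


class TestPoreArea:
    def _square_model(self, s, jumble=False):
        half = s / 2.0
        pts = [(half, half), (-half, half), (-half, -half), (half, -half)]
        if jumble:
            pts = [pts[2], pts[0], pts[3], pts[1]]
        xyz = np.array([[x, y, 0.0] for x, y in pts])
        return StructureModel(chain=np.array(list("ABCD")),
                              resid=np.full(4, 621), resname=np.array(["ALA"] * 4),
                              name=np.array(["CA"] * 4),
                              element=np.array(["C"] * 4), xyz=xyz)

    def test_square_area(self):
        assert pore_area(self._square_model(3.0), 621) == pytest.approx(9.0, abs=1e-12)

    def test_vertex_order_irrelevant(self):
        a = pore_area(self._square_model(2.0), 621)
        b = pore_area(self._square_model(2.0, jumble=True), 621,
                      chains=("C", "A", "D", "B"))
        assert a == pytest.approx(b, abs=1e-12)

    def test_irregular_quadrilateral_matches_triangle_split(self, rng):
        # convex irregular quadrilateral; oracle = sum of two triangle areas
        ang = np.sort(rng.uniform(0, 2 * np.pi, 4))
        rad = rng.uniform(2.0, 6.0, 4)
        pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang),
                               np.zeros(4)])
        def tri(a, b, c):
            u, v = b[:2] - a[:2], c[:2] - a[:2]
            return 0.5 * abs(u[0] * v[1] - u[1] * v[0])
        oracle = tri(pts[0], pts[1], pts[2]) + tri(pts[0], pts[2], pts[3])
        m = StructureModel(chain=np.array(list("ABCD")), resid=np.full(4, 617),
                          resname=np.array(["THR"] * 4),
                          name=np.array(["CA"] * 4),
                          element=np.array(["C"] * 4), xyz=pts)
        assert pore_area(m, 617) == pytest.approx(oracle, abs=1e-9)


def _lbd_model(d2_rotation_deg=0.0, d635_half=13.0):
    """Synthetic two-chain LBD: D1 = residues 1-6, D2 = 10-15, marker 635."""
    cfg = LbdConfig(d1_ranges=[(1, 6)], d2_ranges=[(10, 15)],
                    dimer_pairs=(("A", "B"),), d635_residue=635)
    rows = []
    rng = np.random.default_rng(0)
    base_d1 = rng.normal(size=(6, 3)) * 2.0
    base_d2 = rng.normal(size=(6, 3)) * 2.0 + [0.0, 0.0, -6.0]
    R = Rotation.from_euler("y", d2_rotation_deg, degrees=True).as_matrix()
    hinge = np.array([0.0, 0.0, -3.0])
    for ch, sign in (("A", 1.0), ("B", -1.0)):
        off = np.array([sign * 8.0, 0.0, 0.0])
        for i in range(6):
            rows.append((ch, i + 1, base_d1[i] + off))
        for i in range(6):
            p = (R @ (base_d2[i] - hinge)) + hinge + off
            rows.append((ch, i + 10, p))
        rows.append((ch, 635, off + [sign * (d635_half - 8.0), 0.0, -8.0]))
    n = len(rows)
    model = StructureModel(
        chain=np.array([r[0] for r in rows]),
        resid=np.array([r[1] for r in rows], dtype=int),
        resname=np.array(["GLY"] * n), name=np.array(["CA"] * n),
        element=np.array(["C"] * n),
        xyz=np.array([r[2] for r in rows], dtype=float))
    return model, cfg


class TestLbdMetrics:
    def test_apo_identical_gives_zero_alpha(self):
        apo, cfg = _lbd_model()
        out = lbd_metrics(apo, apo, cfg, chains=("A", "B"))
        for ch in "AB":
            assert out.alpha[ch] == pytest.approx(0.0, abs=1e-5)

    def test_constructed_d2_rotation_recovered(self):
        apo, cfg = _lbd_model(0.0)
        closed, _ = _lbd_model(20.0)
        out = lbd_metrics(closed, apo, cfg, chains=("A", "B"))
        for ch in "AB":
            assert out.alpha[ch] == pytest.approx(20.0, abs=0.1)

    def test_d635_by_construction(self):
        m, cfg = _lbd_model(d635_half=13.0)
        out = lbd_metrics(m, m, cfg, chains=("A", "B"))
        assert out.d635["AB"] == pytest.approx(26.0, abs=1e-9)


class TestFeatureScaler:
    def test_distance_standardised_to_unit_sd(self, rng):
        df = pd.DataFrame({"d": rng.normal(10.0, 2.0, 5000)})
        X, names = FeatureScaler().fit_transform(df)
        assert np.std(X[:, 0]) == pytest.approx(1.0, abs=1e-9)

    def test_constant_angle_dropped_with_warning(self, rng):
        df = pd.DataFrame({"chi": np.full(100, 42.0),
                           "d": rng.normal(size=100)})
        sc = FeatureScaler(angle_cols=("chi",))
        with pytest.warns(UserWarning, match="zero variance"):
            X, names = sc.fit_transform(df)
        assert X.shape[1] == 1 and names == ["d"]

    def test_wrapped_angles_are_near_neighbours(self, rng):
        angles = np.where(rng.random(1000) < 0.5, 179.0, -179.0)
        angles = angles + rng.normal(0, 0.5, 1000)
        df = pd.DataFrame({"chi": angles})
        sc = FeatureScaler(angle_cols=("chi",))
        X, _ = sc.fit_transform(df)
        from porestate._geom import wrap_deg
        i, j = int(np.argmax(df.chi)), int(np.argmin(df.chi))
        gap = np.linalg.norm(X[i] - X[j])
        scale = sc.stats_["cols"][0][2][0]
        delta = abs(wrap_deg(df.chi[i] - df.chi[j]))   # circular separation
        chord = 2.0 * np.sin(np.radians(delta) / 2.0) * scale
        assert gap == pytest.approx(chord, rel=1e-6)
        # never torn to opposite ends: tiny next to the diametric chord
        assert gap < 0.05 * (2.0 * scale)

    def test_angle_encoding_invertible(self, rng):
        a = rng.uniform(-179.0, 180.0, 500)
        df = pd.DataFrame({"chi": a})
        sc = FeatureScaler(angle_cols=("chi",))
        X, names = sc.fit_transform(df)
        back = sc.decode_angle(X, names, "chi")
        assert np.allclose(back, a, atol=1e-9)
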