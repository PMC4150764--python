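"""Disulfide geometry/strain, dimer-of-dimers angle, and SASA."""

import math

import numpy as np
import pytest

from tfdna import (
    classify_disulfide,
    dimer_dna_angle,
    disulfide_geometry,
    sasa,
    strain_energy,
)
from tfdna._linalg import dihedral, fibonacci_sphere, rotation_about_axis
from tfdna.structure import Atom, Chain, Residue, Structure


def _closed_form_strain(chi1, chi2, chi3, chi2p, chi1p):
    r = math.radians
    return (
        2.0 * (1 + math.cos(3 * r(chi1)))
        + 2.0 * (1 + math.cos(3 * r(chi1p)))
        + 1.0 * (1 + math.cos(3 * r(chi2)))
        + 1.0 * (1 + math.cos(3 * r(chi2p)))
        + 3.5 * (1 + math.cos(2 * r(chi3)))
        + 0.6 * (1 + math.cos(3 * r(chi3)))
    )


def _build_disulfide(chi1=-60.0, chi2=-60.0, chi3=-87.0, chi2p=-60.0, chi1p=-60.0):
    """Place two CYS residues realizing the requested torsions exactly.

    The chain N-CA-CB-SG-SG'-CB'-CA'-N' is grown atom by atom with ideal
    bond lengths/angles, each torsion set by explicit rotation about the
    preceding bond.
    """
    b_ca_cb, b_cb_sg, b_ss = 1.53, 1.81, 2.04
    ang = 109.5  # tetrahedral-ish everywhere

    def extend(p3, p2, p1, bond, angle_deg, torsion_deg):
        # place the next atom at distance `bond` from p1, bond angle at p1,
        # torsion p3-p2-p1-new
        v12 = p1 - p2
        v12 /= np.linalg.norm(v12)
        n = np.cross(p2 - p3, v12)
        n /= np.linalg.norm(n)
        d = v12.copy()
        d = rotation_about_axis(n, 180.0 - angle_deg) @ d
        d = rotation_about_axis(v12, -torsion_deg) @ d
        return p1 + bond * d

    n_a = np.array([0.0, 1.45, 0.0])
    ca_a = np.zeros(3)
    cb_a = np.array([1.53 * math.sin(math.radians(70.5)), -1.53 * math.cos(math.radians(70.5)), 0.0])
    sg_a = extend(n_a, ca_a, cb_a, b_cb_sg, ang, chi1)
    sg_b = extend(ca_a, cb_a, sg_a, b_ss, 104.0, chi2)
    cb_b = extend(cb_a, sg_a, sg_b, b_cb_sg, 104.0, chi3)
    ca_b = extend(sg_a, sg_b, cb_b, b_ca_cb, ang, chi2p)
    n_b = extend(sg_b, cb_b, ca_b, 1.45, ang, chi1p)

    st = Structure("ss", [Chain("A"), Chain("B")])
    ra = Residue("A", 159, "", "CYS")
    for name, pos, elem in (("N", n_a, "N"), ("CA", ca_a, "C"), ("CB", cb_a, "C"), ("SG", sg_a, "S")):
        ra.atoms.append(Atom("A", 159, "", "CYS", name, elem, pos))
    rb = Residue("B", 159, "", "CYS")
    for name, pos, elem in (("N", n_b, "N"), ("CA", ca_b, "C"), ("CB", cb_b, "C"), ("SG", sg_b, "S")):
        rb.atoms.append(Atom("B", 159, "", "CYS", name, elem, pos))
    st.chain("A").residues.append(ra)
    st.chain("B").residues.append(rb)
    return st


class TestDisulfide:
    def test_constructed_left_handed_spiral(self):
        st = _build_disulfide(chi1=-60, chi2=-60, chi3=-87, chi2p=-60, chi1p=-60)
        g = disulfide_geometry(st, ("A", 159), ("B", 159))
        assert g.chi3 == pytest.approx(-87.0, abs=1e-6)
        assert g.chi1 == pytest.approx(-60.0, abs=1e-6)
        assert g.handedness == "LH"
        assert g.conformation_class == "spiral"
        assert g.strain_energy == pytest.approx(
            _closed_form_strain(-60, -60, -87, -60, -60), abs=1e-6
        )

    def test_right_handed_by_chi3_sign(self):
        st = _build_disulfide(chi3=+87.0, chi2=60.0, chi2p=60.0)
        g = disulfide_geometry(st, ("A", 159), ("B", 159))
        assert g.handedness == "RH"
        assert g.conformation_class == "spiral"

    @pytest.mark.parametrize(
        "chi2, chi2p, chi3, expected",
        [(-60, -60, -87, "spiral"), (60, 60, -87, "staple"), (-60, 60, -87, "hook"),
         (60, -60, -87, "hook"), (60, 60, 87, "spiral")],
    )
    def test_sign_pattern_taxonomy(self, chi2, chi2p, chi3, expected):
        _, cls = classify_disulfide(chi2, chi2p, chi3)
        assert cls == expected

    def test_broken_bridge_rejected(self):
        st = _build_disulfide()
        for a in st.chain("B").residue(159).atoms:
            a.position += np.array([10.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="not a disulfide"):
            disulfide_geometry(st, ("A", 159), ("B", 159))

    def test_strain_energy_periodic_and_nonnegative(self, rng):
        for _ in range(200):
            chis = rng.uniform(-180, 180, size=5)
            e = strain_energy(*chis)
            assert e >= 0.0
            shifted = strain_energy(chis[0] + 120.0, chis[1] + 120.0, chis[2],
                                    chis[3] + 120.0, chis[4] + 120.0)
            assert shifted == pytest.approx(e, abs=1e-9)
        # global minimum: every cosine term at -1 simultaneously
        assert strain_energy(60.0, 60.0, 90.0, 60.0, 60.0) == pytest.approx(
            0.6 * (1 + math.cos(math.radians(270.0))), abs=1e-9
        )


def _point_structure(points, element="C", chain="A", resname="GLY", atom="CA"):
    st = Structure("pts", [Chain(chain)])
    for i, p in enumerate(points, start=1):
        r = Residue(chain, i, "", resname)
        r.atoms.append(Atom(chain, i, "", resname, atom, element, np.asarray(p, float)))
        st.chain(chain).residues.append(r)
    return st


class TestDimerDnaAngle:
    def _toy(self, c1, c2, dna_at=(0.0, 0.0, 0.0)):
        st = Structure("toy", [Chain("A"), Chain("C"), Chain("E")])
        for cid, pos in (("A", c1), ("C", c2)):
            r = Residue(cid, 1, "", "GLY")
            r.atoms.append(Atom(cid, 1, "", "GLY", "CA", "C", np.asarray(pos, float)))
            st.chain(cid).residues.append(r)
        r = Residue("E", 1, "", "DA")
        r.atoms.append(Atom("E", 1, "", "DA", "C1'", "C", np.asarray(dna_at, float)))
        st.chain("E").residues.append(r)
        return st

    def test_arithmetic_construction(self):
        # dimer centroids at (+-30, 0, 10), pivot at origin
        st = self._toy((30.0, 0.0, 10.0), (-30.0, 0.0, 10.0))
        q = dimer_dna_angle(st, ("A",), ("C",), ("E",))
        assert q.inter_dimer_angle == pytest.approx(2 * math.degrees(math.atan(3.0)), abs=1e-9)

    def test_collinear_is_180(self):
        st = self._toy((30.0, 0.0, 0.0), (-12.0, 0.0, 0.0))
        q = dimer_dna_angle(st, ("A",), ("C",), ("E",))
        assert q.inter_dimer_angle == pytest.approx(180.0, abs=1e-9)

    def test_mirror_symmetry_preserves_angle(self):
        st = self._toy((30.0, 5.0, 10.0), (-30.0, 5.0, 10.0))
        ref = dimer_dna_angle(st, ("A",), ("C",), ("E",)).inter_dimer_angle
        mirrored = self._toy((-30.0, 5.0, 10.0), (30.0, 5.0, 10.0))
        assert dimer_dna_angle(mirrored, ("A",), ("C",), ("E",)).inter_dimer_angle == pytest.approx(ref)

    def test_overlapping_dimers_rejected(self):
        st = self._toy((1.0, 0, 0), (-1.0, 0, 0))
        with pytest.raises(ValueError):
            dimer_dna_angle(st, ("A",), ("A",), ("E",))


class TestSasa:
    def test_single_sphere_closed_form(self):
        rep = sasa(_point_structure([(0, 0, 0)]), probe=1.4, n_points=960)
        assert rep.total == pytest.approx(4 * math.pi * 3.1**2, rel=1e-12)

    def test_distant_spheres_additive(self):
        rep = sasa(_point_structure([(0, 0, 0), (100.0, 0, 0)]), probe=1.4)
        assert rep.total == pytest.approx(2 * 4 * math.pi * 3.1**2, rel=1e-12)

    def test_two_overlapping_spheres_match_spherical_cap_closed_form(self):
        # two equal spheres, R = r + probe = 3.1, centers 2.0 Å apart:
        # each loses a cap of height h = R - d/2
        d = 2.0
        R = 3.1
        h = R - d / 2
        expected_each = 4 * math.pi * R**2 - 2 * math.pi * R * h
        rep = sasa(_point_structure([(0, 0, 0), (d, 0, 0)]), probe=1.4, n_points=8000)
        assert rep.per_atom_area[0] == pytest.approx(expected_each, rel=0.01)
        assert rep.per_atom_area[1] == pytest.approx(expected_each, rel=0.01)

    def test_burial_is_nonnegative_on_random_clusters(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 8, size=(12, 3))
            whole = sasa(_point_structure(pts)).total
            parts = sum(sasa(_point_structure([p])).total for p in pts)
            assert whole <= parts + 1e-9

    def test_agreement_with_independent_shrake_rupley(self, rng):
        biotite_sasa = pytest.importorskip("biotite.structure")
        import biotite.structure as bst

        pts = rng.uniform(0, 10, size=(20, 3))
        arr = bst.AtomArray(len(pts))
        arr.coord = pts.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, len(pts) + 1)
        arr.res_name[:] = "GLY"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        ref = float(
            np.sum(bst.sasa(arr, probe_radius=1.4, point_number=1000,
                            vdw_radii=np.full(len(pts), 1.7)))
        )
        mine = sasa(_point_structure(pts), probe=1.4, n_points=2000).total
        assert mine == pytest.approx(ref, rel=0.02)

    def test_unknown_element_rejected(self):
        st = _point_structure([(0, 0, 0)], element="Xx")
        with pytest.raises(ValueError, match="Xx"):
            sasa(st)

    def test_rigid_body_invariance(self, rng):
        pts = rng.uniform(0, 6, size=(8, 3))
        ref = sasa(_point_structure(pts)).total
        R = rotation_about_axis([1, 1, 1], 50.0)
        moved = _point_structure([R @ p + np.array([3.0, -2.0, 9.0]) for p in pts])
        assert sasa(moved).total == pytest.approx(ref, abs=1e-6)
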