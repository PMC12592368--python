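"""Structure I/O, site-criterion geometry, dihedrals and pore profiling."""
import numpy as np
import pytest

import mgbind as mg
from mgbind.structure import (AtomRecord, Structure, dihedral_angle,
                              place_atom)


# ----------------------------------------------------------------------
# I/O

class TestReadStructure:
    def test_pdb_fixture_elements_and_residues(self, tmp_path):
        st = mg.make_toy_tetramer(1, [("ASP", "GLU", 1.1)])
        path = tmp_path / "two_res.pdb"
        mg.write_pdb(st, path)
        back = mg.read_structure(path, format="pdb")
        assert len(back.residues()) == 2
        elements = {a.name: a.element for a in back.atoms}
        assert elements["CA"] == "C" and elements["N"] == "N" \
            and elements["OD1"] == "O"

    def test_mmcif_dialect_equivalence(self, tmp_path):
        import gemmi

        st = mg.make_toy_tetramer(1, [("ASP", "ASP", 1.05)])
        pdb = tmp_path / "toy.pdb"
        mg.write_pdb(st, pdb)
        gst = gemmi.read_structure(str(pdb))
        gst.setup_entities()
        cif = tmp_path / "toy.cif"
        gst.make_mmcif_document().write_file(str(cif))
        a = mg.read_structure(pdb, format="pdb")
        b = mg.read_structure(cif, format="mmcif")
        assert np.max(np.abs(a.coords() - b.coords())) < 1e-4  # 1e-3 A

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        text = (
            "ATOM      1  CA AASP A 100       0.000   0.000   0.000  0.40 10.00           C\n"
            "ATOM      2  CA BASP A 100       9.999   0.000   0.000  0.60 10.00           C\n"
            "END\n")
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        st = mg.read_structure(p)
        assert len(st.atoms) == 1
        assert st.atoms[0].pos[0] == pytest.approx(0.9999)

    def test_unparseable_and_empty_inputs(self, tmp_path):
        bad = tmp_path / "junk.cif"
        bad.write_text("not a structure at all\n")
        with pytest.raises(ValueError):
            mg.read_structure(bad, format="mmcif")
        empty = tmp_path / "empty.pdb"
        empty.write_text("")
        with pytest.raises(ValueError):
            mg.read_structure(empty, format="pdb")


# ----------------------------------------------------------------------
# pair thresholds and site scanning

class TestPairThreshold:
    @pytest.mark.parametrize("a,b,expect", [
        ("ASP", "ASP", 1.1), ("ASP", "GLU", 1.2),
        ("GLU", "ASP", 1.2), ("GLU", "GLU", 1.3)])
    def test_values_and_symmetry(self, a, b, expect):
        assert mg.pair_threshold(a, b) == pytest.approx(expect)

    def test_non_acidic_rejected(self):
        with pytest.raises(ValueError):
            mg.pair_threshold("ASP", "LYS")


def _shift_chain(structure, dx):
    atoms = [AtomRecord(a.name, a.element, a.residue_name, a.residue_number,
                        a.chain_id, a.altloc, a.occupancy, a.pos + dx)
             for a in structure.atoms]
    return Structure(atoms=atoms)


class TestScanSites:
    def test_tetramer_yields_four_two_residue_sites(self, toy_closed):
        sites = mg.scan_sites(toy_closed)
        assert len(sites) == 4
        assert all(len(s.residues) == 2 for s in sites)
        assert all(p.pair_class == "DD" for s in sites for p in s.member_pairs)

    def test_class_dependent_cutoffs(self):
        dd = mg.make_toy_tetramer(1, [("ASP", "ASP", 1.15)])
        de = mg.make_toy_tetramer(1, [("ASP", "GLU", 1.15)])
        assert mg.scan_sites(dd) == []
        assert len(mg.scan_sites(de)) == 1

    def test_exact_threshold_excluded(self):
        st = mg.make_toy_tetramer(1, [("ASP", "ASP", 1.1)])
        assert mg.scan_sites(st) == []

    def test_chained_pairs_merge_into_one_site(self):
        # residues A-B-C-D spaced 1.0 nm apart: adjacent DD pairs chain up
        st = mg.make_toy_tetramer(1, [("ASP", "ASP", 1.0)])
        extra = mg.make_toy_tetramer(1, [("ASP", "ASP", 1.0)])
        atoms = list(st.atoms)
        for a in extra.atoms:
            atoms.append(AtomRecord(a.name, a.element, a.residue_name,
                                    a.residue_number + 100, a.chain_id,
                                    a.altloc, a.occupancy,
                                    a.pos + np.array([0.0, 2.0, 0.0])))
        merged = mg.scan_sites(Structure(atoms=atoms))
        assert len(merged) == 1
        assert len(merged[0].residues) == 4
        unmerged = mg.scan_sites(Structure(atoms=atoms), merge=False)
        assert len(unmerged) == 3

    def test_invariance_under_reordering_and_rigid_motion(self, toy_closed):
        base = [tuple(s.residues) for s in mg.scan_sites(toy_closed)]
        shuffled = Structure(atoms=list(reversed(toy_closed.atoms)))
        assert [tuple(s.residues) for s in mg.scan_sites(shuffled)] == base
        # rigid rotation + translation
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = Structure(atoms=[
            AtomRecord(a.name, a.element, a.residue_name, a.residue_number,
                       a.chain_id, a.altloc, a.occupancy,
                       rot @ a.pos + np.array([1.0, -2.0, 0.5]))
            for a in toy_closed.atoms])
        assert [tuple(s.residues) for s in mg.scan_sites(moved)] == base

    def test_region_slab_filter(self, toy_closed):
        # all toy CAs sit at z ~ 0; an off-slab filter removes everything
        assert mg.scan_sites(toy_closed, region=(5.0, 10.0)) == []

    def test_no_acidic_residues_is_empty_not_error(self):
        st = mg.make_toy_tetramer(1, [("LYS", "LYS", 1.0)])
        assert mg.scan_sites(st) == []


class TestCaDistance:
    def test_axis_aligned_distance(self):
        st = mg.make_toy_tetramer(1, [("ASP", "ASP", 1.1)])
        assert mg.ca_distance(st, ("A", 100), ("A", 105)) == pytest.approx(1.1, abs=1e-9)

    def test_identity_is_zero(self, toy_closed):
        assert mg.ca_distance(toy_closed, ("A", 100), ("A", 100)) == 0.0

    def test_missing_ca_raises(self, toy_closed):
        st = Structure(atoms=[a for a in toy_closed.atoms
                              if not (a.residue_number == 100
                                      and a.chain_id == "A" and a.name == "CA")])
        with pytest.raises(ValueError):
            mg.ca_distance(st, ("A", 100), ("A", 105))


# ----------------------------------------------------------------------
# dihedrals

def _asp_fixture(chi1, chi2):
    """Single ASP with prescribed chi angles, built by internal coordinates."""
    n = np.array([1.458, 0.0, 0.0])
    ca = np.zeros(3)
    cb = place_atom(np.array([2.0, 1.0, 0.0]), n, ca, 1.53, 110.0, 60.0)
    cg = place_atom(n, ca, cb, 1.52, 114.0, chi1)
    od1 = place_atom(ca, cb, cg, 1.25, 119.0, chi2)
    od2 = place_atom(ca, cb, cg, 1.25, 119.0, chi2 + 180.0)
    atoms = [AtomRecord(nm, el, "ASP", 7, "A", "", 1.0, pos / 10.0)
             for nm, el, pos in [("N", "N", n), ("CA", "C", ca),
                                 ("CB", "C", cb), ("CG", "C", cg),
                                 ("OD1", "O", od1), ("OD2", "O", od2)]]
    return Structure(atoms=atoms)


class TestSidechainDihedrals:
    def test_planar_anti_chi1(self):
        st = _asp_fixture(180.0, 10.0)
        chi1, chi2 = mg.sidechain_dihedrals(st, ("A", 7))
        assert chi1 == pytest.approx(180.0, abs=1e-6)
        assert chi2 == pytest.approx(10.0, abs=1e-6)

    def test_rotation_by_60_from_anti(self):
        # rotate CG by +60 deg about the CA-CB axis starting from anti
        st = _asp_fixture(180.0, -30.0)
        atoms = {a.name: a for a in st.atoms}
        ca, cb = atoms["CA"].pos, atoms["CB"].pos
        axis = (cb - ca) / np.linalg.norm(cb - ca)
        ang = np.radians(60.0)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        for name in ("CG", "OD1", "OD2"):
            atoms[name].pos = cb + R @ (atoms[name].pos - cb)
        chi1, _ = mg.sidechain_dihedrals(st, ("A", 7))
        assert chi1 == pytest.approx(-120.0, abs=1e-6)

    def test_mirror_image_negates_angles(self):
        st = _asp_fixture(-65.0, 40.0)
        mirrored = Structure(atoms=[
            AtomRecord(a.name, a.element, a.residue_name, a.residue_number,
                       a.chain_id, a.altloc, a.occupancy,
                       a.pos * np.array([1.0, 1.0, -1.0]))
            for a in st.atoms])
        c1, c2 = mg.sidechain_dihedrals(st, ("A", 7))
        m1, m2 = mg.sidechain_dihedrals(mirrored, ("A", 7))
        assert m1 == pytest.approx(-c1, abs=1e-6)
        assert m2 == pytest.approx(-c2, abs=1e-6)

    def test_missing_atom_named_in_error(self, toy_closed):
        st = Structure(atoms=[a for a in toy_closed.atoms if a.name != "CG"])
        with pytest.raises(ValueError, match="CG"):
            mg.sidechain_dihedrals(st, ("A", 100))

    def test_dihedral_sign_convention(self):
        p = [np.array([0.0, 1.0, 0.0]), np.zeros(3), np.array([1.0, 0.0, 0.0]),
             np.array([1.0, 0.5, 0.5])]
        a = dihedral_angle(*p)
        assert -180.0 < a <= 180.0
        assert dihedral_angle(*p[::-1]) == pytest.approx(a)


# ----------------------------------------------------------------------
# pore profiler

def _ring(radius, z, n=8, vdw_elem="O"):
    atoms = []
    for i, t in enumerate(np.linspace(0, 2 * np.pi, n, endpoint=False)):
        atoms.append(AtomRecord("O", "O", "HOH", i + 1, "W", "", 1.0,
                                np.array([radius * np.cos(t),
                                          radius * np.sin(t), z])))
    return atoms


class TestPoreProfile:
    def test_single_ring_radius(self):
        st = Structure(atoms=_ring(0.5, 0.0))
        prof = mg.pore_profile(st, -0.0, 0.0, 0.1, axis_point=np.zeros(3))
        z, r = prof.as_arrays()
        assert r[0] == pytest.approx(0.5 - 0.152, abs=1e-3)

    def test_minimum_at_narrower_ring(self):
        st = Structure(atoms=_ring(0.5, 0.0) + _ring(0.4, 1.0))
        prof = mg.pore_profile(st, 0.0, 1.0, 0.25, axis_point=np.zeros(3))
        z, r = prof.as_arrays()
        assert z[np.argmin(r)] == pytest.approx(1.0)

    def test_cylinder_constant_and_matches_grid_search(self):
        rng = np.random.default_rng(5)
        atoms = []
        num = 0
        for z in np.arange(0.0, 1.01, 0.1):
            for t in np.linspace(0, 2 * np.pi, 12, endpoint=False):
                num += 1
                atoms.append(AtomRecord("C", "C", "CYL", num, "X", "", 1.0,
                                        np.array([0.45 * np.cos(t),
                                                  0.45 * np.sin(t), z])))
        st = Structure(atoms=atoms)
        step = 0.2
        prof = mg.pore_profile(st, 0.2, 0.8, step, axis_point=np.zeros(3))
        z, r = prof.as_arrays()
        assert np.ptp(r) < step / 2
        # exhaustive fine-grid oracle in the middle plane
        coords = st.coords()
        radii = np.full(len(coords), 0.17)
        best = -np.inf
        for cx in np.arange(-0.1, 0.1001, 0.005):
            for cy in np.arange(-0.1, 0.1001, 0.005):
                c = np.array([cx, cy, 0.5])
                best = max(best, np.min(
                    np.linalg.norm(coords - c, axis=1) - radii))
        mid = r[np.argmin(np.abs(z - 0.5))]
        assert abs(mid - best) < step / 2

    def test_empty_slab_reports_sentinel(self):
        st = Structure(atoms=_ring(0.5, 0.0))
        prof = mg.pore_profile(st, 5.0, 5.0, 0.1, axis_point=np.zeros(3),
                               max_radius=1.5, slab_half_width=0.5)
        assert prof.samples[0][1] == 1.5
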