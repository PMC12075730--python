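"""Descriptor extraction: geometry, neighbours, SASA and vector assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from nosbond.config import ScreeningConfig
from nosbond.contact_screen import find_sn_contacts
from nosbond.descriptors import (
    DESCRIPTOR_COLUMNS,
    DescriptorError,
    build_descriptor_table,
    compute_geometry,
    count_neighbors,
    nearest_bonded_carbon,
    vec_angle,
    vec_dihedral,
)
from nosbond.sasa import VDW_RADII, shrake_rupley, sphere_points
from nosbond.structure_io import read_bdb_bfactors, read_structure
from nosbond.synthetic import ContactSpec

from .conftest import make_atom, make_structure


# ---------------------------------------------------------------------------
# independent vector-algebra oracle (cosine / projection formulation,
# distinct from the implementation's atan2 route)

def oracle_angle(a, b, c):
    u, v = a - b, c - b
    cosv = float(np.dot(u, v) / math.sqrt(np.dot(u, u) * np.dot(v, v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def oracle_dihedral(p1, p2, p3, p4):
    b2 = p3 - p2
    u = p1 - p2 - np.dot(p1 - p2, b2) / np.dot(b2, b2) * b2  # reject onto axis
    w = p4 - p3 - np.dot(p4 - p3, b2) / np.dot(b2, b2) * b2
    cosv = float(np.dot(u, w) / math.sqrt(np.dot(u, u) * np.dot(w, w)))
    ang = math.degrees(math.acos(max(-1.0, min(1.0, cosv))))
    if np.dot(np.cross(u, w), b2) < 0:
        ang = -ang
    return 180.0 if ang == -180.0 else ang


class TestNearestBondedCarbon:
    def test_cys_sulfur_selects_cb(self, entry_factory):
        s = read_structure(entry_factory() / "structure.cif")
        sg = s.atom(("A", 10, "", "CYS", "SG"))
        assert nearest_bonded_carbon(s, sg).atom_name == "CB"

    def test_arg_nh1_selects_cz(self, entry_factory):
        s = read_structure(
            entry_factory(n_residue="ARG", n_atom="NH1") / "structure.cif"
        )
        n = s.atom(("A", 2, "", "ARG", "NH1"))
        assert nearest_bonded_carbon(s, n).atom_name == "CZ"

    def test_backbone_n_selects_preceding_carbonyl(self, entry_factory):
        # preceding C at 1.33 Å beats own CA at 1.46 Å
        s = read_structure(entry_factory() / "structure.cif")
        n = s.atom(("A", 2, "", "GLY", "N"))
        c = nearest_bonded_carbon(s, n)
        assert c.atom_name == "C" and c.residue_number == 1

    def test_isolated_nitrogen_raises(self):
        s = make_structure([make_atom("N", "N", (0, 0, 0))])
        with pytest.raises(DescriptorError, match="no_bonded_carbon"):
            nearest_bonded_carbon(s, s.atoms[0])


class TestGeometry:
    def test_orthogonal_placement(self, cfg):
        atoms = [
            make_atom("SG", "S", (0, 0, 0), resname="CYS", resnum=1),
            make_atom("CB", "C", (1.8, 0, 0), resname="CYS", resnum=1),
            make_atom("NZ", "N", (0, 2.7, 0), resname="LYS", resnum=5),
            make_atom("CE", "C", (0, 2.7, 1.49), resname="LYS", resnum=5),
        ]
        s = make_structure(atoms)
        pair = find_sn_contacts(s, cfg)[0]
        g = compute_geometry(s, pair)
        assert g.angle_csn == pytest.approx(90.0, abs=1e-9)
        assert g.dist_sn == pytest.approx(2.7, abs=1e-12)

    def test_trans_planar_torsion_is_180(self, cfg):
        atoms = [
            make_atom("CB", "C", (-1.0, 1.0, 0), resname="CYS", resnum=1),
            make_atom("SG", "S", (0, 0, 0), resname="CYS", resnum=1),
            make_atom("NZ", "N", (2.7, 0, 0), resname="LYS", resnum=5),
            make_atom("CE", "C", (3.7, -1.0, 0), resname="LYS", resnum=5),
        ]
        s = make_structure(atoms)
        pair = find_sn_contacts(s, cfg)[0]
        g = compute_geometry(s, pair)
        assert abs(g.torsion_cs_nc) == pytest.approx(180.0, abs=1e-9)

    def test_matches_oracle_on_random_configurations(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            p = rng.uniform(-5, 5, (4, 3))
            # skip near-degenerate frames the oracle cannot resolve either
            if min(np.linalg.norm(p[i] - p[i + 1]) for i in range(3)) < 0.5:
                continue
            assert vec_angle(p[0], p[1], p[2]) == pytest.approx(
                oracle_angle(p[0], p[1], p[2]), abs=1e-6
            )
            got = vec_dihedral(*p)
            want = oracle_dihedral(*p)
            assert abs(got - want) < 1e-6 or abs(abs(got) + abs(want) - 360) < 1e-6

    def test_rigid_motion_invariance_and_mirror_antisymmetry(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(-3, 3, (4, 3))
        from scipy.spatial.transform import Rotation

        for seed in range(5):
            rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            shift = rng.uniform(-10, 10, 3)
            q = p @ rot.T + shift
            assert vec_angle(*q[:3]) == pytest.approx(vec_angle(*p[:3]), abs=1e-6)
            assert vec_dihedral(*q) == pytest.approx(vec_dihedral(*p), abs=1e-6)
        mirrored = p * np.array([1, 1, -1])
        assert vec_dihedral(*mirrored) == pytest.approx(-vec_dihedral(*p), abs=1e-6)


class TestNeighborCounting:
    def _residue(self, resnum, center, resname="ALA"):
        return [
            make_atom("CA", "C", center, resname=resname, resnum=resnum),
            make_atom("CB", "C", np.add(center, (0.5, 0, 0)), resname=resname, resnum=resnum),
        ]

    def test_isolated_residue_has_zero(self):
        s = make_structure(self._residue(1, (0, 0, 0)))
        assert count_neighbors(s, ("A", 1, "", "ALA"), 4.0) == 0

    def test_planted_neighbors_counted_exactly(self):
        atoms = self._residue(1, (0, 0, 0))
        for k in range(1, 6):
            # one atom of each neighbour at 3.5 Å from the Cα
            atoms.append(make_atom("CB", "C", (3.5 * np.cos(k), 3.5 * np.sin(k), 0),
                                   resname="GLY", resnum=10 + k))
        s = make_structure(atoms)
        assert count_neighbors(s, ("A", 1, "", "ALA"), 4.0) == 5

    def test_multi_atom_residue_counted_once(self):
        atoms = self._residue(1, (0, 0, 0)) + [
            make_atom("CA", "C", (3.0, 0, 0), resname="GLY", resnum=2),
            make_atom("CB", "C", (3.2, 0, 0), resname="GLY", resnum=2),
        ]
        s = make_structure(atoms)
        assert count_neighbors(s, ("A", 1, "", "ALA"), 4.0) == 1

    def test_boundary_inclusive_and_missing_ca(self):
        atoms = self._residue(1, (0, 0, 0)) + [
            make_atom("CB", "C", (4.0, 0, 0), resname="GLY", resnum=2)
        ]
        s = make_structure(atoms)
        assert count_neighbors(s, ("A", 1, "", "ALA"), 4.0) == 1
        s2 = make_structure([make_atom("CB", "C", (0, 0, 0))])
        with pytest.raises(DescriptorError, match="missing_ca"):
            count_neighbors(s2, ("A", 1, "", "GLY"), 4.0)


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        r = VDW_RADII["S"]
        area = shrake_rupley(np.zeros((1, 3)), np.array([r]), probe=1.4, n_points=960)[0]
        exact = 4 * np.pi * (r + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.02)
        assert exact == pytest.approx(128.68, abs=0.01)

    def test_buried_atom_has_zero_area(self):
        # shell of 60 atoms at radius 2 around a central atom
        shell = 2.0 * sphere_points(60)
        coords = np.vstack([[0, 0, 0], shell])
        radii = np.full(len(coords), 1.7)
        areas = shrake_rupley(coords, radii, probe=1.4)
        assert areas[0] == 0.0

    def test_occlusion_reduces_total_area_monotonically(self):
        r = np.array([1.7, 1.7])
        isolated = 2 * 4 * np.pi * (1.7 + 1.4) ** 2
        prev = isolated
        for d in (6.5, 5.0, 4.0, 3.0, 2.0):
            coords = np.array([[0, 0, 0], [d, 0, 0]], dtype=float)
            total = shrake_rupley(coords, r, probe=1.4).sum()
            assert total <= prev + 1e-9
            prev = total
        assert prev < isolated

    def test_residue_sasa_is_exact_sum_of_atoms(self, entry_factory, cfg):
        from nosbond.sasa import structure_sasa

        s = read_structure(entry_factory() / "structure.cif")
        per_atom, per_res = structure_sasa(s)
        for key, total in per_res.items():
            member_sum = sum(v for ak, v in per_atom.items() if ak[:4] == key)
            assert total == pytest.approx(member_sum, abs=1e-12)

    def test_agrees_with_biopython_shrake_rupley(self):
        """Cross-check against the independent Bio.PDB implementation."""
        from Bio.PDB.SASA import ShrakeRupley as BioSR
        from Bio.PDB.StructureBuilder import StructureBuilder

        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 8, (20, 3))
        elements = ["C", "N", "O", "S"] * 5
        radii = np.array([VDW_RADII[e] for e in elements])
        ours = shrake_rupley(coords, radii, probe=1.4, n_points=960)

        builder = StructureBuilder()
        builder.init_structure("x")
        builder.init_model(0)
        builder.init_chain("A")
        builder.init_seg(" ")
        bio_atoms = []
        for i, (xyz, el) in enumerate(zip(coords, elements)):
            builder.init_residue("GLY", " ", i + 1, " ")
            builder.init_atom(f"{el}{i}", xyz, 0.0, 1.0, " ", f"{el}{i}", i, element=el)
        model = builder.get_structure()[0]
        # align radii tables so only the point sampling differs
        sr = BioSR(probe_radius=1.4, n_points=960,
                   radii_dict={e: VDW_RADII[e] for e in "CNOS"})
        sr.compute(model, level="A")
        bio = np.array([a.sasa for a in model.get_atoms()])
        # different deterministic point sets: agreement to a few percent of
        # the isolated-sphere area
        scale = 4 * np.pi * (radii + 1.4) ** 2
        assert np.all(np.abs(ours - bio) / scale < 0.03)


class TestAssembly:
    def test_vector_has_fifteen_numeric_descriptors(self, entry_factory, cfg):
        entry = entry_factory()
        s = read_structure(entry / "structure.cif")
        pairs = find_sn_contacts(s, cfg)
        bdb = read_bdb_bfactors(entry / "bdb.pdb")
        table, excluded = build_descriptor_table(s, pairs, bdb, cfg)
        assert excluded == []
        assert len(table) == 1
        numeric = table[DESCRIPTOR_COLUMNS]
        assert numeric.shape[1] == 15
        assert numeric.notna().all().all()
        assert np.issubdtype(numeric.to_numpy().dtype, np.floating)

    def test_missing_bdb_value_excludes_with_reason(self, entry_factory, cfg):
        entry = entry_factory(omit_bdb=("S",))
        s = read_structure(entry / "structure.cif")
        pairs = find_sn_contacts(s, cfg)
        bdb = read_bdb_bfactors(entry / "bdb.pdb")
        table, excluded = build_descriptor_table(s, pairs, bdb, cfg)
        assert len(table) == 0
        assert [r for _, r in excluded] == ["bdb_missing"]

    def test_tsv_roundtrip_is_lossless(self, entry_factory, cfg, tmp_path):
        entry = entry_factory()
        s = read_structure(entry / "structure.cif")
        bdb = read_bdb_bfactors(entry / "bdb.pdb")
        table, _ = build_descriptor_table(s, find_sn_contacts(s, cfg), bdb, cfg)
        path = tmp_path / "desc.tsv"
        table.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t", keep_default_na=False,
                           dtype={c: float for c in DESCRIPTOR_COLUMNS})
        assert np.allclose(back[DESCRIPTOR_COLUMNS], table[DESCRIPTOR_COLUMNS])
        assert list(back["candidate_id"]) == list(table["candidate_id"])

    def test_reference_geometry_fixture_reproduced(self, entry_factory, cfg):
        # inverse-geometry construction: requested values come back ≤ 1e-3
        entry = entry_factory(dist_sn=2.70, angle_csn=94.02, angle_cns=95.11)
        s = read_structure(entry / "structure.cif")
        bdb = read_bdb_bfactors(entry / "bdb.pdb")
        table, _ = build_descriptor_table(s, find_sn_contacts(s, cfg), bdb, cfg)
        row = table.iloc[0]
        assert row["dist_sn"] == pytest.approx(2.70, abs=1e-3)
        assert row["angle_csn"] == pytest.approx(94.02, abs=1e-3)
        assert row["angle_cns"] == pytest.approx(95.11, abs=1e-3)
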