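"""Cα–Cα distance validation against toy structures written by the tests."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from mifilter.records import CrossLinkRecord, LinkType
from mifilter.structval import (
    DistanceResult,
    StructureMappingError,
    link_distance,
    load_structure,
    satisfaction_summary,
)


def pdb_atom(serial, chain, resnum, x, y, z):
    return (
        f"ATOM  {serial:5d}  CA  ALA {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
    )


def write_pdb(path, atoms):
    """atoms: (chain, resnum, x, y, z)."""
    lines = [pdb_atom(i + 1, *a) for i, a in enumerate(atoms)]
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def write_cif(path, atoms):
    header = """data_toy
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
"""
    rows = [
        f"ATOM {i + 1} C CA . ALA {c} 1 {r} {r} {c} {x:.3f} {y:.3f} {z:.3f}"
        for i, (c, r, x, y, z) in enumerate(atoms)
    ]
    path.write_text(header + "\n".join(rows) + "\n")
    return path


TOY_ATOMS = [
    ("A", 1, 0.0, 0.0, 0.0),
    ("A", 2, 3.0, 4.0, 0.0),
    ("B", 1, 10.0, 0.0, 0.0),
    ("B", 2, 0.0, 0.0, 40.0),
]


def inter(rid, a, pa, b, pb):
    return CrossLinkRecord(
        record_id=rid, raw_type="xlink", protein_a=a, pos_a=pa,
        protein_b=b, pos_b=pb, ld_score=30, link_type=LinkType.INTER,
        replicate_id="r1",
    )


class TestLoadStructure:
    def test_toy_pdb_gives_four_row_table(self, tmp_path):
        path = write_pdb(tmp_path / "toy.pdb", TOY_ATOMS)
        model = load_structure(path, {"protA": ["A"], "protB": ["B"]})
        assert set(model.coords) == {("A", 1), ("A", 2), ("B", 1), ("B", 2)}
        assert model.coords[("A", 2)] == pytest.approx((3.0, 4.0, 0.0))

    def test_absent_chain_raises_mapping_error(self, tmp_path):
        path = write_pdb(tmp_path / "toy.pdb", TOY_ATOMS)
        with pytest.raises(StructureMappingError, match="Z"):
            load_structure(path, {"protA": ["A"], "protZ": ["Z"]})

    def test_unmapped_chains_excluded(self, tmp_path):
        path = write_pdb(tmp_path / "toy.pdb", TOY_ATOMS)
        model = load_structure(path, {"protA": ["A"]})
        assert set(model.coords) == {("A", 1), ("A", 2)}

    def test_pdb_and_mmcif_give_identical_tables(self, tmp_path):
        chain_map = {"protA": ["A"], "protB": ["B"]}
        from_pdb = load_structure(
            write_pdb(tmp_path / "toy.pdb", TOY_ATOMS), chain_map)
        from_cif = load_structure(
            write_cif(tmp_path / "toy.cif", TOY_ATOMS), chain_map)
        assert set(from_pdb.coords) == set(from_cif.coords)
        for key in from_pdb.coords:
            assert from_pdb.coords[key] == pytest.approx(from_cif.coords[key])


class TestLinkDistance:
    @pytest.fixture
    def model(self, tmp_path):
        path = write_pdb(tmp_path / "toy.pdb", TOY_ATOMS)
        return load_structure(path, {"protA": ["A"], "protB": ["B"]})

    def test_3_4_5_triangle(self, model):
        res = link_distance(inter("x", "protA", 1, "protA", 2), model)
        assert res.mappable
        assert res.min_distance == pytest.approx(5.0, abs=1e-9)
        assert res.satisfied

    def test_self_pair_distance_zero(self, model):
        res = link_distance(inter("x", "protA", 1, "protA", 1), model)
        assert res.min_distance == pytest.approx(0.0, abs=1e-12)

    def test_cutoff_flag(self, model):
        res = link_distance(inter("x", "protA", 1, "protB", 2), model)
        assert res.min_distance == pytest.approx(40.0, abs=1e-9)
        assert not res.satisfied

    def test_unmappable_residue(self, model):
        res = link_distance(inter("x", "protA", 1, "protB", 99), model)
        assert not res.mappable
        assert res.min_distance is None and res.satisfied is None

    def test_monolink_rejected(self, model):
        mono = CrossLinkRecord(record_id="m", raw_type="monolink",
                               protein_a="protA", pos_a=1, ld_score=30,
                               link_type=LinkType.MONO, replicate_id="r1")
        with pytest.raises(TypeError):
            link_distance(mono, model)

    def test_min_over_chain_copies_matches_enumeration(self, tmp_path):
        atoms = [
            ("A", 1, 0.0, 0.0, 0.0),
            ("B", 5, 30.0, 0.0, 0.0),
            ("C", 5, 0.0, 7.0, 0.0),   # second copy of protB, closer
        ]
        path = write_pdb(tmp_path / "copies.pdb", atoms)
        model = load_structure(path, {"protA": ["A"], "protB": ["B", "C"]})
        res = link_distance(inter("x", "protA", 1, "protB", 5), model)
        expected = min(
            math.dist((0, 0, 0), p) for p in [(30, 0, 0), (0, 7, 0)]
        )
        assert res.min_distance == pytest.approx(expected, abs=1e-9)

    def test_extra_copy_never_increases_distance(self, tmp_path):
        base = [("A", 1, 0.0, 0.0, 0.0), ("B", 5, 30.0, 0.0, 0.0)]
        extra = base + [("C", 5, 100.0, 100.0, 100.0)]
        m1 = load_structure(write_pdb(tmp_path / "m1.pdb", base),
                            {"protA": ["A"], "protB": ["B"]})
        m2 = load_structure(write_pdb(tmp_path / "m2.pdb", extra),
                            {"protA": ["A"], "protB": ["B", "C"]})
        r = inter("x", "protA", 1, "protB", 5)
        assert (link_distance(r, m2).min_distance
                <= link_distance(r, m1).min_distance)

    def test_symmetry_and_rigid_motion_invariance(self, tmp_path):
        rng = np.random.default_rng(0)
        atoms = [("A", i + 1, *rng.uniform(-20, 20, 3)) for i in range(5)]
        atoms += [("B", i + 1, *rng.uniform(-20, 20, 3)) for i in range(5)]
        model = load_structure(write_pdb(tmp_path / "m.pdb", atoms),
                               {"pA": ["A"], "pB": ["B"]})
        # a rotation about a random axis plus a translation
        theta = 0.83
        rot = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ])
        shift = np.array([5.0, -3.0, 12.0])
        moved = [
            (c, r, *(rot @ np.array([x, y, z]) + shift))
            for c, r, x, y, z in atoms
        ]
        model2 = load_structure(write_pdb(tmp_path / "m2.pdb", moved),
                                {"pA": ["A"], "pB": ["B"]})
        fwd = inter("x", "pA", 2, "pB", 4)
        rev = inter("x", "pB", 4, "pA", 2)
        d = link_distance(fwd, model).min_distance
        assert link_distance(rev, model).min_distance == pytest.approx(d)
        # PDB files carry 0.001 Å coordinate precision, which bounds the
        # reproducibility of the transformed distance
        assert link_distance(fwd, model2).min_distance == pytest.approx(
            d, abs=5e-3)

    def test_residue_offset_applied(self, tmp_path):
        path = write_pdb(tmp_path / "off.pdb", [("A", 11, 0.0, 0.0, 0.0),
                                                ("A", 12, 3.0, 4.0, 0.0)])
        model = load_structure(path, {"pA": ["A"]}, offsets={"A": 10})
        res = link_distance(inter("x", "pA", 1, "pA", 2), model)
        assert res.min_distance == pytest.approx(5.0, abs=1e-9)


class TestSatisfactionSummary:
    def test_nine_of_ten(self):
        results = [
            DistanceResult(record_id=f"r{i}", mappable=True,
                           min_distance=10.0, satisfied=True)
            for i in range(9)
        ] + [DistanceResult(record_id="far", mappable=True,
                            min_distance=50.0, satisfied=False)]
        n_map, n_sat, frac = satisfaction_summary(results, cutoff=35.0)
        assert (n_map, n_sat) == (10, 9)
        assert frac == pytest.approx(0.9)

    def test_all_unmappable(self):
        results = [DistanceResult(record_id="r", mappable=False)] * 3
        assert satisfaction_summary(results, 35.0) == (0, 0, None)

    def test_matches_brute_force_recount(self, tmp_path):
        rng = np.random.default_rng(4)
        atoms = [("A", i + 1, *rng.uniform(-30, 30, 3)) for i in range(20)]
        model = load_structure(write_pdb(tmp_path / "geom.pdb", atoms),
                               {"pA": ["A"]})
        pairs = list(itertools.combinations(range(1, 21), 2))[:40]
        results = [
            link_distance(inter(f"r{i}", "pA", a, "pA", b), model)
            for i, (a, b) in enumerate(pairs)
        ]
        cutoff = 35.0
        n_map, n_sat, frac = satisfaction_summary(results, cutoff)
        coords = {r: np.array(model.coords[("A", r)]) for r in range(1, 21)}
        brute = sum(
            1 for a, b in pairs
            if np.linalg.norm(coords[a] - coords[b]) <= cutoff
        )
        assert n_map == len(pairs)
        assert n_sat == brute
        assert frac == pytest.approx(brute / len(pairs))
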