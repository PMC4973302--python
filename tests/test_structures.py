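"""Coordinate I/O, altloc models, ligand extraction and polar roles."""

import numpy as np
import pytest

from tunneldock.structures import (
    Atom,
    ConformerModel,
    ProteinStructure,
    StructureError,
    StructureParseError,
    assign_polar_roles,
    collapse_altlocs,
    extract_ligand_conformers,
    hydroxyl_span,
    read_structure,
    select_model,
    write_structure,
)
from tunneldock.synthetic import LigandSpec, make_ligand_library


MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1      11.000  12.000  13.000  1.00 20.00"
    "           C  \n"
    "END\n"
)


def _atom(name, res, seq, xyz, element=None, altloc="", occ=1.0, chain="A"):
    return Atom(
        serial=1,
        name=name,
        element=element or name[0],
        residue_name=res,
        chain_id=chain,
        residue_seq=seq,
        position=np.asarray(xyz, dtype=float),
        altloc=altloc,
        occupancy=occ,
    )


def _altloc_structure():
    """Gly-Arg toy with an alternate-conformation arginine."""
    atoms = [
        _atom("N", "GLY", 1, (0, 0, 0), "N"),
        _atom("CA", "GLY", 1, (1.5, 0, 0), "C"),
        _atom("C", "GLY", 1, (2.2, 1.3, 0), "C"),
        _atom("O", "GLY", 1, (1.7, 2.4, 0), "O"),
        _atom("N", "ARG", 2, (3.5, 1.2, 0), "N"),
        _atom("CA", "ARG", 2, (4.4, 2.3, 0), "C"),
        _atom("C", "ARG", 2, (5.8, 1.8, 0), "C"),
        _atom("O", "ARG", 2, (6.2, 0.7, 0), "O"),
        _atom("CB", "ARG", 2, (4.3, 3.2, 1.2), "C"),
        _atom("CG", "ARG", 2, (4.9, 4.6, 1.1), "C", altloc="A", occ=0.57),
        _atom("CG", "ARG", 2, (4.7, 4.5, 2.5), "C", altloc="B", occ=0.43),
        _atom("NE", "ARG", 2, (5.5, 5.5, 2.0), "N", altloc="A", occ=0.57),
        _atom("NE", "ARG", 2, (5.1, 5.9, 3.1), "N", altloc="B", occ=0.43),
    ]
    return ProteinStructure(atoms, id="toy")


class TestReadWrite:
    def test_minimal_single_atom_parse(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(MINIMAL_PDB)
        s = read_structure(path)
        assert len(s) == 1
        a = s.atoms[0]
        assert a.name == "CA" and a.occupancy == 1.0 and a.altloc == ""
        assert np.allclose(a.position, [11, 12, 13])

    def test_roundtrip_preserves_atom_table(self, tmp_path, tunnel_system):
        protein, _, _ = tunnel_system
        path = tmp_path / "tunnel.pdb"
        write_structure(protein, path)
        back = read_structure(path)
        assert len(back) == len(protein)
        assert [a.name for a in back.atoms] == [a.name for a in protein.atoms]
        assert [a.element for a in back.atoms] == [a.element for a in protein.atoms]
        # PDB coordinate fields carry 3 decimals
        assert np.allclose(back.coords, protein.coords, atol=1.5e-3)

    def test_roundtrip_preserves_altlocs_and_occupancies(self, tmp_path):
        s = _altloc_structure()
        path = tmp_path / "alt.pdb"
        write_structure(s, path)
        back = read_structure(path)
        assert [a.altloc for a in back.atoms] == [a.altloc for a in s.atoms]
        assert np.allclose(
            [a.occupancy for a in back.atoms], [a.occupancy for a in s.atoms]
        )

    def test_parse_error_names_line_number(self, tmp_path):
        bad = MINIMAL_PDB.replace("11.000", "xx.xxx")
        path = tmp_path / "bad.pdb"
        path.write_text(bad)
        with pytest.raises(StructureParseError, match="line 1"):
            read_structure(path)

    def test_truncated_record_rejected(self, tmp_path):
        path = tmp_path / "short.pdb"
        path.write_text("ATOM      1  CA  ALA A   1      11.000\n")
        with pytest.raises(StructureParseError, match="line 1"):
            read_structure(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(StructureParseError):
            read_structure(tmp_path / "absent.pdb")

    def test_unknown_dialect(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(MINIMAL_PDB)
        with pytest.raises(StructureError):
            read_structure(path, dialect="xyz")

    def test_mmcif_dialect(self, tmp_path):
        import gemmi

        s = _altloc_structure()
        pdb_path = tmp_path / "alt.pdb"
        write_structure(s, pdb_path)
        st = gemmi.read_pdb(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "alt.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        back = read_structure(cif_path, dialect="mmcif")
        assert len(back) == len(s)
        assert sorted(a.altloc for a in back.atoms) == sorted(a.altloc for a in s.atoms)


class TestInvariants:
    def test_occupancy_sum_checked(self):
        atoms = [
            _atom("CG", "ARG", 2, (0, 0, 0), "C", altloc="A", occ=0.8),
            _atom("CG", "ARG", 2, (1, 0, 0), "C", altloc="B", occ=0.4),
        ]
        with pytest.raises(StructureError, match="occupanc"):
            ProteinStructure(atoms)

    def test_occupancy_range_checked(self):
        with pytest.raises(StructureError):
            _atom("CA", "ALA", 1, (0, 0, 0), occ=1.5)

    def test_nonfinite_position_rejected(self):
        with pytest.raises(StructureError):
            _atom("CA", "ALA", 1, (np.nan, 0, 0))

    def test_residue_index_covers_all_atoms(self, tunnel_system):
        protein, _, _ = tunnel_system
        covered = sorted(i for idx in protein.residue_index.values() for i in idx)
        assert covered == list(range(len(protein)))


class TestSelectModel:
    def test_altloc_choice_keeps_single_conformer(self):
        s = _altloc_structure()
        m = ConformerModel(groups={"Arg2": [("A", 2)]}, choices={"Arg2": "A"})
        out = select_model(s, m)
        names = [(a.name, a.altloc) for a in out.residue("A", 2)]
        assert ("CG", "") in names and ("NE", "") in names
        assert all(alt == "" for _, alt in names)
        # no duplicate (chain, seq, name) keys remain
        keys = [(a.chain_id, a.residue_seq, a.name) for a in out.atoms]
        assert len(keys) == len(set(keys))

    def test_absent_altloc_choice_lists_available(self):
        s = _altloc_structure()
        m = ConformerModel(groups={"Arg2": [("A", 2)]}, choices={"Arg2": "C"})
        with pytest.raises(StructureError, match=r"\['A', 'B'\]"):
            select_model(s, m)

    def test_delete_group_removes_all_atoms(self):
        s = _altloc_structure()
        m = ConformerModel(
            groups={"Gly1": [("A", 1)]}, modifications=[("delete_group", "Gly1")]
        )
        out = select_model(s, m)
        assert ("A", 1) not in out.residue_index
        assert len(out) == len(s) - 4

    def test_truncate_to_alanine(self):
        s = _altloc_structure()
        m = ConformerModel(
            groups={"Arg2": [("A", 2)]},
            modifications=[("truncate_to_alanine", "Arg2")],
        )
        out = select_model(s, m)
        residue = out.residue("A", 2)
        assert sorted(a.name for a in residue) == ["C", "CA", "CB", "N", "O"]
        assert all(a.residue_name == "ALA" for a in residue)

    def test_untouched_atoms_identical(self):
        s = _altloc_structure()
        m = ConformerModel(groups={"Arg2": [("A", 2)]}, choices={"Arg2": "B"})
        out = select_model(s, m)
        assert np.allclose(
            [a.position for a in out.residue("A", 1)],
            [a.position for a in s.residue("A", 1)],
        )

    def test_unknown_group_residue_errors(self):
        s = _altloc_structure()
        m = ConformerModel(groups={"X": [("A", 99)]}, choices={"X": "A"})
        with pytest.raises(StructureError, match="absent"):
            select_model(s, m)

    def test_collapse_altlocs_prefers_occupancy_then_a(self):
        s = _altloc_structure()
        out = collapse_altlocs(s)
        cg = [a for a in out.residue("A", 2) if a.name == "CG"]
        assert len(cg) == 1 and cg[0].occupancy == 1.0
        # tie case breaks toward 'A'
        atoms = [
            _atom("CG", "ARG", 2, (0, 0, 0), "C", altloc="A", occ=0.5),
            _atom("CG", "ARG", 2, (9, 0, 0), "C", altloc="B", occ=0.5),
        ]
        tie = collapse_altlocs(ProteinStructure(atoms))
        assert np.allclose(tie.atoms[0].position, [0, 0, 0])


class TestPolarRoles:
    def test_canonical_residue_dictionary(self):
        atoms = [
            _atom("OG", "SER", 1, (0, 0, 0), "O"),
            _atom("OD1", "ASP", 2, (3, 0, 0), "O"),
            _atom("CB", "ALA", 3, (6, 0, 0), "C"),
            _atom("N", "PRO", 4, (9, 0, 0), "N"),
            _atom("N", "LEU", 5, (12, 0, 0), "N"),
            _atom("O", "HOH", 6, (15, 0, 0), "O"),
            _atom("NZ", "LYS", 7, (18, 0, 0), "N"),
            _atom("NE2", "GLN", 8, (21, 0, 0), "N"),
            _atom("OE1", "GLN", 8, (22, 0, 0), "O"),
        ]
        out = assign_polar_roles(ProteinStructure(atoms))
        roles = {(a.residue_name, a.name): a.polar_role for a in out.atoms}
        assert roles[("SER", "OG")] == "both"
        assert roles[("ASP", "OD1")] == "acceptor"
        assert roles[("ALA", "CB")] == "none"
        assert roles[("PRO", "N")] == "none"
        assert roles[("LEU", "N")] == "donor"
        assert roles[("HOH", "O")] == "both"
        assert roles[("LYS", "NZ")] == "donor"
        assert roles[("GLN", "NE2")] == "donor"
        assert roles[("GLN", "OE1")] == "acceptor"

    def test_nonstandard_residue_warns_never_crashes(self):
        atoms = [_atom("O1", "XYZ", 1, (0, 0, 0), "O")]
        with pytest.warns(UserWarning, match="XYZ"):
            out = assign_polar_roles(ProteinStructure(atoms))
        assert out.atoms[0].polar_role == "none"


class TestLigandConformers:
    def test_extraction_roundtrip(self, tmp_path, small_library):
        atoms = []
        serial = 0
        for k, conf in enumerate(small_library):
            for a in conf.atoms:
                serial += 1
                b = a.copy()
                b.serial = serial
                b.residue_seq = k + 1
                atoms.append(b)
        path = tmp_path / "lib.pdb"
        write_structure(ProteinStructure(atoms, id="lib"), path)
        confs, excluded = extract_ligand_conformers([path], "SLG")
        assert len(confs) == len(small_library) and excluded == 0
        for conf in confs:
            inv = conf.inversion_map
            assert np.array_equal(inv[inv], np.arange(conf.n_atoms))

    def test_incomplete_conformer_excluded_and_counted(self, tmp_path, small_library):
        atoms = []
        for k, conf in enumerate(small_library[:3]):
            for i, a in enumerate(conf.atoms):
                if k == 1 and a.name == "C3":  # delete one ring atom
                    continue
                b = a.copy()
                b.residue_seq = k + 1
                atoms.append(b)
        path = tmp_path / "partial.pdb"
        write_structure(ProteinStructure(atoms, id="partial"), path)
        confs, excluded = extract_ligand_conformers([path], "SLG")
        assert len(confs) == 2 and excluded == 1

    def test_absent_species_errors(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(MINIMAL_PDB)
        with pytest.raises(StructureError, match="LUT"):
            extract_ligand_conformers([path], "LUT")

    def test_unknown_species_dictionary_errors(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(MINIMAL_PDB)
        with pytest.raises(StructureError, match="dictionary"):
            extract_ligand_conformers([path], "QQQ")


class TestHydroxylSpan:
    def test_three_four_five_triangle(self):
        from tunneldock.structures import LigandConformer

        positions = [
            (0.0, 0.0, 0.0),    # O1
            (0.6, 0.4, 0.0),    # beta ring
            (0.6, -0.4, 0.0),
            (2.4, 4.4, 0.0),    # epsilon ring
            (2.4, 3.6, 0.0),
            (3.0, 4.0, 0.0),    # O2
        ]
        atoms = [
            _atom(f"C{i}" if 0 < i < 5 else f"O{1 if i == 0 else 2}",
                  "TOY", 1, p, "C" if 0 < i < 5 else "O", chain="L")
            for i, p in enumerate(positions)
        ]
        conf = LigandConformer(
            atoms=atoms,
            hydroxyl_indices=(0, 5),
            ring_labels={"beta": [1, 2], "epsilon": [3, 4]},
            inversion_map=np.array([5, 4, 3, 2, 1, 0]),
            species="TOY",
        )
        assert hydroxyl_span(conf) == pytest.approx(5.0)

    def test_span_matches_generator_parameter(self):
        conf = make_ligand_library(LigandSpec(n_conformers=1, jitter=0.0, span=27.0))[0]
        assert hydroxyl_span(conf) == pytest.approx(27.0, abs=1e-9)

    def test_rigid_invariance(self, canonical_ligand):
        from conftest import random_rigid

        rng = np.random.default_rng(11)
        base = hydroxyl_span(canonical_ligand)
        for _ in range(5):
            R, t = random_rigid(rng)
            moved = canonical_ligand.with_coords(canonical_ligand.coords @ R.T + t)
            assert hydroxyl_span(moved) == pytest.approx(base, abs=1e-9)

    def test_invariant_under_inversion_relabel(self, canonical_ligand):
        conf = canonical_ligand
        inverted = conf.with_coords(conf.coords[conf.inversion_map])
        assert hydroxyl_span(inverted) == pytest.approx(hydroxyl_span(conf), abs=1e-9)
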