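import numpy as np
import pytest

from pocketatlas import (
    Atom,
    PocketComplex,
    Residue,
    generate_synthetic_complex,
    list_ligands,
    read_complex,
    write_pdb,
)
from pocketatlas.errors import (
    AmbiguousLigand,
    EmptyProtein,
    GenerationError,
    LigandNotFound,
    ParseError,
)

from conftest import pdb_atom_line


class TestReadComplex:
    def test_minimal_two_residue_complex(self, two_residue_pdb):
        cplx = read_complex(two_residue_pdb, "LIG")
        assert len(cplx.residues) == 2
        assert cplx.sequence == "AG"
        assert len(cplx.ligand_atoms) == 2
        assert [r.seq_index for r in cplx.residues] == [0, 1]
        # author numbering retained
        assert cplx.author_lookup[("A", 1, "")] == 0
        assert cplx.author_lookup[("A", 2, "")] == 1

    def test_water_never_selectable(self, two_residue_pdb):
        with pytest.raises(LigandNotFound):
            read_complex(two_residue_pdb, "HOH")

    def test_buffer_never_selectable(self):
        lines = [
            pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
            pdb_atom_line(2, "C1", "GOL", "A", 90, 1.0, 1.0, 1.0, "C", het=True),
            "END",
        ]
        with pytest.raises(LigandNotFound):
            read_complex("\n".join(lines), "GOL")

    def test_ambiguous_ligand_without_disambiguator(self, two_chain_atp_pdb):
        with pytest.raises(AmbiguousLigand):
            read_complex(two_chain_atp_pdb, "ATP")

    def test_chain_disambiguator_selects_one_copy(self, two_chain_atp_pdb):
        cplx = read_complex(two_chain_atp_pdb, "ATP:B")
        assert len(cplx.ligand_atoms) == 1
        # chain with the most ligand contacts is extracted
        assert {r.chain_id for r in cplx.residues} == {"B"}

    def test_empty_protein_after_filter(self, two_residue_pdb):
        with pytest.raises(EmptyProtein):
            read_complex(two_residue_pdb, "LIG", chain_filter=["Q"])

    def test_unknown_ligand_code(self, two_residue_pdb):
        with pytest.raises(LigandNotFound):
            read_complex(two_residue_pdb, "XYZ")

    def test_hydrogens_dropped_by_default(self):
        lines = [
            pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
            pdb_atom_line(2, "HA", "ALA", "A", 1, 0.5, 0.5, 0.5, "H"),
            pdb_atom_line(3, "C1", "LIG", "A", 90, 1.0, 1.0, 1.0, "C", het=True),
            "END",
        ]
        cplx = read_complex("\n".join(lines), "LIG")
        assert [a.atom_name for a in cplx.residues[0].atoms] == ["CA"]

    def test_altloc_highest_occupancy_wins(self):
        lines = [
            pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C",
                          altloc="A", occ=0.4),
            pdb_atom_line(2, "CA", "ALA", "A", 1, 5.0, 0.0, 0.0, "C",
                          altloc="B", occ=0.6),
            pdb_atom_line(3, "C1", "LIG", "A", 90, 1.0, 1.0, 1.0, "C", het=True),
            "END",
        ]
        cplx = read_complex("\n".join(lines), "LIG")
        assert cplx.residues[0].atoms[0].coords[0] == pytest.approx(5.0)

    def test_altloc_tie_prefers_a(self):
        lines = [
            pdb_atom_line(1, "CA", "ALA", "A", 1, 5.0, 0.0, 0.0, "C",
                          altloc="B", occ=0.5),
            pdb_atom_line(2, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C",
                          altloc="A", occ=0.5),
            pdb_atom_line(3, "C1", "LIG", "A", 90, 1.0, 1.0, 1.0, "C", het=True),
            "END",
        ]
        cplx = read_complex("\n".join(lines), "LIG")
        assert cplx.residues[0].atoms[0].coords[0] == pytest.approx(0.0)

    def test_nonstandard_residue_maps_to_x_and_is_reported(self):
        lines = [
            pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
            pdb_atom_line(2, "CA", "UNK", "A", 2, 3.8, 0.0, 0.0, "C"),
            pdb_atom_line(3, "C1", "LIG", "A", 90, 1.0, 1.0, 1.0, "C", het=True),
            "END",
        ]
        cplx = read_complex("\n".join(lines), "LIG")
        assert cplx.sequence == "AX"
        assert cplx.parse_report["nonstandard_residues"] == ["A/UNK2"]


class TestListLigands:
    def test_waters_excluded(self, two_residue_pdb):
        assert list_ligands(two_residue_pdb) == [("LIG", "A", 101, 2)]

    def test_no_hetatm(self):
        lines = [
            pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
            "END",
        ]
        assert list_ligands("\n".join(lines)) == []

    def test_two_copies_listed(self, two_chain_atp_pdb):
        out = list_ligands(two_chain_atp_pdb)
        assert len(out) == 2
        assert [o[0] for o in out] == ["ATP", "ATP"]

    def test_unparseable_input(self):
        with pytest.raises(ParseError):
            list_ligands("this is\nnot a pdb\n\x00\x01")


class TestRoundTrip:
    def test_pdb_round_trip(self, standard_truth):
        cplx = standard_truth.complex
        text = write_pdb(cplx)
        back = read_complex(text, cplx.ligand_name, chain_filter=["A"])
        assert back.sequence == cplx.sequence
        assert len(back.residues) == len(cplx.residues)
        assert [r.res_name for r in back.residues] == [r.res_name for r in cplx.residues]
        np.testing.assert_allclose(
            back.protein_coords(), cplx.protein_coords(), atol=1.5e-3
        )
        np.testing.assert_allclose(
            back.ligand_coords(), cplx.ligand_coords(), atol=1.5e-3
        )

    def test_json_round_trip(self, standard_truth):
        cplx = standard_truth.complex
        back = PocketComplex.from_json(cplx.to_json())
        assert back.sequence == cplx.sequence
        assert back.author_lookup == cplx.author_lookup
        np.testing.assert_allclose(back.protein_coords(), cplx.protein_coords(),
                                   atol=1e-4)


class TestDomainTypes:
    def test_atom_requires_finite_coords(self):
        with pytest.raises(ValueError):
            Atom("C", np.array([np.nan, 0, 0]), "CA")

    def test_residue_requires_atoms(self):
        with pytest.raises(ValueError):
            Residue("A", 0, "ALA", [])

    def test_complex_requires_ligand(self, standard_truth):
        with pytest.raises(ValueError):
            PocketComplex("x", standard_truth.complex.residues, [])


class TestSyntheticGenerator:
    def test_planted_constraints_hold_exactly(self, standard_truth):
        truth = standard_truth
        cplx = truth.complex
        assert truth.planted_interface == {5, 6, 9}
        lig = cplx.ligand_coords()
        r = truth.truncation_radius
        for res in cplx.residues:
            dmin = min(
                np.linalg.norm(a.coords - l) for a in res.atoms for l in lig
            )
            i = res.seq_index
            if i in truth.planted_interface:
                assert dmin <= 0.6 * r
            elif i in truth.buried_decoys:
                assert dmin <= r
            else:
                assert dmin > r

    def test_deterministic_for_fixed_seed(self, standard_truth):
        again = generate_synthetic_complex(20, {5, 6, 9}, 6.0, seed=7)
        assert np.array_equal(
            again.complex.protein_coords(), standard_truth.complex.protein_coords()
        )
        assert np.array_equal(
            again.complex.ligand_coords(), standard_truth.complex.ligand_coords()
        )
        assert again.complex.sequence == standard_truth.complex.sequence

    def test_different_seeds_differ(self, standard_truth):
        other = generate_synthetic_complex(20, {5, 6, 9}, 6.0, seed=8)
        assert not np.array_equal(
            other.complex.protein_coords(), standard_truth.complex.protein_coords()
        )

    def test_out_of_range_interface_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_complex(20, {50}, 6.0, seed=1)

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_complex(5, {1}, 6.0, seed=1)

    def test_too_many_interface_positions(self):
        with pytest.raises(GenerationError):
            generate_synthetic_complex(40, set(range(1, 38, 4)), 6.0, seed=1)

    def test_helixlike_backbone_spacing(self, standard_truth):
        ca = np.array(
            [r.atoms[0].coords for r in standard_truth.complex.residues]
        )
        steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        # helix-like: consecutive CA atoms a few Å apart, never clashing
        assert steps.min() > 1.0
        assert np.median(steps) < 5.0
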