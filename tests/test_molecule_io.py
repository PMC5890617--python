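"""Molecule parsing and normalisation."""

import pytest
from rdkit import Chem

from parity.molecule import (
    ComponentTable,
    MoleculeParseError,
    load_component_table,
    parse_molfile,
    parse_sdf,
    parse_smiles,
    write_smiles,
)


def molblock(smiles: str) -> str:
    return Chem.MolToMolBlock(Chem.MolFromSmiles(smiles))


@pytest.mark.parametrize(
    "smiles, n_atoms, elements",
    [
        ("CCO", 3, {"C": 2, "O": 1}),
        ("O", 1, {"O": 1}),
        ("OC(=O)CCC(=O)C(O)=O", 10, {"C": 5, "O": 5}),   # 2-oxoglutarate
        ("OC(=O)CNC(=O)C(O)=O", 10, {"C": 4, "N": 1, "O": 5}),  # N-oxalylglycine
    ],
)
def test_parse_smiles_heavy_atom_counts(smiles, n_atoms, elements):
    m = parse_smiles(smiles, "X")
    assert m.n_atoms == n_atoms
    assert m.element_multiset() == elements


def test_ethanol_bond_count():
    assert len(parse_smiles("CCO", "ETOH").bonds) == 2


def test_unparseable_smiles_carries_id_and_source():
    with pytest.raises(MoleculeParseError) as exc:
        parse_smiles("not-a-smiles((", "BAD1")
    assert exc.value.id == "BAD1"
    assert "not-a-smiles((" in str(exc.value)


def test_empty_smiles_rejected():
    with pytest.raises(MoleculeParseError):
        parse_smiles("   ", "E")


def test_hydrogens_always_suppressed():
    m = parse_smiles("[H]C([H])([H])[H]", "CH4")
    assert m.n_atoms == 1
    assert m.elements == ("C",)


def test_salt_keeps_largest_fragment():
    m = parse_smiles("CC(=O)[O-].[Na+]", "NAACT")
    assert m.n_atoms == 4
    assert "Na" not in m.element_multiset()


def test_parse_molfile_methane():
    assert parse_molfile(molblock("C"), "CH4").n_atoms == 1


def test_parse_molfile_r_group_flags_markush():
    m = parse_molfile(molblock("*c1ccccc1"), "RBZ")
    assert m.n_atoms == 7
    assert m.is_markush
    assert sum(a.is_r_group for a in m.atoms) == 1


def test_parse_molfile_oxalylglycine_atoms():
    m = parse_molfile(molblock("OC(=O)CNC(=O)C(O)=O"), "OGA")
    assert m.n_atoms == 10
    assert m.element_multiset() == {"C": 4, "N": 1, "O": 5}


def test_malformed_molblock_raises_with_location():
    with pytest.raises(MoleculeParseError) as exc:
        parse_molfile("garbage\nnot\na molfile\nxx yy\n", "BAD")
    assert "line" in str(exc.value)


def test_smiles_and_molfile_paths_agree(corpus):
    for cid in ("C00026", "OGA", "C00114", "C07088"):
        via_smiles = corpus.compound_table[cid]
        via_mol = parse_molfile(molblock(write_smiles(via_smiles)), cid)
        assert via_mol.element_multiset() == via_smiles.element_multiset()
        assert len(via_mol.bonds) == len(via_smiles.bonds)


def test_smiles_round_trip_preserves_graph(corpus):
    for cid, m in corpus.compound_table.molecules.items():
        back = parse_smiles(write_smiles(m), cid)
        assert back.element_multiset() == m.element_multiset(), cid
        assert len(back.bonds) == len(m.bonds), cid


def test_parse_sdf_yields_named_records():
    sdf = molblock("CCO") + "$$$$\n" + molblock("CC") + "$$$$\n"
    mols = list(parse_sdf(sdf))
    assert [m.n_atoms for m in mols] == [3, 2]


class TestComponentTable:
    def test_csv_loading(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("OGA,OC(=O)CNC(=O)C(O)=O\n")
        t = load_component_table(p)
        assert len(t) == 1
        assert t["OGA"].n_atoms == 10

    def test_empty_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("")
        assert len(load_component_table(p)) == 0

    def test_duplicate_id_raises_naming_it(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("AAA,CC\nAAA,CCC\n")
        with pytest.raises(ValueError, match="AAA"):
            load_component_table(p)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            load_component_table("/nonexistent/components.csv")

    def test_unusable_entries_skipped_and_counted(self):
        t = ComponentTable.from_pairs(
            [("OK", "CCO"), ("BAD", "(((("), ("H", "[H+]")]
        )
        assert len(t) == 1
        assert t.n_skipped == 2
        assert set(t.skipped_ids) == {"BAD", "H"}

    def test_mmcif_dialect(self, tmp_path):
        cif = (
            "data_OGA\n"
            "_chem_comp.id OGA\n"
            "loop_\n"
            "_pdbx_chem_comp_descriptor.comp_id\n"
            "_pdbx_chem_comp_descriptor.type\n"
            "_pdbx_chem_comp_descriptor.program\n"
            "_pdbx_chem_comp_descriptor.descriptor\n"
            'OGA SMILES_CANONICAL OpenEye "OC(=O)CNC(=O)C(O)=O"\n'
        )
        p = tmp_path / "ccd.cif"
        p.write_text(cif)
        t = load_component_table(p)
        assert t["OGA"].n_atoms == 10
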