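"""Molecular data model, PDB reading, bond perception and atom typing."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from eemkit.structures import (
    Atom,
    Bond,
    ChargeTable,
    MissingHydrogensError,
    Molecule,
    StructureError,
    assign_atom_types,
    ex_to_e_key,
    formal_total_charge,
    perceive_bonds,
    read_charge_table,
    read_pdb,
    require_hydrogens,
    write_charge_table,
)
from eemkit.synthetic import gly_gly, ser_gly


def pdb_line(record, serial, name, resname, chain, resnum, x, y, z,
             occ=1.0, altloc=" ", icode=" ", element=""):
    if len(name) < 4:
        name = f" {name:<3}"
    return (
        f"{record:<6}{serial:>5} {name}{altloc}{resname:>3} {chain}"
        f"{resnum:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def test_read_pdb_water(tmp_path):
    text = "\n".join([
        pdb_line("ATOM", 1, "O", "HOH", "A", 1, 0.0, 0.0, 0.0, element="O"),
        pdb_line("ATOM", 2, "H1", "HOH", "A", 1, 0.96, 0.0, 0.0, element="H"),
        pdb_line("ATOM", 3, "H2", "HOH", "A", 1, -0.24, 0.93, 0.0, element="H"),
        "END",
    ])
    path = tmp_path / "water.pdb"
    path.write_text(text + "\n")
    mol = read_pdb(path)
    assert mol.n_atoms == 3
    assert [a.element for a in mol.atoms] == ["O", "H", "H"]
    assert all(a.residue_name == "HOH" for a in mol.atoms)


def test_read_pdb_default_model_is_first(tmp_path):
    lines = ["MODEL        1",
             pdb_line("ATOM", 1, "O", "HOH", "A", 1, 0.0, 0.0, 0.0, element="O"),
             "ENDMDL",
             "MODEL        2",
             pdb_line("ATOM", 1, "O", "HOH", "A", 1, 5.0, 0.0, 0.0, element="O"),
             "ENDMDL", "END"]
    path = tmp_path / "nmr.pdb"
    path.write_text("\n".join(lines) + "\n")
    mol = read_pdb(path)
    assert mol.n_atoms == 1
    assert mol.atoms[0].coords[0] == pytest.approx(0.0)
    mol2 = read_pdb(path, model_index=1)
    assert mol2.atoms[0].coords[0] == pytest.approx(5.0)
    with pytest.raises(StructureError, match="model"):
        read_pdb(path, model_index=5)


def test_alpha_carbon_without_element_columns_is_carbon(tmp_path):
    # " CA " in a standard residue with blank element columns must resolve to
    # carbon, never calcium; a HETATM calcium ion (name at column 13) stays Ca.
    lines = [
        pdb_line("ATOM", 1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
        pdb_line("ATOM", 2, "CA", "ALA", "A", 1, 1.46, 0.0, 0.0),
        pdb_line("HETATM", 3, "CA  ", "CA", "B", 1, 9.0, 9.0, 9.0, element="CA"),
        "END",
    ]
    path = tmp_path / "ca.pdb"
    path.write_text("\n".join(lines) + "\n")
    mol = read_pdb(path)
    assert mol.atoms[1].element == "C"
    assert mol.atoms[2].element == "Ca"


def test_altloc_keeps_highest_occupancy(tmp_path):
    lines = [
        pdb_line("ATOM", 1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, element="N"),
        pdb_line("ATOM", 2, "CA", "ALA", "A", 1, 0.0, 1.46, 0.0, occ=0.4, altloc="A", element="C"),
        pdb_line("ATOM", 3, "CA", "ALA", "A", 1, 1.46, 0.0, 0.0, occ=0.6, altloc="B", element="C"),
        "END",
    ]
    path = tmp_path / "alt.pdb"
    path.write_text("\n".join(lines) + "\n")
    mol = read_pdb(path)
    cas = [a for a in mol.atoms if a.name.strip() == "CA"]
    assert len(cas) == 1
    assert cas[0].coords[0] == pytest.approx(1.46)


def test_read_pdb_unreadable(tmp_path):
    with pytest.raises(StructureError):
        read_pdb(tmp_path / "nonexistent.pdb")


# ---------------------------------------------------------------------------
# Bond perception
# ---------------------------------------------------------------------------

def test_glycine_dipeptide_carbonyls_are_double_bonded():
    mol = gly_gly()
    for res in (1, 2):
        o_idx = next(a.index for a in mol.atoms if a.name == "O" and a.residue_number == res)
        incident = [b for b in mol.bonds if o_idx in (b.i, b.j)]
        assert len(incident) == 1
        assert incident[0].order == 2


def test_peptide_bond_found_between_residues():
    mol = gly_gly()
    c1 = next(a.index for a in mol.atoms if a.name == "C" and a.residue_number == 1)
    n2 = next(a.index for a in mol.atoms if a.name == "N" and a.residue_number == 2)
    assert any(b.pair == (min(c1, n2), max(c1, n2)) for b in mol.bonds)


def test_disulfide_bond_at_2_05_angstrom():
    spec = [
        ("N", "N", 1, (0.0, 0.0, 0.0)), ("C", "CA", 1, (1.46, 0.0, 0.0)),
        ("C", "CB", 1, (2.0, 1.35, 0.0)), ("S", "SG", 1, (2.6, 2.9, 0.0)),
        ("S", "SG", 2, (2.6, 4.95, 0.0)), ("C", "CB", 2, (2.0, 6.5, 0.0)),
        ("C", "CA", 2, (1.46, 7.9, 0.0)), ("N", "N", 2, (0.0, 7.9, 0.0)),
    ]
    atoms = [Atom(index=i, element=e, name=n, coords=xyz, residue_number=r,
                  residue_name="CYS") for i, (e, n, r, xyz) in enumerate(spec)]
    bonds = perceive_bonds(Molecule("ss", atoms))
    ss = [b for b in bonds if {atoms[b.i].name, atoms[b.j].name} == {"SG"}]
    assert len(ss) == 1
    assert ss[0].order == 1


def test_isolated_calcium_ion_gets_no_bonds():
    mol = ser_gly(with_calcium=True)
    ca = next(a.index for a in mol.atoms if a.element == "Ca")
    assert not any(ca in (b.i, b.j) for b in mol.bonds)


def test_clash_raises():
    atoms = [
        Atom(index=0, element="C", name="C1", coords=(0, 0, 0), residue_name="SYN"),
        Atom(index=1, element="C", name="C2", coords=(0.3, 0, 0), residue_name="SYN"),
    ]
    with pytest.raises(StructureError, match="clash"):
        perceive_bonds(Molecule("clash", atoms))


def test_unknown_residue_falls_back_to_distance_bonds():
    atoms = [
        Atom(index=0, element="C", name="C1", coords=(0, 0, 0), residue_name="LIG"),
        Atom(index=1, element="O", name="O1", coords=(1.4, 0, 0), residue_name="LIG"),
        Atom(index=2, element="C", name="C2", coords=(8.0, 0, 0), residue_name="LIG"),
    ]
    with pytest.warns(UserWarning, match="no bond template"):
        bonds = perceive_bonds(Molecule("lig", atoms))
    assert [b.pair for b in bonds] == [(0, 1)]


def test_bond_perception_rotation_invariant():
    mol = gly_gly()
    R = Rotation.from_euler("xyz", [31, -47, 119], degrees=True).as_matrix()
    rotated = mol.with_coords(mol.coords @ R.T + np.array([3.0, -2.0, 7.0]))
    assert sorted((b.pair, b.order) for b in perceive_bonds(rotated)) == sorted(
        (b.pair, b.order) for b in mol.bonds
    )


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------

def test_ex_typing_distinguishes_oxygen_environments():
    mol = ser_gly(with_calcium=True)
    types = dict(zip([(a.residue_name, a.name) for a in mol.atoms],
                     assign_atom_types(mol, "EX")))
    assert types[("SER", "OG")] == "O1"      # hydroxyl: singly bonded
    assert types[("SER", "O")] == "O2"       # carbonyl: doubly bonded
    assert types[("GLY", "O")] == "O2"
    assert types[("CA", "CA")] == "Ca"       # unbonded ion: bare element


def test_e_typing_is_element_only(gly_gly):
    assert assign_atom_types(gly_gly, "E") == [a.element for a in gly_gly.atoms]


def test_ex_refines_e(ser_gly_ca):
    ex = assign_atom_types(ser_gly_ca, "EX")
    e = assign_atom_types(ser_gly_ca, "E")
    assert [ex_to_e_key(t) for t in ex] == e


def test_typing_permutation_invariant(gly_gly):
    rng = np.random.default_rng(4)
    perm = rng.permutation(gly_gly.n_atoms)
    inv = np.argsort(perm)
    atoms = [
        Atom(index=k, element=a.element, name=a.name, coords=a.coords,
             residue_number=a.residue_number, residue_name=a.residue_name)
        for k, a in enumerate(gly_gly.atoms[p] for p in perm)
    ]
    bonds = [Bond(int(inv[b.i]), int(inv[b.j]), b.order) for b in gly_gly.bonds]
    shuffled = Molecule("perm", atoms, bonds)
    types_s = assign_atom_types(shuffled, "EX")
    types = assign_atom_types(gly_gly, "EX")
    assert [types_s[inv[k]] for k in range(gly_gly.n_atoms)] == types


# ---------------------------------------------------------------------------
# Formal charges and hydrogens
# ---------------------------------------------------------------------------

def test_formal_charge_free_arginine():
    atoms = [Atom(index=0, element="N", name="N", coords=(0, 0, 0), residue_name="ARG")]
    assert formal_total_charge(Molecule("arg", atoms)) == 1  # +1 side chain +1 Nterm -1 Cterm


def test_formal_charge_calcium_alone():
    atoms = [Atom(index=0, element="Ca", name="CA", coords=(0, 0, 0),
                  residue_name="CA", formal_charge=2)]
    assert formal_total_charge(Molecule("ca", atoms)) == 2


def test_formal_charge_neutral_dipeptide(gly_gly):
    assert formal_total_charge(gly_gly) == 0


def test_require_hydrogens_rejects_heavy_only():
    atoms = [
        Atom(index=0, element="N", name="N", coords=(0, 0, 0), residue_name="GLY"),
        Atom(index=1, element="C", name="CA", coords=(1.46, 0, 0), residue_name="GLY"),
    ]
    with pytest.raises(MissingHydrogensError, match="hydrogens"):
        require_hydrogens(Molecule("noH", atoms))


# ---------------------------------------------------------------------------
# Charge table I/O
# ---------------------------------------------------------------------------

def test_charge_table_roundtrip(tmp_path):
    table = ChargeTable("m1", [(0, "O", -0.8123456), (1, "H1", 0.4061728), (2, "H2", 0.4061728)])
    path = tmp_path / "m1.charges.tsv"
    write_charge_table(table, path)
    back = read_charge_table(path)
    assert back.molecule_id == "m1"
    assert back.entries == [(i, n, pytest.approx(q, abs=1e-6)) for i, n, q in table.entries]


def test_charge_table_duplicate_index_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        ChargeTable("m1", [(0, "O", -0.8), (0, "H1", 0.4)])


def test_charge_table_no_sum_check_at_io_layer(tmp_path):
    # a tiny nonzero sum for a nominally neutral molecule is an upstream
    # concern, not an I/O error
    table = ChargeTable("m1", [(0, "O", 0.000001)])
    path = tmp_path / "t.tsv"
    write_charge_table(table, path)
    assert read_charge_table(path).entries[0][2] == pytest.approx(1e-6)


def test_charge_table_count_mismatch(gly_gly):
    table = ChargeTable("m1", [(0, "O", 0.0)])
    with pytest.raises(ValueError, match="entries"):
        table.check_against(gly_gly)
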