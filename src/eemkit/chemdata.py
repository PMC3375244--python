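"""Chemical reference tables: electronegativities, covalent radii, residue bond templates.

All distances are in angstroms; electronegativities are on the Pauling scale.
"""

from __future__ import annotations

# Pauling-scale electronegativities (Allred's revised values) for the elements
# the charge model supports.
PAULING_ELECTRONEGATIVITY: dict[str, float] = {
    "H": 2.20,
    "C": 2.55,
    "N": 3.04,
    "O": 3.44,
    "S": 2.58,
    "Ca": 1.00,
    # common counter-ions that may ride along in structures
    "Na": 0.93,
    "K": 0.82,
    "Mg": 1.31,
    "Zn": 1.65,
    "Cl": 3.16,
}

# Single-bond covalent radii (Cordero et al. consensus values).
COVALENT_RADIUS: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "Ca": 1.76,
    "Na": 1.66,
    "K": 2.03,
    "Mg": 1.41,
    "Zn": 1.22,
    "Cl": 1.02,
}

#: Extra slack added to the sum of covalent radii when deciding bonded pairs.
COVALENT_TOLERANCE = 0.4

#: S(gamma)-S(gamma) distance below which two cysteines are considered disulfide-bonded.
DISULFIDE_CUTOFF = 2.3

#: Any interatomic distance below this is a structural clash.
CLASH_DISTANCE = 0.5

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: Monoatomic ion residue names -> (element, formal charge).
ION_RESIDUES: dict[str, tuple[str, int]] = {
    "CA": ("Ca", 2),
    "NA": ("Na", 1),
    "K": ("K", 1),
    "MG": ("Mg", 2),
    "ZN": ("Zn", 2),
    "CL": ("Cl", -1),
}

# Formal side-chain charges at neutral pH (His kept neutral).
SIDECHAIN_FORMAL_CHARGE: dict[str, int] = {
    "ASP": -1,
    "GLU": -1,
    "LYS": 1,
    "ARG": 1,
    "HIS": 0,
}

# Backbone connectivity shared by every amino acid; C=O is a double bond.
_BACKBONE = [("N", "CA", 1), ("CA", "C", 1), ("C", "O", 2), ("C", "OXT", 1)]

# Heavy-atom side-chain bonds per residue with Kekule bond orders.  Aromatic
# rings carry alternating single/double orders so that "maximum bond order"
# atom typing distinguishes, e.g., carbonyl from hydroxyl oxygen.
_SIDECHAINS: dict[str, list[tuple[str, str, int]]] = {
    "GLY": [],
    "ALA": [("CA", "CB", 1)],
    "SER": [("CA", "CB", 1), ("CB", "OG", 1)],
    "CYS": [("CA", "CB", 1), ("CB", "SG", 1)],
    "THR": [("CA", "CB", 1), ("CB", "OG1", 1), ("CB", "CG2", 1)],
    "VAL": [("CA", "CB", 1), ("CB", "CG1", 1), ("CB", "CG2", 1)],
    "LEU": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 1), ("CG", "CD2", 1)],
    "ILE": [("CA", "CB", 1), ("CB", "CG1", 1), ("CB", "CG2", 1), ("CG1", "CD1", 1)],
    "MET": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "SD", 1), ("SD", "CE", 1)],
    "PRO": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1), ("CD", "N", 1)],
    "PHE": [
        ("CA", "CB", 1), ("CB", "CG", 1),
        ("CG", "CD1", 2), ("CD1", "CE1", 1), ("CE1", "CZ", 2),
        ("CZ", "CE2", 1), ("CE2", "CD2", 2), ("CD2", "CG", 1),
    ],
    "TYR": [
        ("CA", "CB", 1), ("CB", "CG", 1),
        ("CG", "CD1", 2), ("CD1", "CE1", 1), ("CE1", "CZ", 2),
        ("CZ", "CE2", 1), ("CE2", "CD2", 2), ("CD2", "CG", 1),
        ("CZ", "OH", 1),
    ],
    "TRP": [
        ("CA", "CB", 1), ("CB", "CG", 1),
        ("CG", "CD1", 2), ("CD1", "NE1", 1), ("NE1", "CE2", 1),
        ("CE2", "CD2", 1), ("CD2", "CG", 1),
        ("CE2", "CZ2", 2), ("CZ2", "CH2", 1), ("CH2", "CZ3", 2),
        ("CZ3", "CE3", 1), ("CE3", "CD2", 2),
    ],
    # Neutral His tautomer with the proton on NE2 (HIE); CE1=ND1 and CG=CD2.
    "HIS": [
        ("CA", "CB", 1), ("CB", "CG", 1),
        ("CG", "CD2", 2), ("CD2", "NE2", 1), ("NE2", "CE1", 1),
        ("CE1", "ND1", 2), ("ND1", "CG", 1),
    ],
    "ASP": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "OD1", 2), ("CG", "OD2", 1)],
    "GLU": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1), ("CD", "OE1", 2), ("CD", "OE2", 1)],
    "ASN": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "OD1", 2), ("CG", "ND2", 1)],
    "GLN": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1), ("CD", "OE1", 2), ("CD", "NE2", 1)],
    "LYS": [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1), ("CD", "CE", 1), ("CE", "NZ", 1)],
    "ARG": [
        ("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
        ("CD", "NE", 1), ("NE", "CZ", 1), ("CZ", "NH1", 2), ("CZ", "NH2", 1),
    ],
}

RESIDUE_BOND_TEMPLATES: dict[str, list[tuple[str, str, int]]] = {
    name: _BACKBONE + sidechain for name, sidechain in _SIDECHAINS.items()
}


def element_from_atom_name(name: str) -> str:
    """Resolve the element of an atom in a *standard amino acid* from its PDB name.

    Standard-residue atom names contain only C/N/O/S/H; digits and primes are
    positional decoration.  This deliberately maps the alpha-carbon name "CA"
    to carbon, never calcium.
    """
    stripped = name.strip().lstrip("0123456789'\"")
    if not stripped:
        raise ValueError(f"cannot resolve element from atom name {name!r}")
    first = stripped[0].upper()
    if first in ("H", "D"):
        return "H"
    if first in ("C", "N", "O", "S", "P"):
        return first
    raise ValueError(f"unexpected atom name {name!r} for a standard residue")
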