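"""Molecular data model, PDB input/output, bond perception and atom typing.

The unit of computation throughout the package is a :class:`Molecule` — an
ordered list of atoms with coordinates in angstroms, an optional bond list
with integer bond orders, and a total molecular charge in elementary charge
units (e).  Structures are read from PDB files through gemmi; bond orders for
standard amino acids come from residue templates so that the element+bond-order
atom-typing scheme ('EX') can distinguish, for example, carbonyl ("O2") from
hydroxyl ("O1") oxygen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

from . import chemdata
from .chemdata import (
    CLASH_DISTANCE,
    COVALENT_RADIUS,
    COVALENT_TOLERANCE,
    DISULFIDE_CUTOFF,
    ION_RESIDUES,
    RESIDUE_BOND_TEMPLATES,
    SIDECHAIN_FORMAL_CHARGE,
    STANDARD_AMINO_ACIDS,
    WATER_NAMES,
    element_from_atom_name,
)

SUPPORTED_ELEMENTS = frozenset(COVALENT_RADIUS)


class StructureError(ValueError):
    """Raised for malformed or physically impossible structures."""


class MissingHydrogensError(StructureError):
    """Raised when a protein structure lacks hydrogens required for charge work."""


@dataclass(frozen=True)
class Atom:
    """One atom of a molecule.

    Coordinates are in angstroms; ``formal_charge`` is the integer formal
    charge in e (usually 0 except for ions).
    """

    index: int
    element: str
    name: str
    coords: tuple[float, float, float]
    residue_number: int = 1
    insertion_code: str = ""
    residue_name: str = "UNK"
    chain_id: str = "A"
    formal_charge: int = 0

    def __post_init__(self) -> None:
        if self.element not in SUPPORTED_ELEMENTS:
            raise StructureError(f"unsupported element {self.element!r} (atom {self.name!r})")
        if not all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates on atom {self.name!r}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass(frozen=True)
class Bond:
    """Covalent bond between atoms ``i`` and ``j`` with integer order 1-3."""

    i: int
    j: int
    order: int = 1

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise StructureError("bond endpoints must differ")
        if self.order not in (1, 2, 3):
            raise StructureError(f"bond order must be 1, 2 or 3, got {self.order}")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass
class Molecule:
    """An ordered collection of atoms, bonds and a total charge Q (e)."""

    id: str
    atoms: list[Atom]
    bonds: list[Bond] = field(default_factory=list)
    total_charge: float | None = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise StructureError(f"bond ({b.i},{b.j}) references a missing atom")
            if b.pair in seen:
                raise StructureError(f"duplicate bond {b.pair}")
            seen.add(b.pair)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def distance_matrix(self) -> np.ndarray:
        xyz = self.coords
        diff = xyz[:, None, :] - xyz[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def residues(self) -> dict[tuple[str, int, str], list[int]]:
        """Atom indices grouped by (chain, residue number, insertion code), in order."""
        out: dict[tuple[str, int, str], list[int]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a.index)
        return out

    def with_coords(self, xyz: np.ndarray, new_id: str | None = None) -> "Molecule":
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=tuple(xyz[k])) for k, a in enumerate(self.atoms)]
        return Molecule(new_id or self.id, atoms, list(self.bonds), self.total_charge)


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _is_amino(resname: str) -> bool:
    return resname in STANDARD_AMINO_ACIDS


def read_pdb(path, model_index: int = 0, mol_id: str | None = None) -> Molecule:
    """Read one model of a PDB file into a :class:`Molecule`.

    ``model_index`` selects among MODEL blocks (0-based; default first model,
    the convention for NMR ensembles).  Alternate locations are collapsed to
    the highest-occupancy conformer (tie: first encountered).  Water and ions
    are retained.  Element symbols come from PDB columns 77-78 when present;
    for ATOM records of standard amino acids the element is resolved from the
    atom name (so an alpha carbon named " CA " is carbon, not calcium).
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError, ValueError) as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    if not (0 <= model_index < len(st)):
        raise StructureError(f"model index {model_index} out of range (file has {len(st)} models)")
    model = st[model_index]

    atoms: list[Atom] = []
    idx = 0
    for chain in model:
        for res in chain:
            amino = _is_amino(res.name)
            # collapse altlocs: keep highest occupancy per atom name, tie -> first
            chosen: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = chosen.get(at.name)
                if prev is None or at.occ > prev.occ:
                    chosen[at.name] = at
            for at in res:  # preserve file order of the survivors
                if chosen.get(at.name) is not at:
                    continue
                if amino:
                    elem = element_from_atom_name(at.name)
                else:
                    elem = at.element.name
                    if elem in ("X", ""):
                        raise StructureError(
                            f"cannot resolve element for atom {at.name!r} in residue {res.name!r}"
                        )
                    elem = elem.capitalize() if len(elem) > 1 else elem
                atoms.append(
                    Atom(
                        index=idx,
                        element=elem,
                        name=at.name,
                        coords=(at.pos.x, at.pos.y, at.pos.z),
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        residue_name=res.name.strip(),
                        chain_id=chain.name,
                        formal_charge=int(at.charge),
                    )
                )
                idx += 1
    if not atoms:
        raise StructureError(f"no atoms in model {model_index} of {path}")
    return Molecule(mol_id or st.name or str(path), atoms)


def write_pdb(mol: Molecule, path) -> None:
    """Write a molecule as a single-model PDB file (standard residues as ATOM,
    everything else as HETATM; element columns always filled)."""
    st = gemmi.Structure()
    st.name = mol.id
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple[str, int, str], gemmi.Residue] = {}
    for a in mol.atoms:
        ch = chain_map.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chain_map[a.chain_id] = ch
            model.add_chain(ch)
            ch = model[len(model) - 1]
            chain_map[a.chain_id] = ch
        key = a.residue_key
        res = res_map.get(key)
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            res.het_flag = "A" if _is_amino(a.residue_name) else "H"
            ch.add_residue(res)
            res = ch[len(ch) - 1]
            res_map[key] = res
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.coords)
        at.occ = 1.0
        at.charge = a.formal_charge
        res.add_atom(at)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Bond perception
# ---------------------------------------------------------------------------

def _covalent_cutoff(e1: str, e2: str) -> float:
    return COVALENT_RADIUS[e1] + COVALENT_RADIUS[e2] + COVALENT_TOLERANCE


def perceive_bonds(mol: Molecule) -> list[Bond]:
    """Assign covalent bonds with orders.

    Heavy-atom bonds inside standard amino acids come from residue templates
    (carbonyl C=O gets order 2, aromatic rings Kekule orders).  Hydrogens bond
    to their nearest heavy atom.  Inter-residue peptide bonds (backbone N to
    preceding C) and disulfides are found by distance.  Monoatomic ions get no
    bonds.  Residues with no template fall back to distance-based single bonds
    with a warning.  Any interatomic distance below 0.5 angstrom is an error.
    """
    n = mol.n_atoms
    D = mol.distance_matrix()
    off = D + np.eye(n) * 10.0
    if off.min() < CLASH_DISTANCE:
        i, j = divmod(int(off.argmin()), n)
        raise StructureError(
            f"atomic clash: atoms {mol.atoms[i].name}/{mol.atoms[j].name} at {off.min():.3f} A"
        )

    bonds: dict[tuple[int, int], int] = {}

    def add(i: int, j: int, order: int) -> None:
        key = (i, j) if i < j else (j, i)
        if key not in bonds or bonds[key] < order:
            bonds[key] = order

    residues = mol.residues()
    heavy = [k for k in range(n) if mol.atoms[k].element != "H"]

    for key, members in residues.items():
        resname = mol.atoms[members[0]].residue_name
        if resname in ION_RESIDUES and len(members) == 1:
            continue  # monoatomic ion: no bonds
        template = RESIDUE_BOND_TEMPLATES.get(resname)
        name_to_idx = {mol.atoms[k].name.strip(): k for k in members}
        if template is not None:
            for n1, n2, order in template:
                i, j = name_to_idx.get(n1), name_to_idx.get(n2)
                if i is not None and j is not None:
                    add(i, j, order)
        elif resname in WATER_NAMES:
            pass  # O-H handled by hydrogen attachment below
        else:
            warnings.warn(
                f"no bond template for residue {resname!r}; using distance-based single bonds",
                stacklevel=2,
            )
            hm = [k for k in members if mol.atoms[k].element != "H"]
            for a_pos, i in enumerate(hm):
                for j in hm[a_pos + 1:]:
                    if D[i, j] <= _covalent_cutoff(mol.atoms[i].element, mol.atoms[j].element):
                        add(i, j, 1)

    # hydrogens: attach each to the nearest heavy atom within covalent reach
    for k in range(n):
        if mol.atoms[k].element != "H" or not heavy:
            continue
        dists = [(D[k, h], h) for h in heavy]
        d, h = min(dists)
        if d <= _covalent_cutoff("H", mol.atoms[h].element):
            add(k, h, 1)
        else:
            warnings.warn(f"hydrogen {mol.atoms[k].name!r} (atom {k}) has no heavy atom nearby")

    # inter-residue peptide bonds: backbone N to backbone C of another residue
    ns = [k for k in heavy if mol.atoms[k].name.strip() == "N" and _is_amino(mol.atoms[k].residue_name)]
    cs = [k for k in heavy if mol.atoms[k].name.strip() == "C" and _is_amino(mol.atoms[k].residue_name)]
    for i in ns:
        for j in cs:
            if mol.atoms[i].residue_key != mol.atoms[j].residue_key and D[i, j] <= _covalent_cutoff("N", "C"):
                add(i, j, 1)

    # disulfides
    sgs = [k for k in heavy if mol.atoms[k].element == "S" and mol.atoms[k].residue_name == "CYS"]
    for a_pos, i in enumerate(sgs):
        for j in sgs[a_pos + 1:]:
            if D[i, j] <= DISULFIDE_CUTOFF:
                add(i, j, 1)

    return [Bond(i, j, order) for (i, j), order in sorted(bonds.items())]


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------

def assign_atom_types(mol: Molecule, scheme: str) -> list[str]:
    """Per-atom type keys under scheme 'E' (element) or 'EX' (element + max
    incident bond order, e.g. "O1" vs "O2"; unbonded species keep the bare
    element symbol)."""
    if scheme == "E":
        return [a.element for a in mol.atoms]
    if scheme != "EX":
        raise ValueError(f"unknown atom-typing scheme {scheme!r}")
    max_order = [0] * mol.n_atoms
    for b in mol.bonds:
        max_order[b.i] = max(max_order[b.i], b.order)
        max_order[b.j] = max(max_order[b.j], b.order)
    return [
        a.element + (str(max_order[k]) if max_order[k] > 0 else "")
        for k, a in enumerate(mol.atoms)
    ]


def ex_to_e_key(key: str) -> str:
    """Strip the bond-order suffix from an 'EX' type key ("O2" -> "O")."""
    return key.rstrip("0123456789")


# ---------------------------------------------------------------------------
# Formal total charge
# ---------------------------------------------------------------------------

def formal_total_charge(mol: Molecule, ph_model: str = "standard") -> int:
    """Conventional total formal charge at neutral pH.

    Asp/Glu -1, Lys/Arg +1, His 0, free N-terminus +1, free C-terminus -1,
    monoatomic ions their nominal charge (Ca2+ -> +2), waters 0.  This is a
    bookkeeping default that callers may override.
    """
    if ph_model != "standard":
        raise ValueError(f"unknown pH model {ph_model!r}")
    total = 0
    chains: dict[str, list[tuple[tuple[str, int, str], str]]] = {}
    for key, members in mol.residues().items():
        resname = mol.atoms[members[0]].residue_name
        if resname in ION_RESIDUES and len(members) == 1:
            total += ION_RESIDUES[resname][1]
            continue
        if resname in WATER_NAMES:
            continue
        if _is_amino(resname):
            total += SIDECHAIN_FORMAL_CHARGE.get(resname, 0)
            chains.setdefault(key[0], []).append((key, resname))
    for _chain_id, res_list in chains.items():
        total += 1   # free N-terminus
        total -= 1   # free C-terminus
    return total


def require_hydrogens(mol: Molecule) -> None:
    """Hard error when a protein structure has no hydrogens: reference charge
    sets include hydrogens, so charges computed without them are meaningless.
    No hydrogen placement is attempted."""
    has_amino = any(_is_amino(a.residue_name) for a in mol.atoms)
    has_h = any(a.element == "H" for a in mol.atoms)
    if has_amino and not has_h:
        raise MissingHydrogensError(
            f"structure {mol.id!r} contains amino-acid residues but no hydrogens; "
            "add hydrogens with an external tool (e.g. reduce, openbabel) before "
            "computing charges"
        )


# ---------------------------------------------------------------------------
# Charge table I/O
# ---------------------------------------------------------------------------

@dataclass
class ChargeTable:
    """Per-atom charges for one molecule (carrier for reference or computed
    charges; entries are (atom_index, atom_name, charge in e))."""

    molecule_id: str
    entries: list[tuple[int, str, float]]

    def __post_init__(self) -> None:
        idx = [e[0] for e in self.entries]
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate atom_index in charge table for {self.molecule_id!r}")

    @property
    def charges(self) -> np.ndarray:
        ordered = sorted(self.entries, key=lambda e: e[0])
        return np.array([e[2] for e in ordered], dtype=float)

    def check_against(self, mol: Molecule) -> None:
        if len(self.entries) != mol.n_atoms:
            raise ValueError(
                f"charge table for {self.molecule_id!r} has {len(self.entries)} entries "
                f"but molecule has {mol.n_atoms} atoms"
            )


CHARGE_TABLE_COLUMNS = ["mol_id", "atom_index", "atom_name", "charge"]


def write_charge_table(table: ChargeTable, path) -> None:
    df = pd.DataFrame(
        [(table.molecule_id, i, name, q) for i, name, q in table.entries],
        columns=CHARGE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_charge_table(path) -> ChargeTable:
    df = pd.read_csv(path, sep="\t", dtype={"atom_name": str})
    missing = [c for c in CHARGE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"charge table {path} lacks columns {missing}")
    ids = df["mol_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"charge table {path} must describe exactly one molecule, found {list(ids)}")
    entries = [
        (int(r.atom_index), str(r.atom_name), float(r.charge)) for r in df.itertuples()
    ]
    return ChargeTable(str(ids[0]), entries)
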