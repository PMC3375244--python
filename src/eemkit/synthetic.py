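"""Synthetic molecules and reference charge sets with known ground truth.

Real calibrations use quantum-chemical population charges for protein
fragments; those inputs are large and expensive.  For testing and
demonstration this module forward-generates reference sets from the
equalization model itself with known per-type parameters, so that the
calibration machinery can be checked for exact parameter recovery, and pairs
of conformers with a localized geometric perturbation, so that the
charge-transfer profiler can be checked against constructed ground truth.

The default composition emulates the element make-up of protein-fragment
reference sets (mostly H and C, some N and O, traces of S and Ca).  Molecules
are random atom clouds with chain bonds, not realistic protein geometry.

The generator pins each molecule's electronegativity to the harmonic mean of
its atoms' Pauling electronegativities and solves the per-atom equalization
equations; the total charge is then implied by the solution.  This makes
noiseless records exactly model-consistent: the rearranged calibration
equations lie exactly on y = A + B x for every atom type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import MANIFEST_NAME, ReferenceRecord
from .core import (
    EemParameters,
    SolverError,
    harmonic_electronegativity,
    solve_charges,
    solve_charges_fixed_chi,
)
from .structures import (
    Atom,
    Bond,
    ChargeTable,
    Molecule,
    perceive_bonds,
    write_charge_table,
    write_pdb,
)

#: element weights emulating the composition of protein-fragment reference
#: sets: dominated by H and C, traces of S and Ca
DEFAULT_ELEMENT_WEIGHTS: dict[str, float] = {
    "H": 10434.0,
    "C": 6649.0,
    "N": 2730.0,
    "O": 3332.0,
    "S": 30.0,
    "Ca": 84.0,
}

#: fixed ground-truth parameter set used across the test suite: an 'E'-scheme
#: table over the six supported elements with k* = 0.4
DEFAULT_TRUE_PARAMS = EemParameters(
    scheme="E",
    k=0.4,
    table={
        "H": (2.20, 8.0),
        "C": (2.55, 6.0),
        "N": (3.04, 7.0),
        "O": (3.44, 9.0),
        "S": (2.58, 5.0),
        "Ca": (2.00, 4.5),
    },
)

_MIN_DISTANCE = 1.0
_ATOMS_PER_RESIDUE = 5
#: minimum observations per modelled atom type; a two-parameter per-type
#: regression on noisy charges needs roughly ten points for the regressor's
#: sample spread to concentrate near its population value
_MIN_TYPE_OBSERVATIONS = 10


class FixtureError(RuntimeError):
    pass


@dataclass
class FixtureSpec:
    """Recipe for a synthetic reference set."""

    n_molecules: int = 20
    atoms_per_molecule: tuple[int, int] = (25, 35)
    element_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_WEIGHTS)
    )
    true_params: EemParameters = field(default_factory=lambda: DEFAULT_TRUE_PARAMS)
    noise_sigma: float = 0.0
    seed: int = 0
    box_size: float = 12.0

    def __post_init__(self) -> None:
        lo, hi = self.atoms_per_molecule
        if lo < 1 or hi < lo:
            raise FixtureError("atoms_per_molecule must be a (lo, hi) range with lo >= 1")
        if self.noise_sigma < 0:
            raise FixtureError("noise_sigma must be non-negative")
        total = sum(self.element_frequencies.values())
        if not total > 0:
            raise FixtureError("element frequencies must sum to a positive value")

    @classmethod
    def from_yaml(cls, path) -> "FixtureSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "true_params" in raw:
            tp = raw["true_params"]
            raw["true_params"] = EemParameters(
                tp["scheme"], float(tp["k"]),
                {k: (float(a), float(b)) for k, (a, b) in tp["table"].items()},
            )
        if "atoms_per_molecule" in raw:
            raw["atoms_per_molecule"] = tuple(raw["atoms_per_molecule"])
        return cls(**raw)


_STEP_LENGTH = 1.5  # chain step, emulating covalent neighbor spacing


def _place_coords(rng: np.random.Generator, n: int, box: float) -> np.ndarray:
    """Uniform coordinates in a cube with pairwise distances >= 1 angstrom."""
    coords = np.empty((n, 3))
    placed = 0
    for _attempt in range(20000 * n):
        cand = rng.uniform(0.0, box, size=3)
        if placed == 0 or np.min(np.linalg.norm(coords[:placed] - cand, axis=1)) >= _MIN_DISTANCE:
            coords[placed] = cand
            placed += 1
            if placed == n:
                return coords
    raise FixtureError(
        f"could not place {n} atoms with min distance {_MIN_DISTANCE} A in a "
        f"{box} A box; increase box_size"
    )


def _chain_walk(rng: np.random.Generator, n: int, box: float) -> np.ndarray:
    """Self-avoiding random-walk coordinates: consecutive atoms one chain step
    apart, so consecutive residues are spatially contiguous segments and a
    localized geometric perturbation stays localized."""
    coords = np.empty((n, 3))
    coords[0] = rng.uniform(0.0, box, size=3)
    placed = 1
    for _attempt in range(20000 * n):
        if placed == n:
            break
        step = rng.normal(size=3)
        cand = coords[placed - 1] + _STEP_LENGTH * step / np.linalg.norm(step)
        if np.all((cand >= -box) & (cand <= 2 * box)) and np.min(
            np.linalg.norm(coords[:placed] - cand, axis=1)
        ) >= _MIN_DISTANCE:
            coords[placed] = cand
            placed += 1
    if placed < n:
        raise FixtureError(
            f"could not grow a {n}-atom chain with min distance {_MIN_DISTANCE} A; "
            "increase box_size"
        )
    return coords


def make_molecules(spec: FixtureSpec) -> list[Molecule]:
    """Generate the reference molecules of a fixture spec (deterministic in
    the seed).  Atoms are grouped into 5-atom pseudo-residues; consecutive
    atoms are chain-bonded with random orders so that the 'EX' typing scheme
    has material to distinguish.  Every element of the ground-truth table is
    guaranteed to appear in at least two molecules and with at least ten
    atoms overall, so per-type parameters stay identifiable under noise."""
    rng = np.random.default_rng(spec.seed)
    elements = sorted(spec.element_frequencies)
    weights = np.array([spec.element_frequencies[e] for e in elements], dtype=float)
    weights /= weights.sum()
    lo, hi = spec.atoms_per_molecule

    per_mol_elements: list[list[str]] = []
    for _m in range(spec.n_molecules):
        n = int(rng.integers(lo, hi + 1))
        per_mol_elements.append([str(e) for e in rng.choice(elements, size=n, p=weights)])

    # Identifiability guarantee: every modelled element appears in >= 2
    # molecules and with >= _MIN_TYPE_OBSERVATIONS atoms overall.  Trace
    # elements drawn at their natural frequency would otherwise yield 2-3
    # observations, too few to identify a two-parameter per-type regression
    # once reference charges carry noise (the sample spread of the regressor
    # can be arbitrarily small, making the slope estimate unbounded).  Real
    # protein reference sets are large enough that even trace elements
    # contribute dozens of observations; a small emulated set must preserve
    # that property explicitly.
    needed = sorted({k.rstrip("0123456789") for k in spec.true_params.table})
    counts = {e: sum(elems.count(e) for elems in per_mol_elements) for e in needed}
    total_atoms = sum(len(elems) for elems in per_mol_elements)
    # small demonstration specs cannot host the full floor; scale it down
    floor = min(_MIN_TYPE_OBSERVATIONS, total_atoms // max(len(needed), 1))

    min_presence = min(2, spec.n_molecules)

    def presence(e: str) -> int:
        return sum(e in elems for elems in per_mol_elements)

    def replaceable(e: str, m: int) -> bool:
        # donors must stay at/above their own floor and molecule presence
        if e not in needed:
            return True
        if counts[e] <= floor:
            return False
        return per_mol_elements[m].count(e) > 1 or presence(e) > min_presence

    # rarest elements first, so they draw from the largest donor pool
    for elem in sorted(needed, key=lambda e: counts[e]):
        have = {m for m, elems in enumerate(per_mol_elements) if elem in elems}
        deficit = max(floor - counts[elem], min_presence - len(have), 0)
        order = [int(m) for m in rng.permutation(spec.n_molecules)]
        order.sort(key=lambda m: m in have)  # fill absent molecules first
        j = 0
        while deficit > 0 and j < 10 * spec.n_molecules:
            m = order[j % spec.n_molecules]
            j += 1
            slots = [i for i, e in enumerate(per_mol_elements[m])
                     if e != elem and replaceable(e, m)]
            if not slots:
                continue
            # consume the most abundant donor element in this molecule
            donor = max((per_mol_elements[m][i] for i in slots),
                        key=lambda e: counts.get(e, total_atoms))
            slots = [i for i in slots if per_mol_elements[m][i] == donor]
            slot = slots[int(rng.integers(len(slots)))]
            old = per_mol_elements[m][slot]
            if old in counts:
                counts[old] -= 1
            per_mol_elements[m][slot] = elem
            counts[elem] += 1
            deficit -= 1
        if deficit > 0:
            raise FixtureError(
                f"cannot reach {floor} observations of {elem!r}; "
                "increase molecule count or size"
            )

    mols: list[Molecule] = []
    for m, elems in enumerate(per_mol_elements):
        n = len(elems)
        coords = _place_coords(rng, n, spec.box_size)
        atoms = [
            Atom(
                index=i,
                element=e,
                name=f"{e.upper()}{i % _ATOMS_PER_RESIDUE + 1}",
                coords=tuple(coords[i]),
                residue_number=i // _ATOMS_PER_RESIDUE + 1,
                residue_name="SYN",
                chain_id="A",
            )
            for i, e in enumerate(elems)
        ]
        bonds = [
            Bond(i, i + 1, int(rng.integers(1, 4))) for i in range(n - 1)
        ]
        mols.append(Molecule(f"syn{m:03d}", atoms, bonds))
    return mols


def forward_reference(
    mols: list[Molecule],
    true_params: EemParameters = DEFAULT_TRUE_PARAMS,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[ReferenceRecord]:
    """Forward-generate reference records from the equalization model.

    Per molecule the molecular electronegativity is pinned to its
    harmonic-mean value and the per-atom equations solved; i.i.d. Gaussian
    noise of standard deviation ``noise_sigma`` (e) emulates the discrepancy
    between reference quantum charges and the model.  With zero noise the
    records are exactly model-consistent.
    """
    rng = np.random.default_rng(seed)
    records: list[ReferenceRecord] = []
    for mol in mols:
        chi = harmonic_electronegativity(mol)
        q = None
        for attempt in range(5):
            try:
                q = solve_charges_fixed_chi(mol, true_params, chi).charges
                break
            except SolverError:
                warnings.warn(
                    f"solver failed on generated molecule {mol.id!r} "
                    f"(attempt {attempt + 1}); jittering coordinates",
                    stacklevel=2,
                )
                mol = mol.with_coords(
                    mol.coords + rng.normal(0.0, 1e-3, size=(mol.n_atoms, 3))
                )
        if q is None:
            raise FixtureError(f"could not solve generated molecule {mol.id!r}")
        ref = q + (rng.normal(0.0, noise_sigma, size=len(q)) if noise_sigma > 0 else 0.0)
        mol.total_charge = float(np.sum(ref))
        records.append(ReferenceRecord(mol, ref, chi))
    return records


def make_reference_set(spec: FixtureSpec) -> list[ReferenceRecord]:
    """Convenience: molecules plus forward-generated reference charges."""
    mols = make_molecules(spec)
    return forward_reference(mols, spec.true_params, spec.noise_sigma, seed=spec.seed + 1)


def _ring_coords(rng: np.random.Generator, n: int, spacing: float = _STEP_LENGTH,
                 jitter: float = 0.15) -> np.ndarray:
    """Coordinates on a jittered planar ring with the given neighbor spacing.

    On a ring, moving any contiguous segment radially outward strictly
    increases its distance to every other atom, so a rigid outward
    displacement weakens all of the segment's pair couplings coherently."""
    radius = spacing / (2.0 * np.sin(np.pi / n))
    ang = 2.0 * np.pi * np.arange(n) / n
    xyz = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)])
    return xyz + rng.normal(0.0, jitter, size=(n, 3))


def make_chain_molecule(
    residue_elements: list[list[str]],
    seed: int = 0,
    box_size: float = 15.0,
    mol_id: str = "chain",
    coords: np.ndarray | None = None,
) -> Molecule:
    """A chain molecule with explicit per-residue element composition.

    ``residue_elements`` lists, per residue, the elements of its atoms; atoms
    are laid out as a self-avoiding walk (or at the given ``coords``) so each
    residue is a spatially contiguous segment, and consecutive atoms are
    chain-bonded (order 1).
    """
    rng = np.random.default_rng(seed)
    elems = [e for res in residue_elements for e in res]
    if coords is None:
        coords = _chain_walk(rng, len(elems), box_size)
    elif len(coords) != len(elems):
        raise FixtureError("coords length must match the total atom count")
    res_of = [r + 1 for r, res in enumerate(residue_elements) for _ in res]
    counters: dict[tuple[int, str], int] = {}
    atoms = []
    for i, (e, r) in enumerate(zip(elems, res_of)):
        counters[(r, e)] = counters.get((r, e), 0) + 1
        atoms.append(
            Atom(index=i, element=e, name=f"{e.upper()}{counters[(r, e)]}",
                 coords=tuple(coords[i]), residue_number=r,
                 residue_name="SYN", chain_id="A")
        )
    bonds = [Bond(i, i + 1, 1) for i in range(len(atoms) - 1)]
    return Molecule(mol_id, atoms, bonds)


def make_profile_fixture(
    seed: int = 0,
    n_residues: int = 10,
    atoms_per_residue: int = 5,
    perturbed_residue: int = 3,
    displacement: float = 1.5,
    total_charge: float = 2.0,
    true_params: EemParameters = DEFAULT_TRUE_PARAMS,
) -> tuple[Molecule, Molecule, float]:
    """A conformer pair with constructed charge-transfer ground truth.

    The base is a compositionally uniform carbon ring carrying a nonzero
    total charge, so every atom holds roughly the same charge.  Displacing
    one residue radially outward increases its distance to every other atom,
    so each of its atoms loses coupling to all the remaining atoms at once
    — a large coherent perturbation — while any single bystander atom only
    loses coupling to the few displaced atoms.  The net charge flow therefore
    concentrates on the displaced residue, which ends up with the maximal
    per-residue net charge difference.

    The segment must not instead be given a distinctive composition: the
    electrostatic force a displacement exerts on an atom scales with the
    *other* side's charge, so a strongly charged (e.g. oxygen-rich) segment
    chiefly perturbs its neighbors, and a rigid displacement inside a folded
    geometry mostly produces intra-residue redistribution with a cancelling
    net term.  Returns (inactive-like conformer, active-like conformer,
    total charge).
    """
    rng = np.random.default_rng(seed)
    residues = [["C"] * atoms_per_residue for _ in range(n_residues)]
    coords = _ring_coords(rng, n_residues * atoms_per_residue)
    base = make_chain_molecule(residues, mol_id=f"pf{seed}", coords=coords)
    base.total_charge = float(total_charge)
    a, b = make_conformer_pair(
        base, [perturbed_residue], displacement, true_params,
        seed=seed + 1, tilt=0.0,
    )
    return a, b, float(total_charge)


def make_conformer_pair(
    base: Molecule,
    perturbed_residues: list[int] | list[tuple[str, int, str]],
    displacement: float,
    true_params: EemParameters | None = None,
    seed: int = 0,
    tilt: float = 0.25,
) -> tuple[Molecule, Molecule]:
    """Base conformer plus a copy with the listed residues rigidly displaced.

    ``perturbed_residues`` entries are residue numbers (any chain) or full
    (chain, number, icode) keys.  Each listed residue's atoms move together by
    ``displacement`` angstroms, outward from the centroid of the remaining
    atoms with a seeded random tilt of relative magnitude ``tilt`` — emulating
    a segment becoming exposed, so the charge perturbation concentrates on the
    moved residue (``tilt=0`` gives a purely outward move).  A displacement
    causing a clash (< 0.5 A) is resampled.  When ``true_params`` is given the
    perturbed conformer is additionally checked to be solvable.  Atom sets and
    ordering are identical between the two conformers.
    """
    rng = np.random.default_rng(seed)
    residues = base.residues()
    targets: list[list[int]] = []
    for spec_key in perturbed_residues:
        if isinstance(spec_key, tuple):
            members = residues.get(spec_key)
            if members is None:
                raise FixtureError(f"residue {spec_key} not found in {base.id!r}")
            targets.append(members)
        else:
            members = [
                idx for key, mem in residues.items() if key[1] == int(spec_key) for idx in mem
            ]
            if not members:
                raise FixtureError(f"residue number {spec_key} not found in {base.id!r}")
            targets.append(members)

    for _attempt in range(50):
        xyz = base.coords.copy()
        for members in targets:
            rest = [i for i in range(base.n_atoms) if i not in set(members)]
            if rest:
                outward = xyz[members].mean(axis=0) - xyz[rest].mean(axis=0)
            else:
                outward = rng.normal(size=3)
            direction = outward / np.linalg.norm(outward) + tilt * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            xyz[members] += displacement * direction
        moved = base.with_coords(xyz, new_id=base.id + "_b")
        D = moved.distance_matrix() + np.eye(moved.n_atoms) * 10.0
        if moved.n_atoms > 1 and D.min() < 0.5:
            continue
        if true_params is not None and displacement > 0:
            try:
                solve_charges(moved, true_params, Q=base.total_charge or 0.0)
            except SolverError:
                continue
        return base, moved
    raise FixtureError("could not find a clash-free displacement; reduce the magnitude")


def write_refset(records: list[ReferenceRecord], outdir) -> None:
    """Write a reference set in the on-disk layout the calibration loader
    reads: manifest.tsv + per-molecule PDB and charge TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        mid = rec.molecule.id
        write_pdb(rec.molecule, outdir / f"{mid}.pdb")
        table = ChargeTable(
            mid,
            [
                (a.index, a.name, float(q))
                for a, q in zip(rec.molecule.atoms, rec.ref_charges)
            ],
        )
        write_charge_table(table, outdir / f"{mid}.charges.tsv")
        rows.append((mid, rec.molecule.total_charge))
    pd.DataFrame(rows, columns=["mol_id", "total_charge"]).to_csv(
        outdir / MANIFEST_NAME, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Small hand-built peptide fixtures (real residue names, template bonds)
# ---------------------------------------------------------------------------

def _peptide(mol_id: str, spec: list[tuple[str, str, int, str, tuple[float, float, float]]],
             total_charge: float | None = None, bonds: bool = True) -> Molecule:
    atoms = [
        Atom(index=i, element=elem, name=name, coords=xyz,
             residue_number=resnum, residue_name=resname, chain_id="A")
        for i, (elem, name, resnum, resname, xyz) in enumerate(spec)
    ]
    mol = Molecule(mol_id, atoms, total_charge=total_charge)
    if bonds:
        mol.bonds = perceive_bonds(mol)
    return mol


def gly_gly(bonds: bool = True) -> Molecule:
    """A glycyl-glycine dipeptide with hydrogens (zwitterion-free bookkeeping:
    formal total charge 0 at neutral pH)."""
    g1 = [
        ("N", "N", 1, "GLY", (0.0, 0.0, 0.0)),
        ("H", "H1", 1, "GLY", (-0.5, -0.8, 0.0)),
        ("H", "H2", 1, "GLY", (-0.5, 0.8, 0.0)),
        ("H", "H3", 1, "GLY", (-0.3, 0.0, 0.9)),
        ("C", "CA", 1, "GLY", (1.46, 0.0, 0.0)),
        ("H", "HA2", 1, "GLY", (1.8, -0.5, 0.8)),
        ("H", "HA3", 1, "GLY", (1.8, -0.5, -0.8)),
        ("C", "C", 1, "GLY", (2.0, 1.4, 0.0)),
        ("O", "O", 1, "GLY", (1.3, 2.4, 0.0)),
    ]
    g2 = [
        ("N", "N", 2, "GLY", (3.33, 1.5, 0.0)),
        ("H", "H", 2, "GLY", (3.0, 2.4, 0.0)),
        ("C", "CA", 2, "GLY", (4.25, 2.6, 0.0)),
        ("H", "HA2", 2, "GLY", (4.0, 3.1, 0.8)),
        ("H", "HA3", 2, "GLY", (4.0, 3.1, -0.8)),
        ("C", "C", 2, "GLY", (5.7, 2.3, 0.0)),
        ("O", "O", 2, "GLY", (6.2, 1.2, 0.0)),
        ("O", "OXT", 2, "GLY", (6.5, 3.3, 0.0)),
    ]
    return _peptide("gly_gly", g1 + g2, total_charge=0.0, bonds=bonds)


def ser_gly(with_calcium: bool = False, bonds: bool = True) -> Molecule:
    """A seryl-glycine dipeptide with hydrogens; the serine hydroxyl oxygen is
    singly bonded ("O1" under 'EX') while the carbonyl oxygens are doubly
    bonded ("O2").  Optionally adds an isolated calcium ion on chain B."""
    s1 = [
        ("N", "N", 1, "SER", (0.0, 0.0, 0.0)),
        ("H", "H1", 1, "SER", (-0.5, -0.8, 0.0)),
        ("H", "H2", 1, "SER", (-0.5, 0.8, 0.0)),
        ("H", "H3", 1, "SER", (-0.3, 0.0, 0.9)),
        ("C", "CA", 1, "SER", (1.46, 0.0, 0.0)),
        ("H", "HA", 1, "SER", (1.8, -0.55, -0.85)),
        ("C", "CB", 1, "SER", (1.9, -0.77, 1.2)),
        ("H", "HB2", 1, "SER", (1.3, -1.37, 1.7)),
        ("H", "HB3", 1, "SER", (2.85, -0.62, 1.55)),
        ("O", "OG", 1, "SER", (2.5, -1.97, 1.6)),
        ("H", "HG", 1, "SER", (3.05, -2.52, 2.05)),
        ("C", "C", 1, "SER", (2.0, 1.4, 0.0)),
        ("O", "O", 1, "SER", (1.3, 2.4, 0.0)),
    ]
    g2 = [
        ("N", "N", 2, "GLY", (3.33, 1.5, 0.0)),
        ("H", "H", 2, "GLY", (3.0, 2.4, 0.0)),
        ("C", "CA", 2, "GLY", (4.25, 2.6, 0.0)),
        ("H", "HA2", 2, "GLY", (4.0, 3.1, 0.8)),
        ("H", "HA3", 2, "GLY", (4.0, 3.1, -0.8)),
        ("C", "C", 2, "GLY", (5.7, 2.3, 0.0)),
        ("O", "O", 2, "GLY", (6.2, 1.2, 0.0)),
        ("O", "OXT", 2, "GLY", (6.5, 3.3, 0.0)),
    ]
    spec = s1 + g2
    if with_calcium:
        spec = spec + [("Ca", "CA", 3, "CA", (9.0, -3.0, 3.0))]
    atoms = [
        Atom(index=i, element=elem, name=name, coords=xyz,
             residue_number=resnum, residue_name=resname,
             chain_id="B" if resname == "CA" else "A",
             formal_charge=2 if resname == "CA" else 0)
        for i, (elem, name, resnum, resname, xyz) in enumerate(spec)
    ]
    mol = Molecule("ser_gly" + ("_ca" if with_calcium else ""), atoms,
                   total_charge=2.0 if with_calcium else 0.0)
    if bonds:
        mol.bonds = perceive_bonds(mol)
    return mol
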