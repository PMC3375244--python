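"""Electronegativity-equalization charge solver.

The model: the electronegativity of atom i in a molecule is

    chi_i = A_i + B_i * q_i + k * sum_{j != i} q_j / R_ij

where A_i is the effective electronegativity of the neutral atom corrected for
its molecular environment, B_i is twice the effective hardness, q_i the partial
charge (e), R_ij interatomic distances (angstrom), and k a dimensionless
scaling of the interatomic electrostatic term (the Yang-Wang modification).
Equalization (chi_i = chi_bar for all i) together with total-charge
conservation (sum q_i = Q) gives an (n+1) x (n+1) linear system in
(q_1..q_n, chi_bar), solved here by a dense direct method with partial
pivoting.  The contract is the residual bound, not the algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.linalg import lapack

from .chemdata import PAULING_ELECTRONEGATIVITY
from .structures import CLASH_DISTANCE, Molecule, assign_atom_types

#: condition-number reciprocal below which a warning is emitted (cond > 1e10)
_RCOND_WARN = 1e-10


class EemError(ValueError):
    pass


class MissingParameterError(EemError):
    """An atom type present in the molecule has no (A, B) entry."""


class SolverError(EemError):
    pass


@dataclass
class EemParameters:
    """A calibrated charge model: typing scheme, k factor and per-type (A, B).

    A and B share the (arbitrary) electronegativity scale of the calibration
    targets; B must be positive (effective hardness is positive).
    """

    scheme: str
    k: float
    table: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.scheme not in ("E", "EX"):
            raise EemError(f"unknown scheme {self.scheme!r}")
        if not (np.isfinite(self.k) and self.k > 0):
            raise EemError(f"k must be positive and finite, got {self.k}")
        for key, (a, b) in self.table.items():
            if not (np.isfinite(a) and np.isfinite(b)):
                raise EemError(f"non-finite parameters for type {key!r}")
            if b <= 0:
                raise EemError(f"B must be positive for type {key!r}, got {b}")

    def ab_arrays(self, type_keys: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Vectors (A_i, B_i) for a list of per-atom type keys."""
        missing = sorted({t for t in type_keys if t not in self.table})
        if missing:
            raise MissingParameterError(
                f"no parameters for atom type(s) {', '.join(missing)} under scheme {self.scheme!r}"
            )
        a = np.array([self.table[t][0] for t in type_keys])
        b = np.array([self.table[t][1] for t in type_keys])
        return a, b


@dataclass
class ChargeSet:
    """Solved per-atom charges plus the equalized molecular electronegativity."""

    molecule_id: str
    charges: np.ndarray
    chi_bar: float
    condition_reciprocal: float | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.charges)


def _pair_terms(mol: Molecule, k: float) -> np.ndarray:
    """Off-diagonal matrix k / R_ij (zero diagonal); errors on clashes."""
    n = mol.n_atoms
    D = mol.distance_matrix()
    off = D + np.eye(n)
    if n > 1 and (D + np.eye(n) * 10.0).min() < CLASH_DISTANCE:
        raise SolverError("interatomic distance below 0.5 A; refusing to assemble")
    C = k / off
    np.fill_diagonal(C, 0.0)
    return C


def assemble_system(
    mol: Molecule, params: EemParameters, Q: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (n+1)x(n+1) matrix and right-hand side.

    Row i (i < n): B_i on the diagonal, k/R_ij off-diagonal, -1 in the last
    column, rhs -A_i.  Last row: ones over the charge unknowns, 0 in the
    chi_bar column, rhs Q.  Unknown vector is (q_1..q_n, chi_bar).
    """
    if Q is None:
        Q = mol.total_charge
    if Q is None:
        raise EemError(f"no total charge available for molecule {mol.id!r}")
    types = assign_atom_types(mol, params.scheme)
    A, B = params.ab_arrays(types)
    n = mol.n_atoms
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = _pair_terms(mol, params.k)
    M[np.arange(n), np.arange(n)] = B
    M[:n, n] = -1.0
    M[n, :n] = 1.0
    rhs = np.empty(n + 1)
    rhs[:n] = -A
    rhs[n] = float(Q)
    return M, rhs


def _solve_dense(M: np.ndarray, rhs: np.ndarray) -> tuple[np.ndarray, float]:
    """LU solve with a LAPACK 1-norm reciprocal condition estimate."""
    anorm = np.linalg.norm(M, 1)
    lu, piv, info = lapack.dgetrf(M)
    if info != 0:
        raise SolverError(f"matrix is numerically singular (LU breakdown at pivot {info})")
    rcond, info = lapack.dgecon(lu, anorm, norm="1")
    if info != 0 or not np.isfinite(rcond) or rcond == 0.0:
        raise SolverError(f"matrix is numerically singular (rcond={rcond!r})")
    if rcond < _RCOND_WARN:
        warnings.warn(
            f"ill-conditioned EEM system: estimated condition number {1.0 / rcond:.3e}",
            stacklevel=3,
        )
    x, info = lapack.dgetrs(lu, piv, rhs)
    if info != 0:
        raise SolverError("triangular solve failed")
    return x, float(rcond)


def solve_charges(
    mol: Molecule, params: EemParameters, Q: float | None = None
) -> ChargeSet:
    """Solve for the partial charges and the molecular electronegativity.

    Postconditions (verified): max residual of the assembled system below
    1e-8 * max(1, |Q|) and |sum(q) - Q| < 1e-8.
    """
    M, rhs = assemble_system(mol, params, Q)
    x, rcond = _solve_dense(M, rhs)
    n = mol.n_atoms
    q, chi_bar = x[:n], float(x[n])
    Qv = rhs[n]
    resid = float(np.abs(M @ x - rhs).max())
    tol = 1e-8 * max(1.0, abs(Qv))
    if resid > tol or abs(q.sum() - Qv) > 1e-8:
        raise SolverError(
            f"solution residual {resid:.3e} exceeds tolerance {tol:.3e} "
            f"(estimated condition number {1.0 / rcond:.3e})"
        )
    return ChargeSet(mol.id, q, chi_bar, condition_reciprocal=rcond)


def solve_charges_fixed_chi(
    mol: Molecule, params: EemParameters, chi_bar: float
) -> ChargeSet:
    """Solve the n-atom equalization equations with the molecular
    electronegativity pinned to ``chi_bar``; the total charge is implied
    (Q = sum of the solved charges).  This is the forward model used to
    generate exactly model-consistent synthetic reference charges."""
    types = assign_atom_types(mol, params.scheme)
    A, B = params.ab_arrays(types)
    n = mol.n_atoms
    M = _pair_terms(mol, params.k)
    M[np.arange(n), np.arange(n)] = B
    q, _ = _solve_dense(M, chi_bar - A)
    return ChargeSet(mol.id, q, float(chi_bar))


def effective_electronegativity(
    mol: Molecule, params: EemParameters, charges: np.ndarray
) -> np.ndarray:
    """Per-atom chi_i = A_i + B_i q_i + k sum_{j != i} q_j / R_ij.

    For charges produced by :func:`solve_charges` all entries coincide with
    chi_bar to solver tolerance — the equalization principle.
    """
    charges = np.asarray(charges, dtype=float)
    if charges.shape != (mol.n_atoms,):
        raise EemError("charge vector length does not match molecule")
    types = assign_atom_types(mol, params.scheme)
    A, B = params.ab_arrays(types)
    C = _pair_terms(mol, params.k)
    return A + B * charges + C @ charges


def harmonic_electronegativity(
    mol: Molecule, pauling_table: dict[str, float] | None = None
) -> float:
    """Harmonic mean of the atomic (Pauling-scale) electronegativities over
    all atoms, hydrogens included: n / sum_i (1 / chi_i).  Used as the
    molecular-electronegativity stand-in during calibration."""
    table = PAULING_ELECTRONEGATIVITY if pauling_table is None else pauling_table
    vals = []
    for a in mol.atoms:
        chi = table.get(a.element)
        if chi is None:
            raise EemError(f"no tabulated electronegativity for element {a.element!r}")
        if chi <= 0:
            raise EemError(f"non-positive electronegativity for element {a.element!r}")
        vals.append(chi)
    vals = np.array(vals)
    return float(len(vals) / np.sum(1.0 / vals))


# ---------------------------------------------------------------------------
# Parameter file I/O
# ---------------------------------------------------------------------------

def write_parameters(params: EemParameters, path) -> None:
    """Plain-text parameter file: `scheme:`, `k:` headers then one
    `TYPE <key> A=<float> B=<float>` line per atom type (9 decimals)."""
    lines = [f"scheme: {params.scheme}", f"k: {params.k:.9f}"]
    for key in sorted(params.table):
        a, b = params.table[key]
        lines.append(f"TYPE {key} A={a:.9f} B={b:.9f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_parameters(path) -> EemParameters:
    scheme = None
    k = None
    table: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("scheme:"):
                scheme = line.split(":", 1)[1].strip()
            elif line.startswith("k:"):
                k = float(line.split(":", 1)[1])
            elif line.startswith("TYPE "):
                parts = line.split()
                if len(parts) != 4 or not parts[2].startswith("A=") or not parts[3].startswith("B="):
                    raise EemError(f"{path}:{lineno}: malformed TYPE line {line!r}")
                key = parts[1]
                if key in table:
                    raise EemError(f"{path}:{lineno}: duplicate type {key!r}")
                table[key] = (float(parts[2][2:]), float(parts[3][2:]))
            else:
                raise EemError(f"{path}:{lineno}: unrecognized line {line!r}")
    if scheme is None or k is None or not table:
        raise EemError(f"parameter file {path} is incomplete")
    return EemParameters(scheme, k, table)
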