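"""Calibration of the charge model against reference charge sets.

Given reference per-atom charges (e.g. quantum-chemical population charges)
for a collection of molecular fragments, the equalization relation

    chi_bar = A_x + B_x * q_i + k * sum_{j != i} q_j / R_ij

is rearranged, for each atom i of type x, into a linear equation in the
unknown per-type parameters (A_x, B_x):

    y_i := chi_bar - k * sum_{j != i} q_j / R_ij  =  A_x + B_x * q_i .

chi_bar is approximated by the harmonic mean of the Pauling atomic
electronegativities of the molecule's atoms.  Rows are grouped by atom type
and (A, B) obtained by ordinary least squares; the electrostatic scaling k is
grid-searched, each candidate scored by internal validation (mean per-molecule
squared Pearson correlation between re-solved and reference charges).

The fitted-model interface follows the Model/Results convention:
``EemCalibration(records, scheme="E").fit()`` returns
:class:`EemCalibrationResults` with the selected parameters, the k score
curve, internal validation statistics and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    EemParameters,
    MissingParameterError,
    SolverError,
    harmonic_electronegativity,
    solve_charges,
)
from .structures import Molecule, assign_atom_types, perceive_bonds, read_charge_table, read_pdb


class CalibrationError(ValueError):
    pass


#: default k grid: 0.05 to 1.50 inclusive, step 0.05
DEFAULT_K_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 1.5001, 0.05), 10))

#: below this many observations per atom type a warning is issued
_MIN_COMFORTABLE_ROWS = 30


@dataclass
class ReferenceRecord:
    """One calibration observation group: a molecule, its reference per-atom
    charges (e) and its harmonic-average molecular electronegativity."""

    molecule: Molecule
    ref_charges: np.ndarray
    chi_bar_ref: float

    def __post_init__(self) -> None:
        self.ref_charges = np.asarray(self.ref_charges, dtype=float)
        if self.ref_charges.shape != (self.molecule.n_atoms,):
            raise CalibrationError(
                f"record {self.molecule.id!r}: {len(self.ref_charges)} charges for "
                f"{self.molecule.n_atoms} atoms"
            )
        if not self.chi_bar_ref > 0:
            raise CalibrationError(f"record {self.molecule.id!r}: chi_bar_ref must be positive")

    @property
    def total_charge(self) -> float:
        return float(self.ref_charges.sum())


@dataclass
class ValidationStats:
    """Agreement between model and reference charges.

    R_avg is the mean per-molecule squared Pearson correlation; RMSD_avg and
    D_avg the mean per-molecule root-mean-square and mean-absolute deviation
    (both in e).  ``per_molecule`` holds (id, R2, RMSD, D) rows.
    """

    R_avg: float
    RMSD_avg: float
    D_avg: float
    per_molecule: list[tuple[str, float, float, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_molecule, columns=["molecule", "R2", "RMSD", "D"])


@dataclass
class CalibrationResult:
    """Outcome of the k grid search: selected parameters, the score curve,
    internal validation statistics, and per-type observation counts."""

    params: EemParameters
    k_grid: list[float]
    per_k_scores: dict[float, float]
    internal_stats: ValidationStats
    type_counts: dict[str, int]


def _pair_sums(mol: Molecule, charges: np.ndarray) -> np.ndarray:
    """sum_{j != i} q_j / R_ij for every atom i, from reference charges."""
    n = mol.n_atoms
    D = mol.distance_matrix() + np.eye(n)
    Cinv = 1.0 / D
    np.fill_diagonal(Cinv, 0.0)
    return Cinv @ charges


def build_regression_rows(
    records: list[ReferenceRecord], scheme: str, k: float
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Group the rearranged per-atom linear equations by atom type.

    Returns type key -> (x, y) with x the reference charge of each atom of
    that type and y = chi_bar_ref - k * sum_{j != i} q_j / R_ij.
    """
    grouped: dict[str, tuple[list[float], list[float]]] = {}
    for rec in records:
        mol = rec.molecule
        types = assign_atom_types(mol, scheme)
        y = rec.chi_bar_ref - k * _pair_sums(mol, rec.ref_charges)
        for t, xi, yi in zip(types, rec.ref_charges, y):
            xs, ys = grouped.setdefault(t, ([], []))
            xs.append(float(xi))
            ys.append(float(yi))
    return {t: (np.array(xs), np.array(ys)) for t, (xs, ys) in grouped.items()}


def fit_parameters(
    rows: dict[str, tuple[np.ndarray, np.ndarray]]
) -> dict[str, tuple[float, float]]:
    """Per-type ordinary least squares of y = A + B x (exact OLS solution)."""
    out: dict[str, tuple[float, float]] = {}
    for t, (x, y) in rows.items():
        if len(x) < 2:
            raise CalibrationError(f"atom type {t!r} has fewer than 2 observations")
        if np.ptp(x) == 0.0:
            raise CalibrationError(f"atom type {t!r} has zero variance in reference charges")
        if len(x) < _MIN_COMFORTABLE_ROWS:
            warnings.warn(
                f"atom type {t!r} has only {len(x)} observations; parameters may be unstable",
                stacklevel=2,
            )
        design = np.column_stack([np.ones_like(x), x])
        (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
        out[t] = (float(a), float(b))
    return out


def validate(params: EemParameters, records: list[ReferenceRecord]) -> ValidationStats:
    """Solve charges for every record (Q = sum of its reference charges) and
    compare with the reference: per-molecule squared Pearson R2, RMSD and
    mean absolute difference, averaged over molecules.

    Molecules on which the solver fails are reported with a warning and
    excluded from the averages; missing atom types raise immediately.
    """
    per_mol: list[tuple[str, float, float, float]] = []
    failures: list[str] = []
    for rec in records:
        mol = rec.molecule
        try:
            cs = solve_charges(mol, params, Q=rec.total_charge)
        except MissingParameterError:
            raise
        except SolverError as exc:
            failures.append(f"{mol.id}: {exc}")
            continue
        diff = cs.charges - rec.ref_charges
        rmsd = float(np.sqrt(np.mean(diff**2)))
        d = float(np.mean(np.abs(diff)))
        if mol.n_atoms < 2 or np.ptp(rec.ref_charges) == 0 or np.ptp(cs.charges) == 0:
            warnings.warn(
                f"molecule {mol.id!r}: correlation undefined (constant charges); skipped",
                stacklevel=2,
            )
            continue
        r = np.corrcoef(rec.ref_charges, cs.charges)[0, 1]
        per_mol.append((mol.id, float(r**2), rmsd, d))
    if failures:
        warnings.warn(
            "solver failed on {} molecule(s): {}".format(len(failures), "; ".join(failures)),
            stacklevel=2,
        )
    if not per_mol:
        raise CalibrationError("validation produced no scored molecules")
    arr = np.array([[r2, rmsd, d] for _, r2, rmsd, d in per_mol])
    return ValidationStats(
        R_avg=float(arr[:, 0].mean()),
        RMSD_avg=float(arr[:, 1].mean()),
        D_avg=float(arr[:, 2].mean()),
        per_molecule=per_mol,
    )


def grid_search_k(
    records: list[ReferenceRecord],
    scheme: str,
    k_grid: list[float] | tuple[float, ...] = DEFAULT_K_GRID,
) -> CalibrationResult:
    """Fit (A, B) at each k on the grid, score by internal-validation R_avg,
    and return the best model (ties broken toward the smallest k).

    k values whose fit violates model invariants (e.g. a non-positive fitted
    B) score NaN; if every k fails, the per-k errors are aggregated and
    raised.
    """
    k_grid = [float(k) for k in k_grid]
    if not k_grid or any(k <= 0 for k in k_grid):
        raise CalibrationError("k grid must be non-empty and strictly positive")
    scores: dict[float, float] = {}
    fits: dict[float, EemParameters] = {}
    errors: dict[float, str] = {}
    for k in sorted(k_grid):
        try:
            rows = build_regression_rows(records, scheme, k)
            table = fit_parameters(rows)
            params = EemParameters(scheme, k, table)
            stats = validate(params, records)
        except (CalibrationError, ValueError) as exc:
            scores[k] = float("nan")
            errors[k] = str(exc)
            continue
        scores[k] = stats.R_avg
        fits[k] = params
    if not fits:
        detail = "; ".join(f"k={k}: {msg}" for k, msg in errors.items())
        raise CalibrationError(f"calibration failed at every k value ({detail})")
    best_k = max(fits, key=lambda k: (scores[k], -k))
    best = fits[best_k]
    internal = validate(best, records)
    rows = build_regression_rows(records, scheme, best_k)
    type_counts = {t: len(x) for t, (x, _y) in rows.items()}
    return CalibrationResult(
        params=best,
        k_grid=sorted(k_grid),
        per_k_scores=scores,
        internal_stats=internal,
        type_counts=type_counts,
    )


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class EemCalibration:
    """Charge-model calibration as a fittable model.

    Parameters
    ----------
    records
        Reference observations (molecule + reference charges).
    scheme
        Atom-typing scheme, 'E' (element) or 'EX' (element + max bond order).
    k_grid
        Candidate values for the electrostatic scaling factor k.
    """

    def __init__(
        self,
        records: list[ReferenceRecord],
        scheme: str = "E",
        k_grid: list[float] | tuple[float, ...] = DEFAULT_K_GRID,
    ) -> None:
        if not records:
            raise CalibrationError("no reference records")
        self.records = list(records)
        self.scheme = scheme
        self.k_grid = [float(k) for k in k_grid]

    @classmethod
    def from_directory(cls, refset_dir, scheme: str = "E", **kwargs) -> "EemCalibration":
        """Build from an on-disk reference set (see :func:`read_refset`)."""
        return cls(read_refset(refset_dir), scheme=scheme, **kwargs)

    def fit(self) -> "EemCalibrationResults":
        result = grid_search_k(self.records, self.scheme, self.k_grid)
        return EemCalibrationResults(self, result)


@dataclass
class EemCalibrationResults:
    """Fitted calibration: selected parameters plus diagnostics."""

    model: EemCalibration
    result: CalibrationResult
    _external: ValidationStats | None = field(default=None, repr=False)

    @property
    def params(self) -> EemParameters:
        return self.result.params

    @property
    def k(self) -> float:
        return self.result.params.k

    @property
    def internal_stats(self) -> ValidationStats:
        return self.result.internal_stats

    def k_curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.result.per_k_scores.items()), columns=["k", "R_avg"]
        )

    def validate_external(self, records: list[ReferenceRecord]) -> ValidationStats:
        """External validation: score the fitted parameters on held-out records."""
        self._external = validate(self.params, records)
        return self._external

    def summary(self) -> str:
        res, stats = self.result, self.result.internal_stats
        lines = [
            "EEM calibration results",
            "=" * 55,
            f"scheme:          {self.params.scheme}",
            f"selected k:      {self.k:.4f}  (grid of {len(res.k_grid)} values,"
            f" {res.k_grid[0]:.2f}..{res.k_grid[-1]:.2f})",
            f"molecules:       {len(self.model.records)}",
            f"atom types:      {len(self.params.table)}",
            "",
            f"internal R_avg:  {stats.R_avg:.6f}",
            f"internal RMSD:   {stats.RMSD_avg:.6f} e",
            f"internal D_avg:  {stats.D_avg:.6f} e",
            "",
            f"{'type':<6}{'n':>7}{'A':>14}{'B':>14}",
            "-" * 41,
        ]
        for t in sorted(self.params.table):
            a, b = self.params.table[t]
            lines.append(f"{t:<6}{res.type_counts.get(t, 0):>7}{a:>14.6f}{b:>14.6f}")
        if self._external is not None:
            ext = self._external
            lines += [
                "",
                f"external R_avg:  {ext.R_avg:.6f}",
                f"external RMSD:   {ext.RMSD_avg:.6f} e",
                f"external D_avg:  {ext.D_avg:.6f} e",
            ]
        return "\n".join(lines)

    def plot_k_curve(self, ax=None):
        """Plot internal-validation R_avg against k (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        curve = self.k_curve()
        ax.plot(curve["k"], curve["R_avg"], marker="o", ms=3)
        ax.axvline(self.k, color="crimson", lw=0.8, ls="--", label=f"selected k = {self.k:g}")
        ax.set_xlabel("k")
        ax.set_ylabel(r"internal $R_{avg}$")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Reference-set directory I/O
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.tsv"


def read_refset(refset_dir) -> list[ReferenceRecord]:
    """Load a reference set directory: a `manifest.tsv` with columns
    `mol_id` (and optional `total_charge` override) plus, per molecule,
    `<id>.pdb` and `<id>.charges.tsv`.  Bonds are perceived on load and the
    harmonic-mean electronegativity computed from the packaged Pauling table.
    """
    refset_dir = Path(refset_dir)
    manifest = refset_dir / MANIFEST_NAME
    if not manifest.is_file():
        raise CalibrationError(f"missing manifest file {manifest}")
    df = pd.read_csv(manifest, sep="\t")
    if "mol_id" not in df.columns:
        raise CalibrationError(f"{manifest} lacks a mol_id column")
    records: list[ReferenceRecord] = []
    for row in df.itertuples():
        mid = str(row.mol_id)
        mol = read_pdb(refset_dir / f"{mid}.pdb", mol_id=mid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # synthetic residues have no templates
            mol.bonds = perceive_bonds(mol)
        table = read_charge_table(refset_dir / f"{mid}.charges.tsv")
        table.check_against(mol)
        charges = table.charges
        if "total_charge" in df.columns and pd.notna(getattr(row, "total_charge", None)):
            mol.total_charge = float(row.total_charge)
        else:
            mol.total_charge = float(charges.sum())
        records.append(
            ReferenceRecord(mol, charges, harmonic_electronegativity(mol))
        )
    if not records:
        raise CalibrationError(f"reference set {refset_dir} is empty")
    return records
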