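# Methods

## 1. Charge model

The electronegativity of atom *i* in a molecule of *n* atoms is modelled as

```
chi_i = A_i + B_i * q_i + k * sum_{j != i} q_j / R_ij        (i = 1 … n)
```

with per-type parameters `A_i` (electronegativity-like offset, arbitrary
consistent units), `B_i > 0` (hardness-like self-term, same units per
elementary charge) and a global Coulomb screening constant `k > 0`
(units · Å / e). Distances `R_ij` are in Å, charges in e.

Equalization (`chi_i = chi_bar` for all *i*) plus charge conservation
(`sum q_i = Q`) give the dense symmetric linear system

```
| B_1    k/R_12 …  -1 | | q_1     |   | -A_1 |
| k/R_21 B_2    …  -1 | | q_2     | = | -A_2 |
|  …                  | |  …      |   |  …   |
|  1      1     …   0 | | chi_bar |   |  Q   |
```

Assumptions: fixed geometry (no polarization feedback on coordinates), a
single global `k`, pairwise 1/R coupling without distance cutoffs, and atom
types that capture all chemical variation of `(A, B)`. Waters are dropped at
structure load; ions participate in the field like any other atom.

## 2. Parameters

| symbol | meaning | default / origin |
| --- | --- | --- |
| `k` | Coulomb screening constant | grid-searched, 0.05–1.50 step 0.05 |
| `A_t, B_t` | per-type regression parameters | calibrated per atom type |
| scheme | atom typing | `E` (element) or `EX` (element + max bond order) |
| `chi_bar_ref` | molecular electronegativity of a reference record | harmonic mean of Pauling electronegativities (H 2.20, C 2.55, N 3.04, O 3.44, S 2.58, Ca 1.00) |
| `Q` | total molecular charge | user-supplied or formal charge at neutral pH (Asp/Glu −1, Lys/Arg +1, His 0, charged termini, ion charges) |

Calibration rearranges the per-atom equation into `y = A_t + B_t * q_i` with
`y = chi_bar_ref − k * sum_j q_j / R_ij` and fits per-type ordinary least
squares at each grid `k`; the selected `k` maximizes internal-validation
`R_avg` (mean per-molecule squared Pearson between solved and reference
charges), ties broken toward smaller `k`. Validation also reports
`RMSD_avg` and `D_avg` (mean absolute difference); `D ≤ RMSD` always
(Cauchy–Schwarz).

## 3. Synthetic reference sets

Real calibrations use quantum-chemical charges for thousands of protein
fragments; those inputs are unavailable at desk scale, so the test and
demonstration data are forward-generated from the model itself
(`eemkit.synthetic`):

* **Geometry** — random atom clouds in a 12 Å box with pairwise distances
  ≥ 1 Å, grouped into 5-atom pseudo-residues, consecutive atoms chain-bonded
  with random bond orders (material for `EX` typing).
* **Composition** — element frequencies emulating protein reference sets
  (mostly H and C; N, O; trace S and Ca).
* **Identifiability floor** — every modelled element is guaranteed ≥ 10
  observations spread over ≥ 2 molecules. Proportion-faithful scaling of a
  protein-sized composition down to ~600 atoms would leave trace elements
  with 2–3 atoms; a two-parameter per-type regression on so few noisy points
  is unidentifiable (the regressor's sample spread can be arbitrarily small,
  making the slope estimate unbounded — observed as spurious negative-B
  fits). Large reference sets have this floor implicitly; a small emulated
  set must impose it explicitly. Ten points suffice for the sample spread to
  concentrate near its population value, bounding the slope error well below
  sign-flip scale.
* **Charges** — `chi_bar` is pinned to the harmonic-mean electronegativity
  and the n-atom equalization system is solved; the total charge is then
  implied by the solution. This makes noiseless records *exactly*
  model-consistent: the calibration regression rows lie exactly on
  `y = A + Bx`, so ground-truth parameter recovery can be asserted at
  1e-6. Optional i.i.d. Gaussian noise (σ in e) emulates the discrepancy
  between reference quantum charges and the model.

**Limitations**: the clouds are not protein geometry; bond orders are random
rather than chemical; the noise model is homoscedastic and uncorrelated,
unlike real QM-vs-EEM residuals; and with `chi_bar` pinned to the harmonic
mean the generated total charges are small non-integers rather than formal
integer charges.

## 4. Conformer-pair ground truth

`make_profile_fixture` constructs a pair of conformations in which the
charge transfer is concentrated on one known residue. The design is not
arbitrary — two intuitive constructions fail:

* In a folded or random geometry, rigidly displacing a residue mostly
  produces *intra-residue redistribution*: its atoms' charges change, but
  with cancelling signs, so the net descriptor `delta_q` stays small while
  spatial neighbors pick up coherent net changes.
* Giving the displaced residue a distinctive, strongly charged composition
  (e.g. oxygen-rich) backfires: to first order the perturbation force on an
  atom scales with the charge on the *other* side of each changed pair
  coupling, so a strongly charged segment chiefly perturbs its neighbors
  (in experiments the neighbor residue carried the maximum `delta_q` in
  ~28/30 seeds).

The working construction is a compositionally **uniform carbon ring**
(50 atoms, neighbor spacing 1.5 Å, seeded coordinate jitter) carrying a
nonzero total charge (+2 e), displaced **radially outward**. On a ring an
outward move strictly increases the distance to every other atom, so each
displaced atom loses coupling to all ~45 others coherently, while any single
bystander atom loses coupling only to the 5 displaced atoms. The net flow
therefore concentrates on the moved residue: across 30 seeds it carries the
maximal `delta_q` and is flagged in 30/30 runs (28–30/30 across sweeps of
the displaced residue index, displacement 0.8–3 Å, and direction tilt).

## 5. Profiling and significance

Residues are paired across conformations by (chain, residue number,
insertion code); per-residue descriptors are `delta_q = |Σq_b − Σq_a|` over
the full residue atom sets (net mode; `sum_abs` available) and `rmsd_q` over
name-matched atoms. A residue is significant when its value strictly exceeds
mean + 1 population SD over all scored residues, separately per descriptor.
Excluded chains (e.g. a binding partner) are removed from the bookkeeping
but kept in the charge solve, so their electrostatic influence remains.

## 6. Numerical choices

* Dense LAPACK LU (`dgetrf`/`dgetrs`) with `dgecon` reciprocal condition
  estimate; a warning is issued below 1e-10 and the solution is verified
  (`residual < 1e-8`, `|Σq − Q| < 1e-8`) before being returned.
* Interatomic distances below 0.5 Å are rejected as clashes before solving.
* Per-type OLS via `numpy.linalg.lstsq`; types with < 2 observations or zero
  regressor variance raise a named error, < 30 observations warn.
* Failed fits at individual grid `k` values score NaN and are skipped; only
  all-`k` failure aborts, with the per-`k` reasons aggregated.
* Parameter files store 9 decimals; charge tables 6 decimals; PDB
  coordinates 3 decimals (the dominant round-trip error, ~1e-5 on recovered
  parameters).

## 7. Open design decisions

* `delta_q` is the absolute **net** residue difference, interpreting the
  per-residue quantity as charge transferred to/from the residue as a unit;
  the per-atom absolute sum is available as `delta_mode="sum_abs"`.
* The significance rule uses the population (not sample) SD and a strict
  inequality, so a degenerate distribution flags nothing.
* `EX` typing uses the *maximum* incident bond order; alternatives
  (valence-state typing, aromaticity perception) were out of scope.
* The generator pins `chi_bar` to the harmonic mean and lets `Q` be implied,
  prioritizing exact model-consistency of noiseless records over integer
  total charges; drawing `Q` from {−1, 0, +1} instead would make exact
  parameter recovery impossible, since the reference `chi_bar` used by the
  calibration regression would no longer solve the equalization equations.
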