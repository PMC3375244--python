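import numpy as np
import pytest

from eemkit import synthetic
from eemkit.calibration import ReferenceRecord
from eemkit.core import EemParameters
from eemkit.structures import Atom, Molecule


@pytest.fixture(scope="session")
def true_params() -> EemParameters:
    return synthetic.DEFAULT_TRUE_PARAMS


@pytest.fixture(scope="session")
def gly_gly() -> Molecule:
    return synthetic.gly_gly()


@pytest.fixture(scope="session")
def ser_gly_ca() -> Molecule:
    return synthetic.ser_gly(with_calcium=True)


@pytest.fixture(scope="session")
def reference_records(true_params) -> list[ReferenceRecord]:
    """20 noiseless synthetic molecules generated at the ground-truth k* = 0.4."""
    spec = synthetic.FixtureSpec(n_molecules=20, seed=11)
    return synthetic.make_reference_set(spec)


SMALL_PARAMS = EemParameters(
    "E", 0.4, {"H": (2.20, 8.0), "C": (2.55, 6.0), "N": (3.04, 7.0), "O": (3.44, 9.0)}
)


@pytest.fixture(scope="session")
def small_records() -> list[ReferenceRecord]:
    """5 noiseless molecules over the four common elements only."""
    spec = synthetic.FixtureSpec(
        n_molecules=5,
        atoms_per_molecule=(10, 15),
        element_frequencies={"H": 4.0, "C": 3.0, "N": 1.5, "O": 1.5},
        true_params=SMALL_PARAMS,
        seed=21,
    )
    return synthetic.make_reference_set(spec)


def random_molecule(rng: np.random.Generator, n: int, elements=("H", "C", "N", "O")) -> Molecule:
    """A small random atom cloud with pairwise distances of at least 1 A."""
    coords = []
    while len(coords) < n:
        cand = rng.uniform(0, 4.0 + n, size=3)
        if not coords or min(np.linalg.norm(np.array(coords) - cand, axis=1)) >= 1.0:
            coords.append(cand)
    elems = [str(e) for e in rng.choice(elements, size=n)]
    atoms = [
        Atom(index=i, element=e, name=f"{e}{i}", coords=tuple(coords[i]),
             residue_number=i // 3 + 1, residue_name="SYN")
        for i, e in enumerate(elems)
    ]
    return Molecule(f"rand{n}", atoms)
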