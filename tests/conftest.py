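import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from pepsigna import (
    assign_types,
    load_default_table,
    make_synthetic_complex,
)
from pepsigna.atom_typing import TypedAtomSet


@pytest.fixture(scope="session")
def default_table():
    return load_default_table()


@pytest.fixture(scope="session")
def toy_complex():
    """Deterministic 60-residue protein + 10-residue peptide in contact."""
    return make_synthetic_complex(60, 10, seed=1)


@pytest.fixture(scope="session")
def typed_peptide(toy_complex, default_table):
    return assign_types(toy_complex.chain("B"), default_table)


def random_typed_set(rng, n_atoms, box=12.0):
    """Random coordinates with random non-empty category subsets."""
    from pepsigna.atom_typing import CATEGORIES
    from pepsigna.structure_io import Atom

    coords = rng.uniform(0, box, size=(n_atoms, 3))
    atoms, cats = [], []
    for i in range(n_atoms):
        k = int(rng.integers(1, 4))
        chosen = frozenset(rng.choice(CATEGORIES, size=k, replace=False).tolist())
        atoms.append(
            Atom(
                serial=i + 1, name="CA", element="C", residue_name="ALA",
                residue_seq=i + 1, icode=" ", chain_id="A", coord=coords[i],
            )
        )
        cats.append(chosen)
    return TypedAtomSet(atoms=atoms, categories=cats)
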