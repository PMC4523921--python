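import numpy as np
import pytest

from ppaffinity.structure import Atom, Residue, Structure
from ppaffinity.synthetic import (
    SyntheticDatasetSpec,
    ToyComplexSpec,
    make_regression_dataset,
    make_toy_complex,
)
from ppaffinity._tables import ONE_TO_THREE


def single_atom_residue(chain, seq, one_letter, xyz, name="CA", element="C"):
    return Residue(
        chain_id=chain, seq_id=seq, icode="",
        name=ONE_TO_THREE[one_letter],
        atoms=[Atom(name=name, element=element,
                    coord=np.asarray(xyz, dtype=float))])


def two_partner_structure(res_a, res_b):
    return Structure(residues=list(res_a) + list(res_b),
                     partner_of={"A": "A", "B": "B"})


@pytest.fixture
def mixed_toy_complex():
    """5 intended contacts (3 charged/apolar, 2 polar/polar) plus extras."""
    spec = ToyComplexSpec(
        contact_pairs=["charged/apolar"] * 3 + ["polar/polar"] * 2,
        n_extra_a=4, n_extra_b=4, seed=11)
    return make_toy_complex(spec)


@pytest.fixture
def noiseless_dataset():
    spec = SyntheticDatasetSpec(n=120, noise_sigma=0.0, seed=7)
    return make_regression_dataset(spec), spec


@pytest.fixture
def noisy_dataset():
    spec = SyntheticDatasetSpec(n=200, noise_sigma=1.0, seed=13)
    return make_regression_dataset(spec), spec
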