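import numpy as np
import pytest

from alphared import (
    ConfidenceSpec,
    Pose,
    ToyComplexSpec,
    make_confidence,
    make_toy_complex,
    split_partners,
)


@pytest.fixture(scope="session")
def toy():
    """A deterministic toy complex: (complex structure, native pose, partner split)."""
    return make_toy_complex(ToyComplexSpec(seed=3))


@pytest.fixture(scope="session")
def toy_partners(toy):
    structure, _, partners = toy
    return split_partners(structure, partners)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def flat_confidence(toy):
    """Uniform high-confidence profile over the toy complex."""
    structure, _, _ = toy
    return make_confidence(structure, ConfidenceSpec(baseline=90.0))


def random_ca_structure(n_residues, rng, chain_id="A", spread=3.8):
    """Random-walk Cα-only chain used for geometry oracles."""
    from alphared import Atom, Residue, Structure

    coords = np.cumsum(rng.normal(scale=spread / np.sqrt(3), size=(n_residues, 3)), axis=0)
    st = Structure()
    for i, c in enumerate(coords):
        st.residues.append(
            Residue(
                chain_id=chain_id,
                seq_num=i + 1,
                name="ALA",
                atoms=[Atom("CA", "C", c, 80.0)],
            )
        )
    return st


def perturbed_copy(structure, rng, sigma):
    """Copy of a structure with iid Gaussian coordinate noise."""
    out = structure.copy()
    for res in out.residues:
        for atom in res.atoms:
            atom.coord = atom.coord + rng.normal(scale=sigma, size=3)
    return out
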