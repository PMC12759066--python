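import numpy as np
import pytest

from afmetrics.fixtures import FixtureSpec
from afmetrics.types import (
    Atom,
    ChainRecord,
    PredictedModel,
    Residue,
)


def make_residue(index, center, plddt=90.0, with_hydrogen=True, name="ALA"):
    """Small residue: a few heavy atoms within 1 Å of the centre."""
    cx, cy, cz = center
    atoms = [
        Atom("N", "N", cx - 0.7, cy, cz),
        Atom("CA", "C", cx, cy, cz),
        Atom("C", "C", cx + 0.7, cy, cz),
    ]
    if with_hydrogen:
        atoms.append(Atom("HA", "H", cx, cy + 0.5, cz))
    return Residue(index=index, name=name, atoms=atoms, plddt=plddt)


def make_two_chain_model(positions_a, positions_b, plddt=90.0, model_id="toy"):
    """Two-chain model with one residue per centre position."""
    chains = [
        ChainRecord(
            "A",
            [make_residue(i + 1, p, plddt) for i, p in enumerate(positions_a)],
        ),
        ChainRecord(
            "B",
            [make_residue(i + 1, p, plddt) for i, p in enumerate(positions_b)],
        ),
    ]
    return PredictedModel(model_id=model_id, chains=chains)


def random_toy_model(rng, n_a=30, n_b=30, box=40.0):
    """Random two-chain toy with mixed H/heavy atoms for oracle tests."""

    def chain(chain_id, n):
        residues = []
        for i in range(1, n + 1):
            center = rng.uniform(0, box, size=3)
            n_atoms = rng.integers(2, 5)
            atoms = []
            for k in range(n_atoms):
                off = rng.uniform(-1.5, 1.5, size=3)
                element = "H" if rng.random() < 0.3 else "C"
                atoms.append(
                    Atom(f"X{k}", element, *(center + off))
                )
            residues.append(
                Residue(index=i, name="ALA", atoms=atoms, plddt=90.0)
            )
        return ChainRecord(chain_id, residues)

    return PredictedModel(
        model_id="random_toy", chains=[chain("A", n_a), chain("B", n_b)]
    )


@pytest.fixture
def shared_spec():
    """Six interface pairs present in all five models, clean confidences."""
    return FixtureSpec(
        interface_pairs=[(2, 3), (5, 7), (8, 11), (12, 14), (15, 20), (20, 25)],
        shared_fraction=1.0,
        seed=11,
        target_id="shared",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
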