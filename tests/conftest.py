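import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from seqaffinity import ComplexDataset, ProteinChain, ProteinComplex


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_complex(cid, ligand_seqs, receptor_seqs, delta_g=None, kd=None):
    return ProteinComplex(
        id=cid,
        ligand=tuple(
            ProteinChain(f"{cid}_L{i+1}", s) for i, s in enumerate(ligand_seqs)
        ),
        receptor=tuple(
            ProteinChain(f"{cid}_R{i+1}", s) for i, s in enumerate(receptor_seqs)
        ),
        delta_g=delta_g,
        kd=kd,
    )


@pytest.fixture
def tiny_dataset(rng):
    """Five labelled single/multi-chain complexes with random sequences."""
    from oracles import random_sequence

    complexes = []
    for i, dg in enumerate([-6.0, -8.5, -10.0, -12.5, -15.0]):
        n_l = 1 + (i % 2)
        complexes.append(
            make_complex(
                f"C{i+1}",
                [random_sequence(rng, 30, 50) for _ in range(n_l)],
                [random_sequence(rng, 30, 50)],
                delta_g=dg,
            )
        )
    return ComplexDataset(complexes, provenance="tiny fixture")
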