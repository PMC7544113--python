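"""Shared fixtures: deterministic random circles and synthetic genomes."""

import numpy as np
import pytest

from plastotype import CircularSequence, generate_plastome


def random_circle(n: int, seed: int, gc: float = 0.38) -> CircularSequence:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    residues = "".join(rng.choice(list("ACGT"), size=n, p=p))
    return CircularSequence(f"circle_{n}_{seed}", residues)


@pytest.fixture
def toy_w_genome():
    seq, feats, truth = generate_plastome("W", 11, "toy")
    return seq, feats, truth


@pytest.fixture
def toy_s_genome():
    seq, feats, truth = generate_plastome("S", 11, "toy")
    return seq, feats, truth
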