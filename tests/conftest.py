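import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from motifbayes import GenomeRecord


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_genomes(rng):
    """Three short, compositionally distinct genomes."""
    biased = []
    for gid, probs in (
        ("alpha", [0.4, 0.1, 0.1, 0.4]),
        ("beta", [0.1, 0.4, 0.4, 0.1]),
        ("gamma", [0.25, 0.25, 0.25, 0.25]),
    ):
        seq = "".join(rng.choice(list("ACGT"), size=400, p=probs))
        biased.append(GenomeRecord.from_sequence(gid, seq))
    return biased
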