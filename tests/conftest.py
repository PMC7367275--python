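import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from geckoabc import synthdata
from geckoabc.iodata import GenotypeMatrix, SequenceAlignment


@pytest.fixture(scope="session")
def toy_fixtures():
    return synthdata.make_toy_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240925)


def random_genotype_matrix(rng, n=8, loci=4, n_alleles=5, missing=0.1) -> GenotypeMatrix:
    sizes = 100 + 4 * np.arange(n_alleles)
    calls = rng.choice(sizes, size=(n, loci, 2))
    mask = rng.random((n, loci)) < missing
    calls[mask] = -1
    pops = ["P1" if i < n // 2 else "P2" for i in range(n)]
    return GenotypeMatrix([f"i{j}" for j in range(n)], [f"L{j}" for j in range(loci)], calls, pops)


def random_alignment(rng, n=6, length=12, with_missing=False) -> SequenceAlignment:
    alphabet = list("ACGT") + (["N", "-"] if with_missing else [])
    probs = None
    if with_missing:
        probs = [0.22, 0.22, 0.22, 0.22, 0.06, 0.06]
    seqs = ["".join(rng.choice(alphabet, size=length, p=probs)) for _ in range(n)]
    pops = ["PopA" if i % 2 == 0 else "PopB" for i in range(n)]
    return SequenceAlignment([f"s{j}" for j in range(n)], pops, seqs)
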