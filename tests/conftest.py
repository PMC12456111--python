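import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from landgen.genio import GenotypeMatrix, MISSING
from landgen.synthdata import SynthConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One moderately sized synthetic dataset shared across tests."""
    return simulate_dataset(SynthConfig(seed=1, n_neutral=500, n_adaptive=10))


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-scale synthetic dataset (seed 1)."""
    return simulate_dataset(SynthConfig(seed=1))


def make_genotypes(dosages, pops=None, chrom=None, pos=None) -> GenotypeMatrix:
    """Hand-rolled GenotypeMatrix builder for toy fixtures."""
    d = np.asarray(dosages, dtype=np.int16)
    n_ind, n_loci = d.shape
    pops = pops if pops is not None else ["A"] * n_ind
    chrom = chrom if chrom is not None else [f"t{i}" for i in range(n_loci)]
    pos = pos if pos is not None else [10] * n_loci
    return GenotypeMatrix(
        dosages=d,
        locus_chrom=np.array(chrom, dtype=object),
        locus_pos=np.array(pos),
        individual_ids=np.array([f"i{k}" for k in range(n_ind)], dtype=object),
        pop_of_individual=np.array(pops, dtype=object),
    )
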