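import numpy as np
import pytest

from autozygomap.genome import GenotypeMatrix, MarkerPanel
from autozygomap.pedigree import build_consanguineous_pedigree
from autozygomap.simulate import SimParams

SMALL_GENOME = {"1": 120_000_000, "2": 100_000_000, "13": 115_000_000}


@pytest.fixture
def small_genome():
    return dict(SMALL_GENOME)


@pytest.fixture
def small_params(small_genome):
    return SimParams(seed=11, chrom_lengths=small_genome, background_n=200)


@pytest.fixture
def fc_pedigree():
    return build_consanguineous_pedigree("first-cousin", 2, family_id="FAM1")


@pytest.fixture
def small_panel(small_genome):
    return MarkerPanel.uniform(small_genome, spacing_bp=30_000)


def matrix_from_codes(codes, positions, chrom="1", sample="S1"):
    """One-sample, one-chromosome genotype matrix from raw call codes."""
    panel = MarkerPanel({chrom: np.asarray(positions, dtype=np.int64)})
    data = {chrom: np.asarray(codes, dtype=np.int8).reshape(1, -1)}
    return GenotypeMatrix(samples=[sample], panel=panel, data=data), panel
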