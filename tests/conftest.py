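import numpy as np
import pytest

from autokin.genome import GenomeMap, build_genome
from autokin.pedigree import common_relationships


@pytest.fixture(scope="session")
def common_fixture():
    """The common-relationships pedigree and its labelled pair table."""
    return common_relationships()


@pytest.fixture(scope="session")
def unlinked_genome():
    """10 chromosomes with one locus each: effectively unlinked loci."""
    return build_genome(n_chrom=10, length_cm=100.0, spacing_cm=100.0)


@pytest.fixture(scope="session")
def coarse_genome():
    """Default-shaped genome at 1 cM spacing (1,000 loci) for speed."""
    return build_genome(n_chrom=10, length_cm=100.0, spacing_cm=1.0)


@pytest.fixture
def single_locus_genome():
    return GenomeMap(
        names=("c1",), lengths=(1.0,), positions=(np.array([0.5]),)
    )
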