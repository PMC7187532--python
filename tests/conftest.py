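from __future__ import annotations

import numpy as np
import pytest

from circkit.core import GeneModel, GenomeRef
from circkit.simulate import FixtureConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic study bundle (seed 7), shared across tests."""
    return generate_bundle(FixtureConfig(seed=7))


@pytest.fixture(scope="session")
def small_cfg():
    return FixtureConfig(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def three_exon_gene():
    """A + strand toy gene: exons [100,200), [300,400), [500,600)."""
    return GeneModel(
        gene_id="gA",
        symbol="GA",
        chrom="chr1",
        strand="+",
        transcripts={"t1": [(100, 200), (300, 400), (500, 600)]},
    )


@pytest.fixture()
def toy_genome(rng):
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=1000)])
    return GenomeRef(species_code="hsa", chroms={"chr1": seq})
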