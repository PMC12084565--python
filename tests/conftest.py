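import numpy as np
import pandas as pd
import pytest

import damaccess as da


@pytest.fixture(scope="session")
def random_genome():
    """Small seeded uniform genome shared by oracle-equivalence tests."""
    genome, classes = da.generate_genome(20_000, seed=101)
    return genome, classes


@pytest.fixture(scope="session")
def random_catalog(random_genome):
    genome, _ = random_genome
    return da.build_filtered_catalog(genome)


def make_genome(seq: str, chrom: str = "chr1") -> da.GenomeSequence:
    return da.GenomeSequence({chrom: seq})


@pytest.fixture
def toy_gene_table():
    rng = np.random.default_rng(7)
    n = 23
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:02d}" for i in range(n)],
            "chrom": "chr1",
            "tss": rng.integers(2_000, 18_000, n),
            "strand": rng.choice(["+", "-"], n),
            "expression": rng.uniform(0, 100, n),
        }
    )
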