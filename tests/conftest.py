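import numpy as np
import pandas as pd
import pytest

from corepress import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy_genome():
    return simulate.gen_genome(2, 2_000_000, 40, seed=42)


@pytest.fixture(scope="session")
def toy_genes(toy_genome):
    return toy_genome[0]


@pytest.fixture
def two_group_design():
    return pd.DataFrame(
        {"group": ["A"] * 4 + ["B"] * 4},
        index=[f"s{i}" for i in range(8)],
    )


def intervals_df(*triples):
    return pd.DataFrame(triples, columns=["chrom", "start", "end"])
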