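import numpy as np
import pandas as pd
import pytest

from parvapop.popio import (
    AlignedSequenceSet,
    PopulationMap,
    collapse_haplotypes,
    table_from_records,
)
from parvapop.synth import generate_invasion, generate_native_range


@pytest.fixture(scope="session")
def toy_alignment():
    """Four 10-bp sequences in two populations: one SNP splits 3/1, plus one
    column holding an N that complete deletion must drop."""
    seqs = (
        "ACGTACGTAN",  # N column dropped by complete deletion
        "ACGTACGTAA",
        "ACGTACGTAA",
        "ACTTACGTAA",  # SNP at column 3 (1-based)
    )
    return AlignedSequenceSet(ids=("s1", "s2", "s3", "s4"), seqs=seqs)


@pytest.fixture(scope="session")
def toy_popmap():
    df = pd.DataFrame(
        {
            "population": ["P1", "P1", "P2", "P2"],
            "group": ["native", "native", "invasive", "invasive"],
            "lat": [40.0, 40.0, 50.0, 50.0],
            "lon": [110.0, 110.0, 10.0, 10.0],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="id"),
    )
    return PopulationMap(table=df)


@pytest.fixture(scope="session")
def native_dataset():
    return generate_native_range(seed=20110603)


@pytest.fixture(scope="session")
def long_distance_dataset(native_dataset):
    return generate_invasion(native_dataset, "long_distance", seed=20110604)


@pytest.fixture(scope="session")
def long_distance_hap(long_distance_dataset):
    ds = long_distance_dataset
    return collapse_haplotypes(ds.alignment, ds.popmap)


@pytest.fixture()
def rng():
    return np.random.default_rng(20110603)


@pytest.fixture(scope="session")
def two_pop_table():
    """A = {h1 x3, h2 x1}, B = {h1 x1, h2 x3}; h1/h2 differ by one transition
    in ten sites (the hand-enumerable FST fixture)."""
    h1, h2 = "AAAAAAAAAA", "GAAAAAAAAA"
    seqs = [h1, h1, h1, h2, h1, h2, h2, h2]
    pops = ["A"] * 4 + ["B"] * 4
    return table_from_records([f"s{i}" for i in range(8)], seqs, pops)
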