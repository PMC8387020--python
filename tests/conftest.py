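import numpy as np
import pandas as pd
import pytest

from hampcr import AmpliconMap, CountTable


@pytest.fixture
def small_table() -> CountTable:
    # one host ASV, three microbial ASVs, three samples
    return CountTable.from_arrays(
        [[50, 4, 0],
         [25, 96, 10],
         [25, 0, 30],
         [0, 0, 60]],
        ["host_GI", "m1", "m2", "m3"],
        ["s1", "s2", "s3"],
    )


@pytest.fixture
def small_map() -> AmpliconMap:
    return AmpliconMap.from_dict(
        {"host_GI": "host", "m1": "16S-V4", "m2": "16S-V4", "m3": "16S-V4"},
        taxa={"host_GI": "Arabidopsis", "m1": "Sphingomonas", "m2": "Sphingomonas",
              "m3": "Pseudomonas"},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_table(rng) -> CountTable:
    counts = rng.integers(0, 500, size=(20, 6))
    return CountTable.from_arrays(
        counts, [f"asv{i}" for i in range(20)], [f"s{j}" for j in range(6)]
    )
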