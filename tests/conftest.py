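import numpy as np
import pandas as pd
import pytest

from gemscreen.screen import CountTable
from gemscreen.synthetic import random_cds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ref_cds():
    return random_cds(400, seed=5)


@pytest.fixture
def small_table():
    """Tiny count table: 5 strains, 3+3 samples, strain s3 drug-enriched."""
    counts = pd.DataFrame(
        {
            "control_1": [100, 200, 50, 80, 10],
            "control_2": [110, 190, 55, 75, 12],
            "control_3": [95, 210, 48, 85, 9],
            "drug_1": [105, 195, 52, 2400, 11],
            "drug_2": [98, 205, 50, 2600, 10],
            "drug_3": [108, 198, 49, 2500, 13],
        },
        index=[f"s{i}" for i in range(5)],
    )
    cond = pd.Series({c: ("drug" if c.startswith("drug") else "control")
                      for c in counts.columns})
    return CountTable(counts, cond)
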