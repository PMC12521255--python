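from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

import padcare as pc

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

DATA = Path(__file__).parent / "data"

#: cells of the bundled published distance matrix that are internally
#: inconsistent: the printed cell does not equal the Euclidean distance
#: between the printed PAD row and the printed benchmark coordinates.
INCONSISTENT_CELLS = {
    ("S_3", "Fear"),
    ("S_11", "Relaxation"),
    ("S_12", "Relaxation"),
    ("S_16", "Reliance"),
}


@pytest.fixture(scope="session")
def codebook():
    return pc.default_codebook()


@pytest.fixture(scope="session")
def benchmarks():
    return pc.default_benchmarks()


@pytest.fixture(scope="session")
def item_means():
    return pc.published_item_means()


@pytest.fixture(scope="session")
def demand_stats():
    return pc.published_demand_stats()


@pytest.fixture(scope="session")
def published():
    """Published PAD values, distance matrix and starred tendencies."""
    return pd.read_csv(DATA / "published_tendencies.csv")


@pytest.fixture(scope="session")
def evaluated(item_means, codebook, benchmarks):
    """Full pipeline output on the published item means."""
    return pc.evaluate_all(item_means, codebook, benchmarks, require_complete=True)
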