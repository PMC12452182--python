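import dataclasses
import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `import oracles`

import riboarch as ra


@pytest.fixture(scope="session")
def fam_map():
    return ra.packaged_family_map()


@pytest.fixture(scope="session")
def default_collection():
    """The default synthetic collection, seed 1 (shared across tests)."""
    return ra.simulate_collection(ra.SimConfig(seed=1))


@pytest.fixture(scope="session")
def classified(default_collection, fam_map):
    """Classified groups + terminator calls for the default collection."""
    regions = {r.region_id: r for r in default_collection.regions}
    groups, calls = ra.classify_collection(default_collection.hits, regions, fam_map)
    return groups, calls


@pytest.fixture(scope="session")
def genes_frame(default_collection):
    return pd.DataFrame([dataclasses.asdict(g) for g in default_collection.genes])
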