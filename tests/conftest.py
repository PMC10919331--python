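import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pleoprophage import FixtureSpec, make_genome_with_provirus, make_toy_structure


@pytest.fixture(scope="session")
def planted_genome():
    """Default synthetic chromosome with one planted provirus and its truth."""
    return make_genome_with_provirus(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def toy_structure():
    return make_toy_structure(n_res=50, planted_bridges=2, planted_cluster_sizes=(4,), seed=1)


@pytest.fixture
def data_dir():
    """Optional local real-data directory (accessions are accepted as files only)."""
    return Path(__file__).resolve().parent.parent / "data"
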