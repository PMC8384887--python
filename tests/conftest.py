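import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mitosel.simulate.genomes import MitogenomeSpec, simulate_mitogenome


@pytest.fixture(scope="session")
def synthetic_genome():
    """Default condor-like synthetic mitogenome with its truth record."""
    genome, truth = simulate_mitogenome(MitogenomeSpec(seed=1))
    return genome, truth


@pytest.fixture(scope="session")
def two_clade_tree():
    from mitosel.studies import two_clade_tree as build

    return build()
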