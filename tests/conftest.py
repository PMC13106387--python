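import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from scfatlas import relatedness as rel
from scfatlas import synth
from scfatlas.pathways import load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def planted_pair():
    """A proteome pair with 15 planted orthologs at 85% identity and 15
    unique proteins each (expected POCP 50, AAI ~85)."""
    truth = synth.ProteomePairTruth(
        n_orthologs=15, n_unique_a=15, n_unique_b=15,
        target_identity=0.85, length_range=(120, 250), seed=101,
    )
    a, b, ortho_map = synth.simulate_proteome_pair(truth, "GA", "GB")
    return truth, a, b, ortho_map


@pytest.fixture(scope="session")
def planted_record(planted_pair):
    _, a, b, _ = planted_pair
    return rel.compute_pocp(a, b)
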