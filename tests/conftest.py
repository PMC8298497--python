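import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from edsem import CohortConfig, toy_graph_fixtures


@pytest.fixture(scope="session")
def toy_graphs():
    return toy_graph_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def study_config():
    """Default cohort configuration: the study's reported generating world."""
    return CohortConfig()
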