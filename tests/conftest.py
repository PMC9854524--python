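import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from slimscan import (
    SyntheticConfig,
    build_scoring,
    calibrate_evd,
    generate_database,
)


@pytest.fixture(scope="session")
def scheme():
    return build_scoring()


@pytest.fixture(scope="session")
def small_db():
    """60-protein database, half planted with 7-mer-family motifs."""
    config = SyntheticConfig(n_proteins=60, length_mean=200.0,
                             length_sd=50.0, seed=7)
    return generate_database(config)


@pytest.fixture(scope="session")
def afp_evd(scheme):
    """E-value model for LDSYQCT against length-200-ish backgrounds."""
    return calibrate_evd(scheme, "LDSYQCT", (200.0, 50.0),
                         n_samples=300, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
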