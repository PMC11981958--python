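import numpy as np
import pandas as pd
import pytest

from ednariver.curation import ASVTable
from ednariver.io_formats import SequenceRecord
from ednariver.synthetic import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic basin reused by pipeline-level tests."""
    cfg = SimConfig(seed=11, n_sites=12, n_asv_pool=40, p_detect=1.0, error_rate=0.2)
    return cfg, simulate_bundle(cfg)


@pytest.fixture
def toy_table():
    """Four ASVs over two sites × two replicates with known structure."""
    counts = pd.DataFrame(
        {
            "S1_r1": [50, 5, 0, 9],
            "S1_r2": [40, 4, 0, 8],
            "S2_r1": [30, 0, 20, 0],
            "S2_r2": [25, 0, 15, 0],
        },
        index=["a1", "a2", "a3", "a4"],
    )
    seqs = {
        "a1": SequenceRecord("a1", "ACGTACGTACGTACGTACGT"),
        "a2": SequenceRecord("a2", "ACGTACGTACGTACGTACGA"),  # d=1 from a1
        "a3": SequenceRecord("a3", "TTTTGGGGCCCCAAAATTTT"),
        "a4": SequenceRecord("a4", "TTTTGGGGCCCCAAAATTTA"),  # d=1 from a3
    }
    return ASVTable(counts, seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
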