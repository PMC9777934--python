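import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tefp.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """Three small genomes with planted copies, decay and truncation."""
    cfg = SimulationConfig(n_species=3, contig_length=150_000,
                           copies_per_genome=5, seed=11,
                           decay_rate=0.03, truncation_prob=0.2)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_bundle():
    """Two genomes with pristine copies (no decay, no truncation)."""
    cfg = SimulationConfig(n_species=2, contig_length=80_000,
                           copies_per_genome=3, seed=4,
                           decay_rate=0.0, truncation_prob=0.0)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
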