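"""Shared fixtures: tiny architectures and small synthetic datasets.

The default 1.29M-parameter architecture is exercised where the checks are
about the architecture itself; everything else runs on scaled-down network
configs and small generated complexes to keep the suite fast on one CPU.
"""

import numpy as np
import pytest
from hypothesis import settings

from akscore import (NetworkConfig, SyntheticComplexSpec, generate_dataset)

settings.register_profile("suite", derandomize=True, database=None)
settings.load_profile("suite")

TINY_GRID_EDGE = 30  # the featurization edge is part of the pipeline contract


@pytest.fixture(scope="session")
def tiny_config():
    """A miniature network with the same topology as the default one."""
    return NetworkConfig(stem_channels=16, block_channels=(16, 16, 32),
                         head_hidden=8)


@pytest.fixture(scope="session")
def small_dataset():
    """Six seeded synthetic complexes with grids and planted labels."""
    spec = SyntheticComplexSpec(seed=42)
    gen, grids, labels = generate_dataset(spec, 6)
    return gen, grids, labels


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
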