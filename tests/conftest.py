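import numpy as np
import pytest

from screensim import (
    CRISPRN,
    GenomeConfig,
    LibraryConfig,
    ScreenConfig,
    build_genome,
    build_library,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_genome(rng):
    return build_genome(GenomeConfig(num_genes=50), rng)


@pytest.fixture
def small_library(small_genome, rng):
    return build_library(small_genome, LibraryConfig(), rng)


@pytest.fixture
def crisprn_library(small_genome, rng):
    return build_library(small_genome, LibraryConfig(mode=CRISPRN), rng)


@pytest.fixture
def fast_config():
    """A small but complete FACS screen configuration for pipeline tests."""
    cfg = ScreenConfig()
    cfg.genome.num_genes = 100
    cfg.infection.representation = 50
    cfg.facs.bottleneck_representation = 50
    cfg.sequencing.representation = 50
    cfg.top_n = 20
    return cfg
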