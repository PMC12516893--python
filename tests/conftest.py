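import numpy as np
import pytest

from tillseq import RunConfig, build_scheme, generate_references


@pytest.fixture(scope="session")
def scheme8():
    """The platform-scale scheme: 512 families on an 8x8x8 cube."""
    return build_scheme(512, 8)


@pytest.fixture(scope="session")
def small_config():
    """A pilot-scale configuration for fast end-to-end tests: 8 families on a
    2x2x2 cube (6 pools of 4), two amplicons, generous per-family coverage."""
    return RunConfig(
        cube_dim=2,
        n_families=8,
        n_amplicons=2,
        n_genes=2,
        length_range=(452, 520),
        coverage=40.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def panel17():
    """A default 17-amplicon dual-haplotype panel."""
    return generate_references(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
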