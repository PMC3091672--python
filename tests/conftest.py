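import numpy as np
import pytest

from supersage.simulate import (
    SimulationConfig,
    build_truth,
    generate_count_matrix,
    generate_reference,
)


@pytest.fixture(scope="session")
def small_config():
    """Small five-library simulation with references, fully mappable mix."""
    return SimulationConfig(
        n_transcripts=400,
        library_depths=(3000, 3000, 3000, 3000, 3000),
        unmappable_fraction=0.35,
        antisense_fraction=0.10,
        sequencing_error_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return build_truth(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_config, small_truth):
    matrix, _ = generate_count_matrix(small_config, small_truth)
    return matrix


@pytest.fixture(scope="session")
def small_reference(small_config, small_truth):
    refs, _ = generate_reference(small_config, small_truth)
    return refs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
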