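import numpy as np
import pytest

from brainte.cohort import (
    ParcellationScheme,
    SyntheticTruth,
    default_dwell_matrix,
    generate_cohort,
    generate_connectome,
    generate_state_centroids,
)


@pytest.fixture(scope="session")
def parcellation():
    return ParcellationScheme.default(86)


@pytest.fixture(scope="session")
def small_parcellation():
    # 9 regions, one per network (minimum that populates every network)
    from brainte.cohort import NETWORKS

    return ParcellationScheme(
        region_names=tuple(f"r{i}" for i in range(9)), networks=NETWORKS
    )


@pytest.fixture(scope="session")
def truth(parcellation):
    return SyntheticTruth(
        true_centroids=generate_state_centroids(parcellation, 4, 1.0, seed=1),
        dwell_matrix=default_dwell_matrix(4),
        noise_sd=0.5,
        seed=1,
    )


@pytest.fixture(scope="session")
def cohort_draw(truth, parcellation):
    """20 subjects x 150 frames; shared across tests that only read it."""
    return generate_cohort(20, truth, parcellation, seed=7, n_frames=150)


@pytest.fixture(scope="session")
def connectome10():
    return generate_connectome(10, 2, 0.5, seed=3)


@pytest.fixture(scope="session")
def connectome86():
    return generate_connectome(86, 4, 0.3, seed=5)
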