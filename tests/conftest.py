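import numpy as np
import pandas as pd
import pytest

from bbpls.synthetic import Parcellation, SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort with planted structure, shared across tests."""
    return generate_cohort(
        SynthConfig(n_participants=240, n_cortical_parcels=60, seed=7)
    )


def prepare_and_fit(data, idx=None, variance_threshold=0.5, n_components=5):
    """Residualize -> PCA -> PLS -> loadings on one (sub)sample."""
    from bbpls.pipeline import fit_sample

    return fit_sample(data, idx, variance_threshold, n_components)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    return prepare_and_fit(small_cohort)


@pytest.fixture()
def toy_parcellation():
    """4 cortical parcels (2 networks) + 1 subcortical (network 3)."""
    cent = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [-1.0, 0.0, 0.0],
            [0.0, -1.0, 0.0],
            [np.nan, np.nan, np.nan],
        ]
    )
    return Parcellation(
        parcel_ids=["A", "B", "C", "D", "S"],
        hemisphere=np.array(["left"] * 4 + ["subcortical"], dtype=object),
        centroids=cent,
        network=np.array([1, 1, 2, 2, 3]),
        n_networks=3,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
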