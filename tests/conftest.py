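import numpy as np
import pandas as pd
import pytest

import lcmsqc as L
from lcmsqc.synthdata import SyntheticConfig


@pytest.fixture(scope="session")
def cultivar_design_1batch():
    """64-sample cultivar design (8 classes x 4 agronomic x 2 technical)."""
    return L.cultivar_design(seed=3)


@pytest.fixture(scope="session")
def noisefree_table(cultivar_design_1batch):
    cfg = SyntheticConfig(
        n_features=40,
        n_batches=0,
        drift_amplitude=0.25,
        drift_shape="exponential",
        cv_injection=0.0,
        cv_extraction=0.0,
        cv_batch=0.0,
        seed=5,
    )
    return L.simulate_feature_table(cfg, cultivar_design_1batch)


@pytest.fixture(scope="session")
def noisy_table(cultivar_design_1batch):
    cfg = SyntheticConfig(
        n_features=60,
        n_batches=0,
        drift_amplitude=0.2,
        drift_shape="linear",
        cv_injection=0.086,
        cv_extraction=0.006,
        cv_batch=0.0,
        seed=7,
    )
    return L.simulate_feature_table(cfg, cultivar_design_1batch)


@pytest.fixture
def spike_compounds():
    return pd.DataFrame(
        {
            "recovery": [0.84, 1.0, 0.95],
            "matrix_effect": [0.6, 1.2, 1.0],
            "solvent_response": [1e5, 2e5, 5e4],
            "background": [2e4, 0.0, 1e4],
        },
        index=["c1", "c2", "c3"],
    )


def nested_lognormal(rng, cvs, shape=(5, 5, 4), mean=1e5):
    """Balanced nested draws: batch -> extract -> injection, multiplicative."""
    from lcmsqc.synthdata import cv_to_sigma

    n_b, n_e, n_r = shape
    return mean * np.exp(
        rng.normal(0, cv_to_sigma(cvs[0]), (n_b, 1, 1))
        + rng.normal(0, cv_to_sigma(cvs[1]), (n_b, n_e, 1))
        + rng.normal(0, cv_to_sigma(cvs[2]), (n_b, n_e, n_r))
    )
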