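import warnings

import numpy as np
import pytest

from cnvrules import (
    HET_DEL,
    HOM_DEL,
    WILD_TYPE,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # small synthetic cohorts legitimately trigger small-class / reduced-k warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort: 48 samples, 120 markers, 20-marker gene region."""
    return SimulationConfig(
        n_samples={WILD_TYPE: 24, HET_DEL: 14, HOM_DEL: 10},
        n_markers=120,
        gene_region=(50, 70),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    dataset, profile = simulate_dataset(small_config, "LRR")
    return dataset, profile


@pytest.fixture(scope="session")
def noiseless_config():
    """Noise-free emission: the three states are exactly separable."""
    return SimulationConfig(
        n_samples={WILD_TYPE: 30, HET_DEL: 12, HOM_DEL: 8},
        n_markers=100,
        gene_region=(40, 45),
        lrr_sd=0.0,
        baf_sd=0.0,
        background_cnv_rate=0.0,
        seed=2,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    dataset, profile = simulate_dataset(noiseless_config, "LRR")
    return dataset, profile


def region_marker_ids(dataset, config):
    lo, hi = config.gene_region
    return {m.marker_id for m in dataset.signal.markers[lo:hi]}
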