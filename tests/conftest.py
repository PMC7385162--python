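import numpy as np
import pytest

from cytopool import repeated_metacluster, signal_cohort
from cytopool.features import frequency_features


@pytest.fixture(scope="session")
def tiny_run():
    """A small signal cohort clustered end to end, shared across tests.

    4 patients per class, 300 cells per sample: enough structure for every
    stage to produce meaningful output, small enough to run in seconds.
    """
    cohort, truth = signal_cohort(seed=11, n_patients_per_class=4, cells_per_sample=300)
    meta = repeated_metacluster(
        cohort.cells, k_per_sample=20, k_prime=5, n_solutions=3, master_seed=11
    )
    F = frequency_features(meta, sample_ids=cohort.manifest.sample_ids)
    return cohort, truth, meta, F


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
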