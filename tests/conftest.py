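import numpy as np
import pytest

from splsmorph import SimulationSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_cohort():
    """Deterministic 20-subject, 30-parcel null cohort."""
    spec = SimulationSpec(
        n_subjects=20, n_parcels=30, n_blocks=6, seed=7,
    )
    return simulate_cohort(spec)


def standardize(X):
    """Reference column standardization (ddof=1), for oracle computations."""
    X = np.asarray(X, dtype=float)
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
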