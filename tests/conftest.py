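import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import ictalgraph as ig


@pytest.fixture(scope="session")
def hub_spec():
    return ig.hub_study_spec(n_channels=12, n_hubs=4, rng_seed=7)


@pytest.fixture(scope="session")
def hub_patient(hub_spec):
    """One seeded good-outcome patient with 4 hubs planted among 12 channels."""
    return ig.simulate_patient(hub_spec, patient_id="p01")


@pytest.fixture(scope="session")
def band_noise_pair():
    """Two independent beta-band 3-s noise signals at 500 Hz."""
    rng = np.random.default_rng(123)
    from ictalgraph.preprocessing import band_filter

    x = band_filter(rng.standard_normal(1500), (15, 29), 500.0)
    y = band_filter(rng.standard_normal(1500), (15, 29), 500.0)
    return x, y


def assert_patients_equal(a, b, signal_tol=1e-6):
    assert a.patient_id == b.patient_id
    assert a.engel_class == b.engel_class
    assert a.onset_type == b.onset_type
    assert a.sex == b.sex and a.laterality == b.laterality
    assert a.age_at_surgery == pytest.approx(b.age_at_surgery)
    assert a.channels == b.channels
    assert set(a.epochs) == set(b.epochs)
    for s, ep in a.epochs.items():
        other = b.epochs[s]
        assert ep.fs == other.fs
        np.testing.assert_allclose(ep.data, other.data, atol=signal_tol, rtol=0)
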