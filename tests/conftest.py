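import numpy as np
import pytest
from hypothesis import settings

import pdxauth as px

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def assays():
    return px.default_panel()


@pytest.fixture
def config():
    return px.SimulationConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def reference_pair(config, assays):
    """Two distinct simulated reference profiles plus their registry."""
    rng = np.random.default_rng(11)
    a, b = px.simulate_profiles(config, 2, assays=assays, rng=rng)
    a.sample_id, b.sample_id = "REF-A", "REF-B"
    registry = px.assign_references([a, b], assays=assays)
    return a, b, registry


def make_profile(sample_id, categories, assays, sex=px.Sex.UNKNOWN):
    """Construct a profile from a per-assay category list."""
    calls = {
        a.assay_id: px.GenotypeCall(c) for a, c in zip(assays, categories, strict=True)
    }
    p = px.SNPProfile(sample_id=sample_id, calls=calls)
    p.inferred_sex = sex
    return p
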