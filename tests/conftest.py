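import numpy as np
import pytest

from diurnalfmri import CohortSpec, EffectParams, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two families, scaled-down acquisition; shared across read-only tests."""
    spec = CohortSpec(n_families=2, family_size_weights=(1.0,), n_frames=120,
                      n_regions=12, n_cortical=10, physio_hz=50.0, seed=7)
    effects = EffectParams(seed=7)
    return simulate_cohort(spec, effects)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
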