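import numpy as np
import pytest

from dti.predictor import PredictorConfig
from dti.synthetic import SyntheticSpec, generate_bundle


@pytest.fixture(scope="session")
def tiny_bundle():
    """A small bundle with planted structure, cheap enough for CV smoke tests."""
    spec = SyntheticSpec(m=40, n=40, n_attributes=80, k_drug=2, k_target=2,
                         seed=11)
    return generate_bundle(spec)


@pytest.fixture(scope="session")
def default_bundle():
    """The default planted-signal fixture (m=150, n=300)."""
    return generate_bundle(SyntheticSpec(seed=7))


def light_predictor_config(input_length, seed=0, **overrides):
    """Fixture-scale classifier settings (small filters, few epochs)."""
    defaults = dict(conv_filters=(8, 16, 16, 16), dense_width=64,
                    batch_size=256, epochs=5, learning_rate=1e-3)
    defaults.update(overrides)
    return PredictorConfig(input_length=input_length, seed=seed, **defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
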