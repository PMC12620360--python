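import numpy as np
import pytest

from earattn.model import ModelConfig
from earattn.preprocess import preprocess_dataset
from earattn.simulate import GeneratorConfig, generate_paired_dataset


@pytest.fixture(scope="session")
def small_config():
    """Eight paired subjects under the default (stress-effect) conditions."""
    return GeneratorConfig(n_subjects=8, seed=123)


@pytest.fixture(scope="session")
def small_recordings(small_config):
    return generate_paired_dataset(small_config)


@pytest.fixture(scope="session")
def small_epochs(small_recordings):
    return preprocess_dataset(small_recordings)


@pytest.fixture()
def tiny_model_config():
    """A reduced-width config that still yields 35 tokens, for fast model
    tests (210 input samples instead of 7500)."""
    return dict(
        kernel_lengths=(9, 7, 5, 3),
        filters=(3, 4, 4, 5),
        pool=((2, 2), (3, 3), (1, 1)),
        input_samples=210,
        dropout_p=0.0,
        hidden_dim=6,
        attention_dk=3,
        attention_dv=2,
        self_attention_dv=3,
        transformer_d_model=8,
        transformer_d_ff=16,
    )


@pytest.fixture()
def tiny_model_cfg_obj(tiny_model_config):
    return ModelConfig(**tiny_model_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
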