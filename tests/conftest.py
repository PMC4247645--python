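import numpy as np
import pytest

from premove import EffectSpec, PipelineConfig, generate_trialset


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def strong_trials_small(config):
    """A small strong-effect synthetic session (decoder unit tests)."""
    spec = EffectSpec(n_trials=14, seed=5)
    return generate_trialset(spec).drop_channels(config.drop_channels)


@pytest.fixture(scope="session")
def loo_small(strong_trials_small, config):
    """Leave-one-out summary on the small session, with fold models kept."""
    from premove.evaluation import loo_evaluate

    return loo_evaluate(strong_trials_small, config, keep_models=True)
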