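import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model():
    """Quarter-of-quarter width model for fast structural tests."""
    from promptseg import EncoderConfig, PromptSegModel

    return PromptSegModel(base_channels=16, encoder_cfg=EncoderConfig(),
                          seed=7).eval()


@pytest.fixture(scope="session")
def desk_runs():
    """Two identical-seed desk-scale prompt-recovery runs.

    Trained once per session; shared by the conditioning, determinism and
    acceptance tests.  This is the expensive fixture (a few minutes each).
    """
    from promptseg.training import prompt_recovery_experiment

    run_a = prompt_recovery_experiment(seed=0)
    run_b = prompt_recovery_experiment(seed=0)
    return run_a, run_b
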