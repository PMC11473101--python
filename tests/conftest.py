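import numpy as np
import pytest

from pupilwalk.walker_stimuli import WalkerConfig, generate_walker


@pytest.fixture(scope="session")
def neutral_walker():
    return generate_walker(WalkerConfig(emotion_score=0.0), seed=11)


@pytest.fixture(scope="session")
def default_experiment():
    """One simulated experiment under the reference conditions, shared
    across tests that only read from it."""
    from pupilwalk.synthetic_pupil import default_paper_config, simulate_experiment

    cfg = default_paper_config(seed=2024)
    trials, truth = simulate_experiment(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def default_matrix(default_experiment):
    from pupilwalk.pupil_preprocess import preprocess_experiment
    from pupilwalk.synthetic_pupil import CONDITIONS

    cfg, trials, _ = default_experiment
    return preprocess_experiment(trials, stim_ms=cfg.stim_ms, conditions=CONDITIONS)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
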