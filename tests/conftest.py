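import numpy as np
import pandas as pd
import pytest

from revlearn import AgentParams, TaskConfig, build_schedule, simulate_agent


@pytest.fixture(scope="session")
def schedule():
    """Canonical 714-trial, 18-reversal schedule."""
    from revlearn import canonical_schedule

    return canonical_schedule()


@pytest.fixture(scope="session")
def small_schedule():
    """One stimulus, two 30-trial blocks (one reversal)."""
    cfg = TaskConfig(
        n_stimuli=1,
        blocks_per_stimulus=2,
        block_length_range=(30, 30),
        total_trials=60,
        seed=3,
    )
    return build_schedule(cfg)


@pytest.fixture(scope="session")
def m3_params():
    return AgentParams(beta=2.5, play_bias=0.0, kappa_weights=(0.0, 1.0), eta=0.3)


@pytest.fixture(scope="session")
def m3_dataset(schedule, m3_params):
    return simulate_agent(m3_params, "M3", schedule, seed=11)


def make_toy_schedule(p_rewards, valences=None, stimulus=0, seed=0):
    """Hand-built single-stimulus schedule for small exact tests."""
    n = len(p_rewards)
    from revlearn.task import good_bad_label, noise_level

    df = pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "stimulus": stimulus,
            "block": 1,
            "trials_since_reversal": np.arange(1, n + 1),
            "p_reward": p_rewards,
            "noise_level": [noise_level(p) for p in p_rewards],
            "label": [good_bad_label(p) for p in p_rewards],
        }
    )
    if valences is None:
        rng = np.random.default_rng(seed)
        valences = np.where(rng.random(n) < df["p_reward"], "win", "loss")
    df["outcome_valence"] = valences
    return df
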