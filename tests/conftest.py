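import numpy as np
import pandas as pd
import pytest

from contextrl import AgentParams, make_schedule
from contextrl.synth import simulate_population
from contextrl.task import TaskSchedule


@pytest.fixture(scope="session")
def schedule():
    return make_schedule("behavioral", 0, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """12 prior-drawn subjects on per-subject schedules."""
    return simulate_population(None, n_subjects=12, seed=5)


@pytest.fixture(scope="session")
def beta0_cohort(schedule):
    """500 zero-inverse-temperature agents (pure random choosers)."""
    params = [AgentParams(0.5, 0.5, 0.0)] * 500
    return simulate_population(schedule, params_list=params, seed=7)


def custom_schedule(n_pairs: int, valence: str = "reward",
                    trials_per_pair: int = 20,
                    prob_good: float = 0.75) -> TaskSchedule:
    """Single-condition schedule with an arbitrary number of pairs.

    Pairs are presented in strict rotation; used to build long streams for
    estimator-consistency checks.
    """
    context = "reward_only" if valence == "reward" else "punishment_only"
    rows = []
    t = 0
    for rep in range(trials_per_pair):
        for p in range(n_pairs):
            t += 1
            rows.append((t, 1, context, p, valence, rep + 1))
    trials = pd.DataFrame(
        rows, columns=["trial", "block", "context", "pair", "valence",
                       "trial_in_pair"])
    return TaskSchedule(study_version="behavioral", counterbalance_index=0,
                        outcome_prob_good=prob_good, trials=trials)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
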