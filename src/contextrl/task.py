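"""Probabilistic reward/punishment learning task structure.

The task has six blocks of 40 trials (240 trials per subject). Block
contexts are reward-only, punishment-only, and mixed; each context occurs
twice, in an alternating, counterbalanced order. Every block contains two
symbol pairs with 20 trials each, interleaved pseudorandomly so that no
pair repeats more than four times in a row. In a mixed block one pair is a
reward pair and the other a punishment pair; single-valence blocks hold two
pairs of the same valence.

For a reward pair the "good" option wins (+1) with probability
``outcome_prob_good`` and yields nothing otherwise; the "bad" option has
the reverse probabilities. For a punishment pair the "good" option is the
one with the *low* loss probability (it loses -1 with probability
``1 - outcome_prob_good``). The behavioral study version uses 0.75/0.25,
the fMRI version 0.70/0.30.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTEXTS = ("reward_only", "punishment_only", "mixed")
VALENCES = ("reward", "punishment")
CONDITIONS = ("reward_mixed", "reward_only", "punishment_mixed", "punishment_only")

N_BLOCKS = 6
TRIALS_PER_BLOCK = 40
TRIALS_PER_PAIR = 20
MAX_RUN = 4

_PROB_GOOD = {"behavioral": 0.75, "fmri": 0.70}

#: the 3! alternating context orders (each context twice, orders repeat)
_CONTEXT_ORDERS = [list(p) + list(p) for p in itertools.permutations(CONTEXTS)]


def condition_of(valence: str, context: str) -> str:
    """Map a trial's valence and block context to one of the four conditions."""
    return f"{valence}_mixed" if context == "mixed" else f"{valence}_only"


@dataclass
class TaskSchedule:
    """Block/pair/probability structure of one run of the task.

    ``trials`` has one row per trial in chronological order with columns
    ``trial`` (1..240), ``block`` (1..6), ``context``, ``pair`` (global id),
    ``valence``, ``trial_in_pair`` (1..20).
    """

    study_version: str
    counterbalance_index: int
    outcome_prob_good: float
    trials: pd.DataFrame = field(repr=False)

    @property
    def outcome_prob_bad(self) -> float:
        return 1.0 - self.outcome_prob_good

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def pair_valence(self) -> dict[int, str]:
        return dict(
            self.trials.drop_duplicates("pair").set_index("pair")["valence"]
        )


def _interleave_pairs(rng: np.random.Generator) -> np.ndarray:
    """0/1 sequence of 40 with 20 of each and no run longer than MAX_RUN."""
    seq = np.array([0] * TRIALS_PER_PAIR + [1] * TRIALS_PER_PAIR)
    while True:
        rng.shuffle(seq)
        if _max_run(seq) <= MAX_RUN:
            return seq.copy()


def _max_run(seq) -> int:
    best = run = 1
    for a, b in zip(seq[:-1], seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def make_schedule(
    study_version: str = "behavioral",
    counterbalance_index: int = 0,
    seed: int | np.random.Generator = 0,
) -> TaskSchedule:
    """Build a 240-trial schedule for one subject.

    Parameters
    ----------
    study_version
        ``"behavioral"`` (0.75/0.25 outcome probabilities) or ``"fmri"``
        (0.70/0.30).
    counterbalance_index
        Selects one of the six alternating context orders (taken modulo 6).
    seed
        Seed or generator for the pseudorandom pair interleaving.
    """
    if study_version not in _PROB_GOOD:
        raise ValueError(f"unknown study_version: {study_version!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = _CONTEXT_ORDERS[counterbalance_index % len(_CONTEXT_ORDERS)]

    rows = []
    trial_no = 0
    for block_index, context in enumerate(order, start=1):
        pair_a = 2 * (block_index - 1)      # globally unique pair ids
        pair_b = pair_a + 1
        if context == "reward_only":
            valences = {pair_a: "reward", pair_b: "reward"}
        elif context == "punishment_only":
            valences = {pair_a: "punishment", pair_b: "punishment"}
        else:
            valences = {pair_a: "reward", pair_b: "punishment"}
        seq = _interleave_pairs(rng)
        counts = {pair_a: 0, pair_b: 0}
        for bit in seq:
            pair = pair_a if bit == 0 else pair_b
            counts[pair] += 1
            trial_no += 1
            rows.append(
                (trial_no, block_index, context, pair, valences[pair], counts[pair])
            )
    trials = pd.DataFrame(
        rows, columns=["trial", "block", "context", "pair", "valence", "trial_in_pair"]
    )
    return TaskSchedule(
        study_version=study_version,
        counterbalance_index=counterbalance_index % len(_CONTEXT_ORDERS),
        outcome_prob_good=_PROB_GOOD[study_version],
        trials=trials,
    )
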