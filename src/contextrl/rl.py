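"""Rescorla-Wagner model family with valence-specific learning rates.

The model learns option values :math:`Q` from prediction errors
:math:`\\delta = \\rho\\,r - Q_{chosen}` with separate learning rates for
positive (:math:`\\alpha^+`) and negative (:math:`\\alpha^-`) prediction
errors, and chooses between the two options of a pair through a softmax
with inverse temperature :math:`\\beta`:

.. math::
    P(A) = \\frac{1}{1 + e^{-\\beta (Q_A - Q_B)}}

Outcomes are coded +1 (win), 0 (nothing), -1 (loss); initial values default
to +0.5 for reward pairs and -0.5 for punishment pairs. The optional
sensitivity scalar :math:`\\rho` rescales outcomes before the prediction
error is formed; :math:`\\rho = 1` reproduces the base model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels

Q0_SCHEMES = ("signed_half", "zero", "free")
CONTEXT_SCHEMES = (None, "null", "alpha_only", "beta_only", "full")


@dataclass(frozen=True)
class AgentParams:
    """One agent's parameters: learning rates, inverse temperature, sensitivity.

    ``alpha_pos``/``alpha_neg`` must lie in [0, 1]; ``beta`` and ``rho`` are
    non-negative. ``q0_scheme`` selects the value initialization:
    ``signed_half`` (+0.5 reward pairs, -0.5 punishment pairs), ``zero``,
    or ``free`` with explicit per-valence values in ``q0_free``.
    """

    alpha_pos: float
    alpha_neg: float
    beta: float
    rho: float = 1.0
    q0_scheme: str = "signed_half"
    q0_free: dict | None = None

    def __post_init__(self):
        if not (0.0 <= self.alpha_pos <= 1.0 and 0.0 <= self.alpha_neg <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if self.beta < 0 or self.rho < 0:
            raise ValueError("beta and rho must be non-negative")
        if self.q0_scheme not in Q0_SCHEMES:
            raise ValueError(f"unknown q0_scheme: {self.q0_scheme!r}")
        if self.q0_scheme == "free" and self.q0_free is None:
            raise ValueError("q0_scheme='free' requires q0_free")

    def with_(self, **kw) -> "AgentParams":
        return replace(self, **kw)

    def q0_for(self, valence: str) -> float:
        if self.q0_scheme == "signed_half":
            return 0.5 if valence == "reward" else -0.5
        if self.q0_scheme == "zero":
            return 0.0
        return float(self.q0_free[valence])


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are free and how they vary.

    ``n_alphas`` is 2 for separate positive/negative learning rates, 1 for a
    shared rate. ``context_scheme`` applies when a valence's mixed and
    separate streams are fit jointly: ``null`` shares alpha and beta,
    ``alpha_only``/``beta_only`` let one of them vary by context, ``full``
    frees both. ``sensitivity`` adds the outcome-scaling parameter rho.
    """

    n_alphas: int = 2
    context_scheme: str | None = None
    sensitivity: bool = False
    q0_scheme: str = "signed_half"
    q0_free: dict | None = None

    def __post_init__(self):
        if self.n_alphas not in (1, 2):
            raise ValueError("n_alphas must be 1 or 2")
        if self.context_scheme not in CONTEXT_SCHEMES:
            raise ValueError(f"unknown context_scheme: {self.context_scheme!r}")
        if self.context_scheme is not None and self.n_alphas != 1:
            raise ValueError("context-scheme variants use a single learning rate")

    @property
    def k(self) -> int:
        """Free-parameter count."""
        if self.context_scheme is None:
            return self.n_alphas + 1 + (1 if self.sensitivity else 0)
        return {"null": 2, "alpha_only": 3, "beta_only": 3, "full": 4}[self.context_scheme]


# --- elementary model operations -------------------------------------------

def prediction_error(q_chosen: float, r: float, rho: float = 1.0) -> float:
    """Signed prediction error delta = rho * r - Q(chosen)."""
    return rho * r - q_chosen


def update_value(q_chosen: float, delta: float, alpha_pos: float, alpha_neg: float) -> float:
    """Update the chosen option's value by the valence-matched learning rate."""
    if delta > 0:
        return q_chosen + alpha_pos * delta
    if delta < 0:
        return q_chosen + alpha_neg * delta
    return q_chosen


def choice_prob(q_a: float, q_b: float, beta: float) -> float:
    """Softmax probability of choosing option A over B (overflow-safe)."""
    x = np.clip(beta * (q_a - q_b), -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(-x))


# --- compiled condition streams ---------------------------------------------

@dataclass
class Stream:
    """A condition stream compiled to flat arrays for the replay kernel."""

    pair_idx: np.ndarray          # int64, 0-based contiguous
    chosen_good: np.ndarray       # int8
    outcome: np.ndarray           # float64
    pair_valence: np.ndarray      # str per pair (in pair_idx order)
    index: np.ndarray = field(default=None)  # original row positions

    @property
    def n_trials(self) -> int:
        return len(self.pair_idx)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_valence)

    def q0(self, scheme: str = "signed_half", free: dict | None = None) -> np.ndarray:
        ref = AgentParams(0, 0, 0, q0_scheme=scheme, q0_free=free)
        return np.array([ref.q0_for(v) for v in self.pair_valence])


def compile_stream(stream_df: pd.DataFrame) -> Stream:
    """Turn one condition's trial rows into a :class:`Stream`.

    Rows must be in chronological order (checked through the ``trial``
    column when present); invalid trials are dropped.
    """
    df = stream_df
    if "trial" in df.columns:
        tr = df["trial"].to_numpy()
        if np.any(np.diff(tr) < 0):
            raise ValueError("trials are not in chronological order")
    if "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    pairs = pd.unique(df["pair"])
    pair_map = {p: i for i, p in enumerate(pairs)}
    pair_idx = df["pair"].map(pair_map).to_numpy(dtype=np.int64)
    choice = df["choice"]
    if choice.dtype == object:
        unknown = set(choice.unique()) - {"good", "bad"}
        if unknown:
            raise ValueError(f"unknown choice labels: {unknown}")
        chosen_good = (choice == "good").to_numpy(dtype=np.int8)
    else:
        chosen_good = choice.to_numpy(dtype=np.int8)
    outcome = df["outcome"].to_numpy(dtype=np.float64)
    valence = df.drop_duplicates("pair").set_index("pair")["valence"]
    pair_valence = np.array([valence[p] for p in pairs], dtype=object)
    return Stream(pair_idx, chosen_good, outcome, pair_valence,
                  index=df.index.to_numpy())


def replay_nll_arrays(stream: Stream, alpha_pos: float, alpha_neg: float,
                      beta: float, rho: float = 1.0,
                      q0: np.ndarray | None = None,
                      q0_scheme: str = "signed_half",
                      q0_free: dict | None = None):
    """Kernel wrapper: (nll, per-trial signed PE, gradient) for one stream."""
    if q0 is None:
        q0 = stream.q0(q0_scheme, q0_free)
    return _kernels.replay_nll(
        stream.pair_idx, stream.chosen_good, stream.outcome, q0,
        stream.n_pairs, float(alpha_pos), float(alpha_neg), float(beta), float(rho),
    )


def replay_negloglik(stream_df: pd.DataFrame, params: AgentParams,
                     model_spec: ModelSpec | None = None):
    """Trial-replay negative log-likelihood of one condition stream.

    Replays the Q-value trajectories from their initialization under
    ``params`` and accumulates ``-sum log P(chosen)``. Returns
    ``(nll, pe)`` where ``pe`` is the signed prediction error of every
    valid trial in chronological order.
    """
    stream = compile_stream(stream_df)
    alpha_neg = params.alpha_neg if (model_spec is None or model_spec.n_alphas == 2) \
        else params.alpha_pos
    nll, pe, _ = replay_nll_arrays(
        stream, params.alpha_pos, alpha_neg, params.beta, params.rho,
        q0_scheme=params.q0_scheme, q0_free=params.q0_free,
    )
    return nll, pe


def pe_table(stream_df: pd.DataFrame, params: AgentParams) -> pd.DataFrame:
    """Valid trials of the stream with a ``pe`` column appended."""
    stream = compile_stream(stream_df)
    _, pe, _ = replay_nll_arrays(
        stream, params.alpha_pos, params.alpha_neg, params.beta, params.rho,
        q0_scheme=params.q0_scheme, q0_free=params.q0_free,
    )
    out = stream_df.loc[stream.index].copy()
    out["pe"] = pe
    return out
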