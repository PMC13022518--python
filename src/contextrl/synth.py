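"""Synthetic data generators: agents, cohorts, BOLD traces, and foci sets.

These generators provide ground-truth inputs for every downstream stage:
model-driven choice data on the 6-block / 240-trial task, event-related ROI
traces whose amplitude depends on punishment history, and per-study
meta-analysis coordinate sets with a planted convergence cluster.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels, bold, mkda
from .rl import AgentParams
from .task import CONDITIONS, TaskSchedule, condition_of, make_schedule

#: Weakly informative priors used for MAP fitting and for drawing simulated
#: agents: Beta(1.1, 1.1) on each learning rate and Gamma(shape 15,
#: scale 0.75) on the inverse temperature (mean 11.25, mode 10.5 -- close
#: to the fixed-beta = 10 robustness check).
@dataclass(frozen=True)
class PriorSpec:
    alpha_a: float = 1.1
    alpha_b: float = 1.1
    beta_shape: float = 15.0
    beta_scale: float = 0.75

    def draw(self, rng: np.random.Generator, q0_scheme: str = "signed_half") -> AgentParams:
        return AgentParams(
            alpha_pos=float(rng.beta(self.alpha_a, self.alpha_b)),
            alpha_neg=float(rng.beta(self.alpha_a, self.alpha_b)),
            beta=float(rng.gamma(self.beta_shape, self.beta_scale)),
            q0_scheme=q0_scheme,
        )

    def modes(self) -> tuple[float, float]:
        """(alpha mode, beta mode) of the priors."""
        a, b = self.alpha_a, self.alpha_b
        return (a - 1) / (a + b - 2), (self.beta_shape - 1) * self.beta_scale


DEFAULT_PRIOR = PriorSpec()
RT_PLACEHOLDER = 0.5  # no response-time model; constant placeholder (s)


def _params_for(params, cond: str) -> AgentParams:
    if isinstance(params, dict):
        return params[cond]
    return params


def simulate_agent(schedule: TaskSchedule, params, seed,
                   subject_id: int = 0, miss_rate: float = 0.0) -> pd.DataFrame:
    """Simulate one subject's 240 trials on a schedule.

    ``params`` is an :class:`AgentParams` or a dict keyed by condition
    (reward_mixed, reward_only, punishment_mixed, punishment_only) for
    condition-specific parameters. Choices follow the softmax of the
    replayed Q values; outcomes are drawn from the schedule's Bernoulli
    probabilities. ``miss_rate`` marks trials invalid at random (missed
    trials carry no choice or outcome and do not update values).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    trials = schedule.trials.copy()
    trials["condition"] = [
        condition_of(v, c) for v, c in zip(trials["valence"], trials["context"])
    ]
    trials["valid"] = True
    if miss_rate > 0:
        trials["valid"] = rng.random(len(trials)) >= miss_rate
    trials["choice"] = pd.NA
    trials["outcome"] = np.nan

    for cond in CONDITIONS:
        sel = (trials["condition"] == cond) & trials["valid"]
        if not sel.any():
            continue
        sub = trials[sel]
        p = _params_for(params, cond)
        pairs = pd.unique(sub["pair"])
        pair_map = {pr: i for i, pr in enumerate(pairs)}
        pair_idx = sub["pair"].map(pair_map).to_numpy(dtype=np.int64)
        valence = sub.drop_duplicates("pair").set_index("pair")["valence"]
        q0 = np.array([p.q0_for(valence[pr]) for pr in pairs])
        is_reward = (sub["valence"] == "reward").to_numpy(dtype=np.int8)
        n = len(sub)
        chosen_good, outcome = _kernels.simulate_stream(
            pair_idx, is_reward, len(pairs), q0, schedule.outcome_prob_good,
            p.alpha_pos, p.alpha_neg, p.beta, p.rho,
            rng.random(n), rng.random(n),
        )
        trials.loc[sel, "choice"] = np.where(chosen_good == 1, "good", "bad")
        trials.loc[sel, "outcome"] = outcome

    trials.insert(0, "subject", subject_id)
    trials["rt"] = np.where(trials["valid"], RT_PLACEHOLDER, np.nan)
    return trials[["subject", "block", "context", "pair", "valence", "trial",
                   "trial_in_pair", "choice", "outcome", "rt", "valid", "condition"]]


def simulate_population(schedule: TaskSchedule | None, params_list=None,
                        prior: PriorSpec | None = None, n_subjects: int | None = None,
                        seed=0, study_version: str = "behavioral",
                        miss_rate: float = 0.0):
    """Simulate a cohort; returns ``(dataset, truth)``.

    Either pass explicit per-subject parameters (``params_list``: each an
    :class:`AgentParams` or a condition-keyed dict) or a :class:`PriorSpec`
    plus ``n_subjects`` to draw them. With ``schedule=None`` each subject
    gets a fresh schedule with the counterbalance order cycling over
    subjects, as in a counterbalanced cohort.
    """
    if params_list is None:
        if n_subjects is None or n_subjects < 1:
            raise ValueError("n_subjects must be >= 1 when drawing from a prior")
        prior = prior or DEFAULT_PRIOR
    else:
        n_subjects = len(params_list)
        if n_subjects < 1:
            raise ValueError("params_list is empty")

    root = np.random.SeedSequence(seed)
    children = root.spawn(n_subjects)
    datasets, truth_rows = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        if params_list is None:
            params = prior.draw(rng)
        else:
            params = params_list[i]
        sched = schedule if schedule is not None else make_schedule(
            study_version, counterbalance_index=i % 6, seed=rng
        )
        datasets.append(simulate_agent(sched, params, rng, subject_id=i,
                                       miss_rate=miss_rate))
        for cond in CONDITIONS:
            p = _params_for(params, cond)
            truth_rows.append({
                "subject": i, "condition": cond, "alpha_pos": p.alpha_pos,
                "alpha_neg": p.alpha_neg, "beta": p.beta, "rho": p.rho,
            })
    dataset = pd.concat(datasets, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return dataset, truth


# --- synthetic BOLD ----------------------------------------------------------

def simulate_bold(dataset: pd.DataFrame, spec: bold.SyntheticBoldSpec | None = None,
                  seed=0, roi: str = "caudate", mode: str = "count") -> bold.RoiTimeSeries:
    """Event-related ROI traces for mixed-block reward trials.

    Each trial's trace is ``amplitude * h(t) + noise`` in percent signal
    change, with ``h`` the double-gamma response (unit 6 s value) and
    ``amplitude = baseline_amp + history_gain * level`` where ``level`` is
    the 0-based punishment-history bin (count bins by default, recency
    tertiles with ``mode="recency"``). Trials without a defined bin (no
    punishment since the last reward, in recency mode) are dropped.
    """
    spec = spec or bold.SyntheticBoldSpec()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hist = bold.punishment_history(dataset)
    if mode == "count":
        levels = hist["count_bin"].to_numpy(dtype=float)
    elif mode == "recency":
        hist = hist[hist["recency_bin"].notna()]
        levels = hist["recency_bin"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    if hist.empty:
        raise ValueError("no trials with defined history bins")
    times = spec.times
    h = bold.double_gamma_hrf(times, spec.hrf_peak_shape, spec.hrf_under_shape,
                              spec.hrf_under_ratio)
    amp = spec.baseline_amp + spec.history_gain * (levels - 1.0)
    data = amp[:, None] * h[None, :]
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    return bold.RoiTimeSeries(roi=roi, times=times, data=data,
                              meta=hist.reset_index(drop=True))


# --- synthetic meta-analysis corpora ----------------------------------------

@dataclass
class SyntheticFociSpec:
    """Study-level foci generator emulating a two-category corpus.

    Defaults mirror a 16 mixed-context / 9 reward-only corpus with ~8 foci
    and ~28 participants per study (about 204 coordinate sets over 706
    participants in total). ``cluster_categories`` lists the categories
    whose studies plant one focus near ``cluster_center`` (Gaussian spread
    ``cluster_sd_mm``); remaining foci are uniform within the mask.
    """

    n_studies: dict = field(default_factory=lambda: {"reward_mixed": 16, "reward_only": 9})
    foci_per_study_mean: float = 8.2
    n_participants_mean: float = 28.0
    cluster_center: tuple = (6.0, 6.0, 2.0)
    cluster_sd_mm: float = 3.0
    cluster_categories: tuple = ("reward_mixed",)


def simulate_foci(spec: SyntheticFociSpec, grid: mkda.Grid, mask: np.ndarray,
                  seed=0) -> list[mkda.FociStudy]:
    """Draw per-study coordinate sets; planted-cluster studies place one
    focus near the cluster center, everything else is uniform in the mask."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    center_vox = grid.mm_to_vox(spec.cluster_center)[0]
    if not mask[tuple(np.clip(center_vox, 0, np.array(grid.shape) - 1))]:
        raise ValueError("cluster center lies outside the mask")
    mask_mm = grid.vox_to_mm(np.argwhere(mask))
    studies = []
    for category, n_stud in spec.n_studies.items():
        for j in range(n_stud):
            n_foci = max(1, int(rng.poisson(spec.foci_per_study_mean)))
            idx = rng.integers(0, len(mask_mm), size=n_foci)
            foci = mask_mm[idx].copy()
            if category in spec.cluster_categories:
                focus = np.asarray(spec.cluster_center, dtype=float)
                if spec.cluster_sd_mm > 0:
                    focus = focus + rng.normal(0, spec.cluster_sd_mm, size=3)
                    vox = np.clip(grid.mm_to_vox(focus)[0], 0, np.array(grid.shape) - 1)
                    if not mask[tuple(vox)]:
                        focus = np.asarray(spec.cluster_center, dtype=float)
                foci[0] = focus
            n_part = max(5, int(rng.poisson(spec.n_participants_mean)))
            studies.append(mkda.FociStudy(f"{category}_{j:02d}", category, foci, n_part))
    return studies
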