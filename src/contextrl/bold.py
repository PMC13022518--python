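"""ROI BOLD time-series analyses of prediction errors and punishment history.

Event-related epochs are cut from 2 volumes before to 8 volumes after
outcome onset (TR 2 s, 11 volumes, times -4..+16 s), normalized to the
pre-outcome baseline window (-4 to 0 s) and expressed as percent signal
change. Reward trials in mixed blocks are grouped by punishment history in
two ways: the number of punishments since the last reward delivery within
the block (bins 0 / 1 / 2+), and the recency of the most recent punishment
(per-subject tertiles of trials elapsed, reset after each reward). The
parametric effect of history is measured either as the 6 s post-outcome
amplitude or as the 0-to-6 s ramp, with a per-subject linear slope across
the three bin levels and a one-tailed group t test on the slopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class SyntheticBoldSpec:
    """Generator settings for synthetic event-related ROI traces.

    The 6 s amplitude of each trial is ``baseline_amp + history_gain *
    level + N(0, noise_sd)`` where ``level`` is the 0-based history bin
    (0, 1, 2), so the per-subject slope across bins equals ``history_gain``
    exactly when ``noise_sd`` is 0. Units are percent signal change.
    """

    tr: float = 2.0
    n_pre: int = 2
    n_post: int = 8
    baseline_window: tuple = (-4.0, 0.0)
    baseline_amp: float = 0.5
    history_gain: float = 0.1
    noise_sd: float = 0.05
    hrf_peak_shape: float = 7.0
    hrf_under_shape: float = 17.0
    hrf_under_ratio: float = 1.0 / 6.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(-self.n_pre, self.n_post + 1) * self.tr


def double_gamma_hrf(t, peak_shape=7.0, under_shape=17.0, under_ratio=1.0 / 6.0):
    """Double-gamma hemodynamic response, zero before onset, unit 6 s value.

    With shape 7 / scale 1 the response peaks exactly at 6 s, matching the
    canonical BOLD peak on a TR = 2 s grid.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak_shape) - under_ratio * stats.gamma.pdf(t, under_shape)
    h = np.where(t <= 0, 0.0, h)
    ref = stats.gamma.pdf(6.0, peak_shape) - under_ratio * stats.gamma.pdf(6.0, under_shape)
    return h / ref


@dataclass
class RoiTimeSeries:
    """Trial x volume matrix of (percent-signal-change) BOLD for one ROI."""

    roi: str
    times: np.ndarray
    data: np.ndarray                       # (n_trials, n_volumes)
    meta: pd.DataFrame = field(repr=False)  # one row per trial

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def at_time(self, t: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 1e-9:
            raise ValueError(f"time {t} not on the volume grid")
        return self.data[:, idx]


# --- epoching ----------------------------------------------------------------

def epoch_and_normalize(raw, onsets, spec: SyntheticBoldSpec | None = None):
    """Cut per-trial epochs from a continuous ROI series and convert to PSC.

    ``onsets`` are volume indices of outcome onset. Each epoch spans
    ``-n_pre..+n_post`` volumes; the mean over the baseline window is
    subtracted and the epoch is scaled to percent change relative to that
    mean. Epochs running past the series bounds are dropped (logged).
    Returns ``(epochs, kept)`` with ``kept`` the onsets actually used.
    """
    spec = spec or SyntheticBoldSpec()
    raw = np.asarray(raw, dtype=float)
    times = spec.times
    base_mask = (times >= spec.baseline_window[0]) & (times <= spec.baseline_window[1])
    epochs, kept = [], []
    n_dropped = 0
    for onset in onsets:
        lo, hi = onset - spec.n_pre, onset + spec.n_post
        if lo < 0 or hi >= len(raw):
            n_dropped += 1
            continue
        ep = raw[lo:hi + 1]
        b = ep[base_mask].mean()
        if b == 0:
            raise ValueError("baseline mean is zero; cannot form percent signal change")
        epochs.append(100.0 * (ep - b) / b)
        kept.append(onset)
    if n_dropped:
        log.info("epoch_and_normalize: dropped %d out-of-bounds trials", n_dropped)
    return np.array(epochs).reshape(len(kept), len(times)), np.asarray(kept)


# --- punishment history labelling -------------------------------------------

def _tertile_sizes(n: int):
    base, extra = divmod(n, 3)
    return [base + (1 if i < extra else 0) for i in range(3)]


def tertile_labels(values: np.ndarray, ascending: bool = True) -> np.ndarray:
    """Equal-count (±1) tertile labels 1..3, ties broken by input order.

    Label 1 holds the smallest values when ``ascending``. Earlier bins take
    the extra items when the count is not divisible by 3.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 values for tertiles")
    order = np.argsort(values, kind="stable")
    if not ascending:
        order = np.argsort(-values, kind="stable")
    labels = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(_tertile_sizes(n), start=1):
        labels[order[start:start + size]] = b
        start += size
    return labels


def punishment_history(dataset: pd.DataFrame) -> pd.DataFrame:
    """Label mixed-block reward trials with punishment-history measures.

    For each subject and mixed block, trials are scanned chronologically.
    A counter of punishment deliveries (outcome -1) accumulates and is
    reset whenever a reward is delivered (outcome +1). At every valid
    reward-pair trial the counter value is recorded as
    ``prior_punishments`` (bin levels 1/2/3 for counts 0/1/2+) together
    with ``trials_since_punishment`` (NaN when no punishment occurred since
    the last reward; such trials carry no recency bin). Recency tertiles
    are formed per subject across mixed blocks, with level 3 = most recent.
    """
    rows = []
    mixed = dataset[dataset["context"] == "mixed"]
    for (subject, block), blk in mixed.groupby(["subject", "block"], sort=True):
        blk = blk.sort_values("trial")
        count = 0
        last_punish = None
        for _, tr in blk.iterrows():
            if not bool(tr.get("valid", True)):
                continue
            if tr["valence"] == "reward":
                recency = np.nan if last_punish is None else tr["trial"] - last_punish
                rows.append({
                    "subject": subject, "block": block, "pair": tr["pair"],
                    "trial": tr["trial"], "choice": tr["choice"],
                    "outcome": tr["outcome"],
                    "prior_punishments": count,
                    "count_bin": min(count, 2) + 1,
                    "trials_since_punishment": recency,
                })
            if tr["outcome"] == 1:
                count = 0
                last_punish = None
            elif tr["outcome"] == -1:
                count += 1
                last_punish = tr["trial"]
    hist = pd.DataFrame(rows)
    if hist.empty:
        raise ValueError("dataset contains no valid reward trials in mixed blocks")
    hist["recency_bin"] = np.nan
    for subject, grp in hist.groupby("subject"):
        mask = grp["trials_since_punishment"].notna()
        if mask.sum() >= 3:
            labels = tertile_labels(
                grp.loc[mask, "trials_since_punishment"].to_numpy(), ascending=False
            )
            hist.loc[grp.index[mask], "recency_bin"] = labels
    return hist


def bin_pe_tertiles(pe_df: pd.DataFrame, by=("subject", "condition"),
                    col: str = "pe"):
    """Split signed PEs into low/medium/high tertiles per subject x condition.

    Returns ``(labels, bin_means)``: integer labels 1..3 aligned with
    ``pe_df`` and a table of per-bin mean PE (for checking that bin
    magnitudes are matched across contexts). Groups with fewer than three
    trials raise.
    """
    labels = pd.Series(index=pe_df.index, dtype=float)
    for _, grp in pe_df.groupby(list(by)):
        if len(grp) < 3:
            raise ValueError("need at least 3 trials per group for tertiles")
        labels.loc[grp.index] = tertile_labels(grp[col].to_numpy())
    labels = labels.astype(int)
    means = (
        pe_df.assign(pe_bin=labels)
        .groupby([*by, "pe_bin"])[col].mean()
        .rename("mean_pe").reset_index()
    )
    return labels, means


# --- parametric history effect ----------------------------------------------

@dataclass
class SlopeTestResult:
    measure: str
    bin_col: str
    slopes: pd.DataFrame      # subject, slope, n_bins
    t: float
    df: int
    p: float
    cohen_d: float
    n_excluded: int


def trial_measure(ts: RoiTimeSeries, measure: str) -> np.ndarray:
    """Per-trial scalar: 6 s amplitude or the 0-to-6 s ramp."""
    if measure == "peak6s":
        return ts.at_time(6.0)
    if measure == "ramp0to6":
        return ts.at_time(6.0) - ts.at_time(0.0)
    raise ValueError(f"unknown measure: {measure!r}")


def history_slope_test(ts: RoiTimeSeries, bin_col: str = "count_bin",
                       measure: str = "peak6s",
                       alternative: str = "greater") -> SlopeTestResult:
    """Per-subject slope of the history effect and a one-tailed group t test.

    For every subject, the trial measure is averaged within each history
    bin (levels 1..3) and an OLS slope across the available levels is
    fitted; subjects with fewer than two non-empty bins are excluded
    (logged). The group test is a one-sample t of the slopes against zero,
    one-tailed (positive) by default.
    """
    vals = trial_measure(ts, measure)
    meta = ts.meta.assign(_y=vals)
    meta = meta[meta[bin_col].notna()]
    slopes = []
    n_excluded = 0
    for subject, grp in meta.groupby("subject"):
        means = grp.groupby(bin_col)["_y"].mean()
        if len(means) < 2:
            n_excluded += 1
            continue
        x = means.index.to_numpy(dtype=float)
        slope = np.polyfit(x, means.to_numpy(), 1)[0]
        slopes.append({"subject": subject, "slope": slope, "n_bins": len(means)})
    if n_excluded:
        log.info("history_slope_test: excluded %d subjects with <2 bins", n_excluded)
    slopes = pd.DataFrame(slopes)
    s = slopes["slope"].to_numpy()
    res = stats.ttest_1samp(s, 0.0, alternative=alternative)
    d = float(np.mean(s) / np.std(s, ddof=1)) if len(s) > 1 else np.nan
    return SlopeTestResult(measure, bin_col, slopes, float(res.statistic),
                           len(s) - 1, float(res.pvalue), d, n_excluded)
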