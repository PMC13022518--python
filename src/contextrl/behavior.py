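"""Behavioral statistics: accuracy, stay/switch, latency, ANOVA, regressions.

Accuracy is the proportion of choices of the high-probability-reward (or
low-probability-loss) option, over valid trials. Positive feedback means a
win or an avoided loss (outcome 0 on a punishment pair); negative feedback
means reward omission or a delivered loss. The 2 (context: mixed vs only)
x 2 (valence: reward vs punishment) within-subject ANOVA is computed by
difference-score decomposition, with paired t contrasts, Bonferroni
adjustment, and Cohen's d for post hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task import CONDITIONS


def _valid(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["valid"].astype(bool)] if "valid" in df.columns else df


def _positive_feedback(valence, outcome):
    return ((valence == "reward") & (outcome == 1)) | (
        (valence == "punishment") & (outcome == 0))


def summarize_conditions(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition summary over valid trials.

    Columns: ``accuracy``, ``stay_after_positive``, ``switch_after_negative``,
    ``stay_switch_index`` (mean of the two proportions), ``mean_rt``, and
    ``learning_slope`` (linear regression of the correct-choice flag on the
    within-pair trial index). A subject x condition cell without valid
    trials raises.
    """
    df = _valid(dataset).copy()
    df["correct"] = (df["choice"] == "good").astype(float)
    rows = []
    for (subject, cond), grp in df.groupby(["subject", "condition"], sort=True):
        if len(grp) == 0:
            raise ValueError(f"no valid trials for subject {subject}, {cond}")
        stays_pos, stays_neg = [], []
        for _, pg in grp.groupby("pair"):
            pg = pg.sort_values("trial")
            pos = _positive_feedback(pg["valence"], pg["outcome"]).to_numpy()
            ch = pg["choice"].to_numpy()
            stay = ch[1:] == ch[:-1]
            stays_pos.extend(stay[pos[:-1]])
            stays_neg.extend(stay[~pos[:-1]])
        slope = np.nan
        if grp["trial_in_pair"].nunique() > 1:
            slope = np.polyfit(grp["trial_in_pair"], grp["correct"], 1)[0]
        sap = float(np.mean(stays_pos)) if stays_pos else np.nan
        swn = float(1.0 - np.mean(stays_neg)) if stays_neg else np.nan
        rows.append({
            "subject": subject, "condition": cond,
            "accuracy": grp["correct"].mean(),
            "stay_after_positive": sap,
            "switch_after_negative": swn,
            "stay_switch_index": np.nanmean([sap, swn]),
            "mean_rt": grp["rt"].mean(),
            "learning_slope": slope,
        })
    return pd.DataFrame(rows)


def condition_wide(summary: pd.DataFrame, value: str = "accuracy") -> pd.DataFrame:
    """Pivot a per subject x condition summary to subjects x 4 conditions."""
    wide = summary.pivot(index="subject", columns="condition", values=value)
    missing = set(CONDITIONS) - set(wide.columns)
    if missing:
        raise ValueError(f"missing conditions: {missing}")
    return wide[list(CONDITIONS)]


# --- repeated-measures ANOVA -------------------------------------------------

@dataclass
class EffectResult:
    name: str
    F: float
    df1: int
    df2: int
    p: float
    eta_sq: float          # classical: SS_effect / SS_total
    eta_sq_partial: float
    zero_variance: bool = False


@dataclass
class AnovaResult:
    context: EffectResult
    valence: EffectResult
    interaction: EffectResult
    n: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in
                             (self.context, self.valence, self.interaction)])


def rm_anova_2x2(wide: pd.DataFrame) -> AnovaResult:
    """2x2 within-subject ANOVA on a subjects x 4 conditions table.

    Columns must be (reward_mixed, reward_only, punishment_mixed,
    punishment_only). Each effect has 1 and n-1 degrees of freedom; with a
    zero-variance difference score the F is reported infinite with p = 0
    and flagged. Classical eta-squared (SS_effect over total SS including
    the subject source) is the headline effect size; partial eta-squared is
    also reported.
    """
    y = wide[list(CONDITIONS)].to_numpy(dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(y).any():
        raise ValueError("complete cases required (no missing cells)")
    rm, ro, pm, po = y.T
    grand = y.mean()
    # cell means layout: context (mixed, only) x valence (reward, punishment)
    cells = {("mixed", "reward"): rm, ("mixed", "punishment"): pm,
             ("only", "reward"): ro, ("only", "punishment"): po}
    subj_mean = y.mean(axis=1)
    ss_total = ((y - grand) ** 2).sum()

    ctx_means = {c: np.mean([cells[(c, v)].mean() for v in ("reward", "punishment")])
                 for c in ("mixed", "only")}
    val_means = {v: np.mean([cells[(c, v)].mean() for c in ("mixed", "only")])
                 for v in ("reward", "punishment")}
    ss_ctx = 2 * n * sum((m - grand) ** 2 for m in ctx_means.values())
    ss_val = 2 * n * sum((m - grand) ** 2 for m in val_means.values())
    ss_int = n * sum(
        (cells[(c, v)].mean() - ctx_means[c] - val_means[v] + grand) ** 2
        for c in ("mixed", "only") for v in ("reward", "punishment"))

    # effect-by-subject error terms via difference scores
    d_ctx = (rm + pm - ro - po) / 2.0
    d_val = (rm + ro - pm - po) / 2.0
    d_int = (rm - ro) - (pm - po)
    results = []
    for name, d, ss_eff, scale in (("context", d_ctx, ss_ctx, 1.0),
                                   ("valence", d_val, ss_val, 1.0),
                                   ("interaction", d_int, ss_int, 2.0)):
        # effect-by-subject SS equals the contrast SS on the cell-mean
        # scale (mains: contrast/1; interaction: contrast/2)
        ss_err = np.sum((d - d.mean()) ** 2) / scale**2
        var_d = np.var(d, ddof=1)
        zero_var = var_d == 0
        if zero_var:
            F = np.inf if ss_eff > 0 else 0.0
            p = 0.0 if ss_eff > 0 else 1.0
        else:
            t = d.mean() / np.sqrt(var_d / n)
            F = t ** 2
            p = 2.0 * stats.t.sf(abs(t), n - 1)
        results.append(EffectResult(
            name, float(F), 1, n - 1, float(p),
            float(ss_eff / ss_total) if ss_total > 0 else 0.0,
            float(ss_eff / (ss_eff + ss_err)) if (ss_eff + ss_err) > 0 else 0.0,
            zero_var))
    return AnovaResult(*results, n=n)


@dataclass
class PairedContrast:
    name: str
    t: float
    df: int
    p: float
    p_bonferroni: float
    cohen_d: float


def paired_contrast(x, y, name: str = "", m: int = 1,
                    one_tailed: bool = False) -> PairedContrast:
    """Paired t test with Bonferroni adjustment (family size m) and Cohen's d.

    Cohen's d is mean(diff) / sd(diff). ``one_tailed`` tests x > y.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    res = stats.ttest_1samp(d, 0.0, alternative="greater" if one_tailed else "two-sided")
    cd = float(d.mean() / d.std(ddof=1))
    p = float(res.pvalue)
    return PairedContrast(name, float(res.statistic), n - 1, p,
                          min(1.0, m * p), cd)


# --- parameter-based analyses ------------------------------------------------

def composite_index(fit_table: pd.DataFrame) -> pd.DataFrame:
    """Learning-rate x inverse-temperature products per subject x condition.

    The products alpha+ x beta and alpha- x beta are more reliably
    estimated than the individual parameters when the two trade off.
    """
    out = fit_table.copy()
    out["alpha_pos_x_beta"] = out["alpha_pos"] * out["beta"]
    out["alpha_neg_x_beta"] = out["alpha_neg"] * out["beta"]
    return out


def accuracy_on_params_regression(accuracy: pd.Series, fit_table: pd.DataFrame,
                                  condition: str,
                                  predictors=("alpha_pos", "alpha_neg", "beta"),
                                  cond_threshold: float = 1e8) -> pd.DataFrame:
    """OLS of mean accuracy on fitted parameters for one condition.

    ``accuracy`` is indexed by subject. Returns the coefficient table with
    standard errors and p-values; a ``collinear`` flag marks an
    ill-conditioned design (duplicated or degenerate predictors).
    """
    import statsmodels.api as sm

    sub = fit_table[fit_table["condition"] == condition].set_index("subject")
    X = sub[list(predictors)].loc[accuracy.index]
    model = sm.OLS(accuracy.to_numpy(dtype=float), sm.add_constant(X.to_numpy()))
    res = model.fit()
    names = ["intercept", *predictors]
    out = pd.DataFrame({
        "term": names, "coef": res.params, "se": res.bse,
        "t": res.tvalues, "p": res.pvalues,
    })
    out.attrs["condition_number"] = float(res.condition_number)
    out.attrs["collinear"] = bool(res.condition_number > cond_threshold
                                  or np.linalg.matrix_rank(X.to_numpy()) < X.shape[1])
    return out


# --- screening filter --------------------------------------------------------

def poor_learning_subjects(dataset: pd.DataFrame,
                           early_window: int = 10,
                           early_floor: float = 0.40) -> list:
    """Subjects meeting the prespecified poor-learning exclusion criteria.

    A subject is flagged when accuracy is below chance in every block, or
    below ``early_floor`` within the first ``early_window`` trials of every
    block.
    """
    df = _valid(dataset).copy()
    df["correct"] = (df["choice"] == "good").astype(float)
    flagged = []
    for subject, grp in df.groupby("subject"):
        block_acc = grp.groupby("block")["correct"].mean()
        early = grp[grp.groupby(["block"])["trial"].rank(method="first") <= early_window]
        early_acc = early.groupby("block")["correct"].mean()
        if (block_acc < 0.5).all() or (early_acc < early_floor).all():
            flagged.append(subject)
    return flagged


def glme_export(dataset: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-trial table for external mixed-model software.

    Columns: subject, block (1 or 2 within context), context, valence,
    trial, correct -- the variables of a logistic mixed model of
    trial-by-trial choice.
    """
    df = _valid(dataset).copy()
    df["correct"] = (df["choice"] == "good").astype(int)
    df["context_bin"] = (df["context"] == "mixed").astype(int)
    df["valence_bin"] = (df["valence"] == "reward").astype(int)
    rep = (df.drop_duplicates(["subject", "context", "block"])
             .sort_values("block")
             .groupby(["subject", "context"]).cumcount() + 1)
    rep_map = df.drop_duplicates(["subject", "context", "block"]).assign(rep=rep.values)
    df = df.merge(rep_map[["subject", "context", "block", "rep"]],
                  on=["subject", "context", "block"])
    return df[["subject", "block", "rep", "context", "context_bin",
               "valence", "valence_bin", "trial", "trial_in_pair", "correct"]]
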