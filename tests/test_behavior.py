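"""Behavioral summaries, repeated-measures ANOVA, and parameter regressions."""

import numpy as np
import pandas as pd
import pytest

from contextrl import AgentParams
from contextrl.behavior import accuracy_on_params_regression, composite_index, \
    condition_wide, glme_export, paired_contrast, poor_learning_subjects, \
    rm_anova_2x2, summarize_conditions
from contextrl.synth import simulate_agent
from contextrl.task import CONDITIONS


def _mini_dataset(choices, outcomes, valence="reward", context="mixed",
                  pair=0, subject=0):
    n = len(choices)
    cond = f"{valence}_mixed" if context == "mixed" else f"{valence}_only"
    return pd.DataFrame({
        "subject": subject, "block": 1, "context": context, "pair": pair,
        "valence": valence, "trial": range(1, n + 1),
        "trial_in_pair": range(1, n + 1), "choice": choices,
        "outcome": outcomes, "rt": 0.5, "valid": True, "condition": cond,
    })


def test_all_correct_subject_scores_one(schedule):
    frames = []
    for cond, (val, ctx) in {
        "reward_mixed": ("reward", "mixed"),
        "reward_only": ("reward", "reward_only"),
        "punishment_mixed": ("punishment", "mixed"),
        "punishment_only": ("punishment", "punishment_only"),
    }.items():
        out = 1.0 if val == "reward" else 0.0
        frames.append(_mini_dataset(["good"] * 6, [out] * 6, val, ctx,
                                    pair=hash(cond) % 100))
    summary = summarize_conditions(pd.concat(frames, ignore_index=True))
    assert (summary["accuracy"] == 1.0).all()


def test_win_stay_lose_shift_agent_has_unit_stay_switch():
    # feedback: win, win, loss-of-reward (0), win -> stays after wins,
    # switches after the omission
    choices = ["good", "good", "good", "bad", "bad"]
    outcomes = [1.0, 1.0, 0.0, 0.0, 1.0]
    # after outcome 0 at t3 the agent switched; after wins it stayed;
    # after t4's 0 (negative) it stayed -> craft strictly WSLS:
    choices = ["good", "good", "good", "bad", "bad"]
    outcomes = [1.0, 1.0, 0.0, 1.0, 1.0]
    d = _mini_dataset(choices, outcomes)
    s = summarize_conditions(d).iloc[0]
    assert s["stay_after_positive"] == 1.0
    assert s["switch_after_negative"] == 1.0
    assert s["stay_switch_index"] == 1.0


def test_avoided_loss_counts_as_positive_feedback():
    choices = ["good", "good", "bad"]
    outcomes = [0.0, -1.0, 0.0]   # avoided, loss, avoided
    d = _mini_dataset(choices, outcomes, valence="punishment")
    s = summarize_conditions(d).iloc[0]
    assert s["stay_after_positive"] == 1.0     # stayed after the avoided loss
    assert s["switch_after_negative"] == 1.0   # switched after the loss


def test_zero_beta_population_accuracy_at_chance(beta0_cohort):
    dataset, _ = beta0_cohort
    summary = summarize_conditions(dataset)
    acc = summary["accuracy"].to_numpy()
    se = acc.std(ddof=1) / np.sqrt(len(acc))
    assert abs(acc.mean() - 0.5) < 3 * se + 1e-12


def test_accuracy_matches_independent_one_pass(small_cohort):
    dataset, _ = small_cohort
    summary = summarize_conditions(dataset).set_index(["subject", "condition"])
    # independent recomputation: single vectorized pass
    df = dataset[dataset["valid"]]
    check = (df.assign(c=(df["choice"] == "good").astype(float))
             .groupby(["subject", "condition"])["c"].mean())
    for key, expected in check.items():
        assert summary.loc[key, "accuracy"] == pytest.approx(expected)


def test_learning_slope_positive_for_learners(schedule):
    d = simulate_agent(schedule, AgentParams(0.5, 0.5, 10.0), seed=5)
    s = summarize_conditions(d)
    assert (s["learning_slope"] > 0).mean() >= 0.75


# --- ANOVA -------------------------------------------------------------------

def _wide(data):
    return pd.DataFrame(data, columns=list(CONDITIONS))


def test_anova_identical_conditions_gives_zero_f():
    y = np.tile(np.array([[0.7, 0.7, 0.7, 0.7]]), (6, 1)) \
        + np.arange(6)[:, None] * 0.01
    res = rm_anova_2x2(_wide(y))
    for eff in (res.context, res.valence, res.interaction):
        assert eff.F == 0.0 and eff.p == 1.0


def test_anova_matches_hand_worked_oracle():
    """Five-subject table; F and p frozen from an independent
    difference-score calculation (cross-checked against pingouin)."""
    y = _wide(np.array([
        [0.90, 0.75, 0.70, 0.72],
        [0.80, 0.70, 0.65, 0.68],
        [0.85, 0.80, 0.75, 0.74],
        [0.70, 0.60, 0.55, 0.62],
        [0.95, 0.85, 0.80, 0.78],
    ]))
    res = rm_anova_2x2(y)
    assert res.context.F == pytest.approx(18.9943502825, rel=1e-9)
    assert res.context.p == pytest.approx(0.0120786775, rel=1e-7)
    assert res.valence.F == pytest.approx(93.5706214689, rel=1e-9)
    assert res.valence.p == pytest.approx(0.0006390671, rel=1e-6)
    assert res.interaction.F == pytest.approx(21.2905198777, rel=1e-9)
    assert res.interaction.p == pytest.approx(0.0099245160, rel=1e-7)
    assert (res.context.df1, res.context.df2) == (1, 4)
    for eff in (res.context, res.valence, res.interaction):
        assert 0 <= eff.eta_sq <= eff.eta_sq_partial <= 1


def test_anova_agrees_with_pingouin_on_random_data(rng):
    pg = pytest.importorskip("pingouin")
    y = rng.normal(0.7, 0.1, size=(12, 4))
    res = rm_anova_2x2(_wide(y))
    long = (_wide(y).reset_index().melt(id_vars="index", var_name="cond",
                                        value_name="y"))
    long["context"] = np.where(long["cond"].str.contains("mixed"), "mixed", "only")
    long["valence"] = np.where(long["cond"].str.contains("reward"),
                               "reward", "punishment")
    ref = pg.rm_anova(data=long, dv="y", within=["context", "valence"],
                      subject="index", detailed=True).set_index("Source")
    assert res.context.F == pytest.approx(ref.loc["context", "F"], rel=1e-6)
    assert res.valence.F == pytest.approx(ref.loc["valence", "F"], rel=1e-6)
    assert res.interaction.F == pytest.approx(
        ref.loc["context * valence", "F"], rel=1e-6)


def test_anova_zero_variance_contrast_flags_infinite_f():
    # dyadic values keep the per-subject contrast exactly constant
    base = np.random.default_rng(0).integers(8, 15, size=(8, 1)) / 16.0
    y = np.hstack([base + 0.125, base, base + 0.0625, base - 0.0625])
    res = rm_anova_2x2(_wide(y))
    assert np.isinf(res.context.F) and res.context.p == 0.0
    assert res.context.zero_variance


def test_anova_interaction_only_simulation(rng):
    """A pure interaction offset drives the interaction F while the mains
    reject only at the nominal rate."""
    hits = {"context": 0, "valence": 0, "interaction": 0}
    n_sims = 100
    for _ in range(n_sims):
        y = rng.normal(0.7, 0.05, size=(20, 4))
        y[:, 0] += 0.04   # rm
        y[:, 3] += 0.04   # po
        y[:, 1] -= 0.04   # ro
        y[:, 2] -= 0.04   # pm
        res = rm_anova_2x2(_wide(y))
        for name, eff in (("context", res.context), ("valence", res.valence),
                          ("interaction", res.interaction)):
            hits[name] += eff.p < 0.05
    assert hits["interaction"] >= 90
    assert hits["context"] <= 15 and hits["valence"] <= 15


def test_anova_requires_minimum_subjects():
    with pytest.raises(ValueError, match="3 subjects"):
        rm_anova_2x2(_wide(np.full((2, 4), 0.5)))


def test_paired_contrast_properties(rng):
    x = rng.normal(0.7, 0.1, 30)
    y = x - 0.05 + rng.normal(0, 0.02, 30)
    two = paired_contrast(x, y, m=3)
    assert two.p_bonferroni == pytest.approx(min(1.0, 3 * two.p))
    assert two.p_bonferroni >= two.p
    one = paired_contrast(x, y, one_tailed=True)
    assert one.p == pytest.approx(two.p / 2, rel=1e-9)
    assert one.cohen_d == pytest.approx(np.mean(x - y) / np.std(x - y, ddof=1))


# --- parameter analyses ------------------------------------------------------

def test_composite_index_products():
    ft = pd.DataFrame({"subject": [0, 1], "condition": ["reward_mixed"] * 2,
                       "alpha_pos": [0.0, 0.5], "alpha_neg": [0.2, 0.4],
                       "beta": [7.0, 10.0]})
    out = composite_index(ft)
    assert list(out["alpha_pos_x_beta"]) == [0.0, 5.0]
    assert list(out["alpha_neg_x_beta"]) == pytest.approx([1.4, 4.0])
    # the product is invariant to a common scale trade-off
    c = 3.0
    assert 0.5 * c * (10.0 / c) == pytest.approx(5.0)


def test_regression_exact_linear_recovery(rng):
    n = 40
    ft = pd.DataFrame({
        "subject": range(n), "condition": "reward_mixed",
        "alpha_pos": rng.uniform(0, 1, n), "alpha_neg": rng.uniform(0, 1, n),
        "beta": rng.gamma(15, 0.75, n),
    })
    acc = pd.Series(0.5 + 0.2 * ft["alpha_pos"].to_numpy(),
                    index=ft["subject"])
    res = accuracy_on_params_regression(acc, ft, "reward_mixed")
    coef = res.set_index("term")["coef"]
    assert coef["alpha_pos"] == pytest.approx(0.2, abs=1e-8)
    assert coef["alpha_neg"] == pytest.approx(0.0, abs=1e-8)
    assert coef["beta"] == pytest.approx(0.0, abs=1e-8)
    assert not res.attrs["collinear"]


def test_regression_flags_duplicated_predictor(rng):
    n = 25
    ft = pd.DataFrame({
        "subject": range(n), "condition": "reward_only",
        "alpha_pos": rng.uniform(0, 1, n), "beta": rng.gamma(15, 0.75, n),
    })
    ft["alpha_neg"] = ft["alpha_pos"]
    acc = pd.Series(rng.uniform(0.4, 0.9, n), index=ft["subject"])
    res = accuracy_on_params_regression(acc, ft, "reward_only")
    assert res.attrs["collinear"]


def test_regression_type_one_error_near_nominal(rng):
    n = 40
    rejections = 0
    tests = 0
    for _ in range(200):
        ft = pd.DataFrame({
            "subject": range(n), "condition": "reward_mixed",
            "alpha_pos": rng.uniform(0, 1, n),
            "alpha_neg": rng.uniform(0, 1, n),
            "beta": rng.gamma(15, 0.75, n),
        })
        acc = pd.Series(rng.normal(0.7, 0.1, n), index=ft["subject"])
        res = accuracy_on_params_regression(acc, ft, "reward_mixed")
        ps = res.set_index("term")["p"]
        for term in ("alpha_pos", "alpha_neg", "beta"):
            tests += 1
            rejections += ps[term] < 0.05
    rate = rejections / tests
    assert 0.02 < rate < 0.09


# --- screening and export ----------------------------------------------------

def test_poor_learning_filter(schedule):
    good = simulate_agent(schedule, AgentParams(0.6, 0.6, 12.0), seed=1,
                          subject_id=0)
    bad = good.copy()
    bad["subject"] = 1
    bad["choice"] = np.where(bad["choice"] == "good", "bad", "good")
    flagged = poor_learning_subjects(pd.concat([good, bad]))
    assert flagged == [1]


def test_glme_export_variables(small_cohort):
    dataset, _ = small_cohort
    out = glme_export(dataset)
    assert set(out.columns) >= {"subject", "rep", "context_bin", "valence_bin",
                                "trial", "correct"}
    assert set(out["rep"]) == {1, 2}
    assert set(out["correct"]) <= {0, 1}


def test_condition_wide_requires_all_conditions(small_cohort):
    dataset, _ = small_cohort
    summary = summarize_conditions(dataset)
    wide = condition_wide(summary)
    assert wide.shape == (12, 4)
    with pytest.raises(ValueError, match="missing conditions"):
        condition_wide(summary[summary["condition"] != "reward_only"])
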