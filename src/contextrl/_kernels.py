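"""Numba inner loops for trial replay and agent simulation.

Everything here operates on flat arrays prepared by :mod:`contextrl.rl` and
:mod:`contextrl.synth`; no pandas inside. Gradients of the replay negative
log-likelihood are propagated forward through the value-update recursion,
which keeps optimizer calls cheap enough for multi-start fitting of
thousands of simulated subjects.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CLIP = 700.0
_PFLOOR = 1e-12


@njit(cache=False)
def replay_nll(pair_idx, chosen_good, outcome, q0, n_pairs,
               alpha_pos, alpha_neg, beta, rho):
    """Replay one condition stream; return (nll, pe, grad).

    ``pair_idx`` are 0-based contiguous pair indices, ``chosen_good`` is 1
    when the objectively better option was chosen, ``q0`` gives the shared
    initial value of both options of each pair. ``grad`` is d(nll)/d
    (alpha_pos, alpha_neg, beta, rho). Both options of a pair start at the
    same initial value, and only the chosen option's value is updated.
    """
    n = pair_idx.shape[0]
    qg = np.empty(n_pairs)
    qb = np.empty(n_pairs)
    # forward-mode partials of each option value wrt (a+, a-, rho)
    gg = np.zeros((n_pairs, 3))
    gb = np.zeros((n_pairs, 3))
    for p in range(n_pairs):
        qg[p] = q0[p]
        qb[p] = q0[p]

    nll = 0.0
    pe = np.empty(n)
    grad = np.zeros(4)  # d/d(alpha_pos, alpha_neg, beta, rho)
    for t in range(n):
        p = pair_idx[t]
        if chosen_good[t] == 1:
            qc, qu = qg[p], qb[p]
        else:
            qc, qu = qb[p], qg[p]
        delta_q = qc - qu
        x = beta * delta_q
        if x > _CLIP:
            x = _CLIP
        elif x < -_CLIP:
            x = -_CLIP
        prob = 1.0 / (1.0 + np.exp(-x))
        pclip = prob if prob > _PFLOOR else _PFLOOR
        nll -= np.log(pclip)
        # d(-log P)/dx = -(1 - P)
        one_m_p = 1.0 - prob
        grad[2] -= one_m_p * delta_q
        if chosen_good[t] == 1:
            dqc = gg[p]
            dqu = gb[p]
        else:
            dqc = gb[p]
            dqu = gg[p]
        grad[0] -= one_m_p * beta * (dqc[0] - dqu[0])
        grad[1] -= one_m_p * beta * (dqc[1] - dqu[1])
        grad[3] -= one_m_p * beta * (dqc[2] - dqu[2])

        r = outcome[t]
        delta = rho * r - qc
        pe[t] = delta
        if delta > 0.0:
            a = alpha_pos
            dqc[0] = (1.0 - a) * dqc[0] + delta
            dqc[1] = (1.0 - a) * dqc[1]
        elif delta < 0.0:
            a = alpha_neg
            dqc[0] = (1.0 - a) * dqc[0]
            dqc[1] = (1.0 - a) * dqc[1] + delta
        else:
            a = 0.0
        if delta != 0.0:
            dqc[2] = (1.0 - a) * dqc[2] + a * r
            qc_new = qc + a * delta
        else:
            qc_new = qc
        if chosen_good[t] == 1:
            qg[p] = qc_new
        else:
            qb[p] = qc_new
    return nll, pe, grad


@njit(cache=False)
def simulate_stream(pair_idx, is_reward, n_pairs, q0, p_good,
                    alpha_pos, alpha_neg, beta, rho, u_choice, u_outcome):
    """Simulate one agent over a trial stream; return (chosen_good, outcome).

    Choices are drawn from the softmax of the two option values; outcomes
    from the pair's Bernoulli schedule: the good option of a reward pair
    wins (+1) with probability ``p_good``, the good option of a punishment
    pair loses (-1) with probability ``1 - p_good``, and the bad options
    carry the reverse probabilities.
    """
    n = pair_idx.shape[0]
    qg = np.empty(n_pairs)
    qb = np.empty(n_pairs)
    for p in range(n_pairs):
        qg[p] = q0[p]
        qb[p] = q0[p]
    chosen_good = np.empty(n, dtype=np.int8)
    outcome = np.empty(n)
    for t in range(n):
        p = pair_idx[t]
        x = beta * (qg[p] - qb[p])
        if x > _CLIP:
            x = _CLIP
        elif x < -_CLIP:
            x = -_CLIP
        prob_good = 1.0 / (1.0 + np.exp(-x))
        cg = 1 if u_choice[t] < prob_good else 0
        chosen_good[t] = cg
        if is_reward[t] == 1:
            p_win = p_good if cg == 1 else 1.0 - p_good
            r = 1.0 if u_outcome[t] < p_win else 0.0
        else:
            p_loss = (1.0 - p_good) if cg == 1 else p_good
            r = -1.0 if u_outcome[t] < p_loss else 0.0
        outcome[t] = r
        qc = qg[p] if cg == 1 else qb[p]
        delta = rho * r - qc
        if delta > 0.0:
            qc += alpha_pos * delta
        elif delta < 0.0:
            qc += alpha_neg * delta
        if cg == 1:
            qg[p] = qc
        else:
            qb[p] = qc
    return chosen_good, outcome
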