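"""Inner loops for the hybrid-model recursion.

The likelihood and the agent simulation share one per-trial recursion
(value update, associability update, biased softmax).  Both are written as
plain Python functions and JIT-compiled with numba when it is available;
the uncompiled functions are kept importable so the two code paths can be
cross-checked.  No fastmath is enabled, so compiled and interpreted results
are bit-identical.
"""

from __future__ import annotations

import math

import numpy as np

PROB_FLOOR = 1e-12


def _loglik_py(
    stim,
    action,
    reward,
    conf,
    mod,
    n_stimuli,
    beta,
    play_bias,
    w_int,
    w_conf,
    w_mod,
    eta,
    uses_assoc,
    use_conf,
    use_mod,
    q_out,
    delta_out,
    assoc_out,
    alpha_out,
    p_play_out,
):
    """Log-likelihood of an observed choice sequence; fills latent arrays.

    Per-trial order: score the choice from the current Q, compute the
    prediction error, fold |delta| (capped at 1) into the stimulus's
    associability, and update Q with the learning rate built from that
    refreshed trace — so a surprising outcome amplifies its own update,
    which is what makes strong surprise weighting costly under
    probabilistic feedback.
    """
    n = stim.shape[0]
    q = np.zeros(n_stimuli)
    assoc = np.ones(n_stimuli)
    ll = 0.0
    for t in range(n):
        s = stim[t]
        v_play = play_bias + q[s]
        p_play = 1.0 / (1.0 + math.exp(-beta * v_play))
        p_play_out[t] = p_play
        p = p_play if action[t] == 1 else 1.0 - p_play
        if p < PROB_FLOOR:
            p = PROB_FLOOR
        ll += math.log(p)

        x = w_int
        if use_conf:
            x += w_conf * conf[t]
        if use_mod:
            x += w_mod * mod[t]
        kappa = 1.0 / (1.0 + math.exp(-x))
        alpha = kappa

        delta = reward[t] - q[s]
        if uses_assoc:
            abs_d = -delta if delta < 0.0 else delta
            assoc[s] = eta * abs_d + (1.0 - eta) * assoc[s]
            alpha = kappa * assoc[s]
            if alpha > 1.0:
                alpha = 1.0
        q_out[t] = q[s]
        delta_out[t] = delta
        assoc_out[t] = assoc[s]
        alpha_out[t] = alpha
        q[s] = q[s] + alpha * delta
    return ll


def _simulate_py(
    stim,
    reward,
    uniforms,
    n_stimuli,
    beta,
    play_bias,
    w_int,
    w_conf,
    w_mod,
    eta,
    uses_assoc,
    use_conf,
    use_mod,
    action_out,
    conf_out,
    mod_out,
    q_out,
    delta_out,
    assoc_out,
    alpha_out,
    p_play_out,
):
    """Simulate choices on a schedule with pre-drawn outcome valences.

    ``reward`` is the fictive/factual reward signal in {+1,-1}; it is the
    same draw whether the agent plays or passes, so counterfactual feedback
    is simply the other view of it.  Returns the total reward signal summed
    over play trials (multiply by the points-per-outcome to get the score).
    """
    n = stim.shape[0]
    q = np.zeros(n_stimuli)
    assoc = np.ones(n_stimuli)
    total_r = 0.0
    for t in range(n):
        s = stim[t]
        v_play = play_bias + q[s]
        p_play = 1.0 / (1.0 + math.exp(-beta * v_play))
        p_play_out[t] = p_play
        play = 1 if uniforms[t] < p_play else 0
        action_out[t] = play
        win = reward[t] > 0.0
        if play == 1:
            total_r += reward[t]
        # confirmatory = factual win or counterfactual loss, centered +-0.5
        if (play == 1 and win) or (play == 0 and not win):
            c = 0.5
        else:
            c = -0.5
        m = 0.5 if play == 1 else -0.5
        conf_out[t] = c
        mod_out[t] = m

        x = w_int
        if use_conf:
            x += w_conf * c
        if use_mod:
            x += w_mod * m
        kappa = 1.0 / (1.0 + math.exp(-x))
        alpha = kappa

        delta = reward[t] - q[s]
        if uses_assoc:
            abs_d = -delta if delta < 0.0 else delta
            assoc[s] = eta * abs_d + (1.0 - eta) * assoc[s]
            alpha = kappa * assoc[s]
            if alpha > 1.0:
                alpha = 1.0
        q_out[t] = q[s]
        delta_out[t] = delta
        assoc_out[t] = assoc[s]
        alpha_out[t] = alpha
        q[s] = q[s] + alpha * delta
    return total_r


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    loglik_kernel = njit(cache=True)(_loglik_py)
    simulate_kernel = njit(cache=True)(_simulate_py)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    loglik_kernel = _loglik_py
    simulate_kernel = _simulate_py
    HAVE_NUMBA = False
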