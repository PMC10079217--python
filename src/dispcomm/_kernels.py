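"""Compiled population-scale trial evaluation.

This is the hot loop of the evolutionary runs: all pairs of a population are
simulated through their five trials in one call.  The event ordering within
a time step is identical to :func:`dispcomm.simulate.run_trial` (sender
senses and updates, emission is nest-gated into the receiver's perception
using this step's positions, receiver senses and updates, both move), and
the arithmetic mirrors the reference path operation for operation so the two
agree to floating-point roundoff.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi

MODE_COMMUNICATION = 0
MODE_NO_COMMUNICATION = 1
MODE_CONSTRAINED_SENDER = 2

MODE_CODES = {
    "communication": MODE_COMMUNICATION,
    "no_communication": MODE_NO_COMMUNICATION,
    "constrained_sender": MODE_CONSTRAINED_SENDER,
}


@njit(cache=True)
def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def _normalize(a):
    return (a + np.pi) % TWO_PI - np.pi


@njit(cache=True)
def _in_arc(pos, center, half):
    d = _normalize(pos - center)
    return (d >= -half) and (d < half)


@njit(cache=True)
def _net_step(w_in, w_hh, w_out, bias, tau, s, y, x, alpha, printed):
    """One layered CTRNN update in place: input, then hidden, then output."""
    ni = w_in.shape[0]
    nh = w_hh.shape[0]
    no = w_out.shape[1]
    # input neurons: drive is the raw sensory value
    for i in range(ni):
        if printed:
            s[i] = alpha * tau[i] * (x[i] - s[i])
        else:
            s[i] = s[i] + (alpha / tau[i]) * (x[i] - s[i])
        y[i] = _sigmoid(s[i] + bias[i])
    # hidden neurons: fresh input activations + previous hidden activations
    drive_h = np.empty(nh)
    for j in range(nh):
        d = 0.0
        for i in range(ni):
            d += y[i] * w_in[i, j]
        for i in range(nh):
            d += y[ni + i] * w_hh[i, j]
        drive_h[j] = d
    for j in range(nh):
        k = ni + j
        if printed:
            s[k] = alpha * tau[k] * (drive_h[j] - s[k])
        else:
            s[k] = s[k] + (alpha / tau[k]) * (drive_h[j] - s[k])
        y[k] = _sigmoid(s[k] + bias[k])
    # output neurons: fresh hidden activations
    for j in range(no):
        k = ni + nh + j
        d = 0.0
        for i in range(nh):
            d += y[ni + i] * w_out[i, j]
        if printed:
            s[k] = alpha * tau[k] * (d - s[k])
        else:
            s[k] = s[k] + (alpha / tau[k]) * (d - s[k])
        y[k] = _sigmoid(s[k] + bias[k])


@njit(cache=True)
def evaluate_generation(
    s_w_in,
    s_w_hh,
    s_w_out,
    s_bias,
    s_tau,
    r_w_in,
    r_w_hh,
    r_w_out,
    r_bias,
    r_tau,
    food_orders,
    site_centers,
    site_half,
    nest_half,
    max_speed,
    n_steps,
    alpha,
    mode,
    printed,
    onset_threshold,
):
    """Simulate five trials for every pair; returns (on-food counts, onsets).

    ``counts[p, j]`` is the number of scored steps (last 20) pair ``p``'s
    receiver spent on the food site in its ``j``-th trial; ``onsets[p, j]``
    is the 1-based onset-delay (start of the first perception episode,
    skipping an episode already in progress at step 1 — the trial-start
    co-presence artifact), or -1 if none.
    """
    n = s_w_in.shape[0]
    n_trials = food_orders.shape[1]
    s_nn = s_bias.shape[1]
    r_nn = r_bias.shape[1]
    s_ni = s_w_in.shape[1]
    s_nh = s_w_hh.shape[1]
    r_ni = r_w_in.shape[1]
    r_nh = r_w_hh.shape[1]

    counts = np.zeros((n, n_trials), dtype=np.int64)
    onsets = np.full((n, n_trials), -1, dtype=np.int64)
    scored_from = n_steps - 20

    s_x = np.empty(3)
    r_x = np.empty(3)
    s_s = np.empty(s_nn)
    s_y = np.empty(s_nn)
    r_s = np.empty(r_nn)
    r_y = np.empty(r_nn)

    for p in range(n):
        for trial in range(n_trials):
            food_site = food_orders[p, trial]
            food_center = site_centers[food_site]
            pos_s = 0.0
            pos_r = 0.0
            prev_above = False
            for i in range(s_nn):
                s_s[i] = 0.0
                s_y[i] = _sigmoid(s_bias[p, i])
            for i in range(r_nn):
                r_s[i] = 0.0
                r_y[i] = _sigmoid(r_bias[p, i])

            for t in range(n_steps):
                food = 1.0 if _in_arc(pos_s, food_center, site_half) else 0.0

                s_x[0] = np.sin(pos_s)
                s_x[1] = np.cos(pos_s)
                s_x[2] = food
                _net_step(
                    s_w_in[p], s_w_hh[p], s_w_out[p], s_bias[p], s_tau[p],
                    s_s, s_y, s_x, alpha, printed,
                )
                emitted = s_y[s_ni + s_nh + 2]
                d_motor = s_y[s_ni + s_nh] - s_y[s_ni + s_nh + 1]
                speed_s = abs(d_motor) * max_speed
                dir_s = 1.0 if d_motor >= 0.0 else -1.0

                sender_in_nest = _in_arc(pos_s, 0.0, nest_half)
                receiver_in_nest = _in_arc(pos_r, 0.0, nest_half)
                if sender_in_nest and receiver_in_nest:
                    perceived = emitted
                else:
                    perceived = 0.0
                if mode == MODE_NO_COMMUNICATION:
                    perceived = 0.0

                r_x[0] = np.sin(pos_r)
                r_x[1] = np.cos(pos_r)
                r_x[2] = perceived
                _net_step(
                    r_w_in[p], r_w_hh[p], r_w_out[p], r_bias[p], r_tau[p],
                    r_s, r_y, r_x, alpha, printed,
                )
                d_motor_r = r_y[r_ni + r_nh] - r_y[r_ni + r_nh + 1]
                speed_r = abs(d_motor_r) * max_speed
                dir_r = 1.0 if d_motor_r >= 0.0 else -1.0

                above = perceived > onset_threshold
                if above and not prev_above and t > 0 and onsets[p, trial] < 0:
                    onsets[p, trial] = t + 1
                prev_above = above
                if t >= scored_from and _in_arc(pos_r, food_center, site_half):
                    counts[p, trial] += 1

                if mode == MODE_CONSTRAINED_SENDER:
                    speed_s = max_speed
                    dir_s = 1.0

                pos_s = _normalize(pos_s + dir_s * speed_s)
                pos_r = _normalize(pos_r + dir_r * speed_r)

    return counts, onsets
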