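"""Spike-triggered weight-update primitives (numba-jitted).

These are the single source of truth for the three rule parameterizations.
Both the full network kernel and the standalone two-neuron pair simulator
call into these functions, so synapse-level tests exercise exactly the code
that runs inside network episodes.

Parameter-vector layout (``prm``, padded to length 21):

* small polynomial: ``[alpha, beta, gamma, kappa, tau_pre_ms, tau_post_ms]``
* big polynomial:   ``theta_0 .. theta_20`` as printed (pre factor group
  ``theta_0..theta_9``, post factor group ``theta_10..theta_20``)
* MLP:              ``[w_pre(4), b_pre, w_post(4), b_post, learning_rate]``
"""

import numpy as np
from numba import njit

# rule kind codes used across the package
STATIC = 0
SMALL = 1
BIG = 2
MLP = 3

# fixed trace time constants of the big-poly / MLP spaces (ms)
TAU_SHORT = 10.0
TAU_LONG = 100.0
# fixed low-pass time constants of the auxiliary synaptic variables (ms)
TAU_VAVG = 100.0
TAU_CE = 10.0
TAU_CI = 100.0

PRM_LEN = 21


@njit(cache=True, inline="always")
def trace_at(value, t_last, t, tau):
    """Exact exponential decay of a lazily-stored trace to time ``t``."""
    return value * np.exp(-(t - t_last) / tau)


@njit(cache=True, inline="always")
def small_delta_pre(prm, x_post):
    # alpha + kappa * x_j  (post trace sampled before any same-step bump)
    return prm[0] + prm[3] * x_post


@njit(cache=True, inline="always")
def small_delta_post(prm, x_pre):
    # beta + gamma * x_i
    return prm[1] + prm[2] * x_pre


@njit(cache=True, inline="always")
def big_delta_pre(prm, w, v_avg, c_e, c_i, x_i_long, x_j_short):
    return (
        prm[0]
        * (1.0 + prm[1] + prm[2] * w + prm[3] * w * w)
        * (1.0 + prm[4] * v_avg)
        * (1.0 + prm[5] * c_e + prm[6] * c_e * c_e)
        * (1.0 + prm[7] * c_i)
        * (1.0 + prm[8] * x_i_long)
        * (1.0 + prm[9] * x_j_short)
    )


@njit(cache=True, inline="always")
def big_delta_post(prm, w, v_avg, c_e, c_i, x_i_short, x_j_long):
    return (
        prm[10]
        * (1.0 + prm[11] + prm[12] * w + prm[13] * w * w)
        * (1.0 + prm[14] * v_avg)
        * (1.0 + prm[15] * c_e + prm[16] * c_e * c_e)
        * (1.0 + prm[17] * c_i)
        * (1.0 + prm[18] * x_i_short)
        * (1.0 + prm[19] * x_j_long + prm[20] * x_j_long**3)
    )


@njit(cache=True)
def mlp_forward(W1, W2, w_out0, w_out1, w_out2, w_out3, b_out, lr,
                x0, x1, x2, x3, x4, x5):
    """Forward pass of one plasticity MLP: 6 -> 50 sigmoid -> 4 sigmoid -> 1.

    Hidden layers are frozen; only the 4 output weights, the output bias and
    the shared learning rate are tunable.
    """
    h1 = np.empty(50)
    for m in range(50):
        a = (W1[m, 0] * x0 + W1[m, 1] * x1 + W1[m, 2] * x2
             + W1[m, 3] * x3 + W1[m, 4] * x4 + W1[m, 5] * x5)
        h1[m] = 1.0 / (1.0 + np.exp(-a))
    out = b_out
    for k in range(4):
        acc2 = 0.0
        for m in range(50):
            acc2 += W2[k, m] * h1[m]
        h2 = 1.0 / (1.0 + np.exp(-acc2))
        if k == 0:
            out += w_out0 * h2
        elif k == 1:
            out += w_out1 * h2
        elif k == 2:
            out += w_out2 * h2
        else:
            out += w_out3 * h2
    return lr * out


@njit(cache=True, inline="always")
def mlp_delta_pre(prm, W1, W2, x_i_long, x_j_short, w, v_avg, c_e, c_i):
    return mlp_forward(W1, W2, prm[0], prm[1], prm[2], prm[3], prm[4], prm[10],
                       x_i_long, x_j_short, w, v_avg, c_e, c_i)


@njit(cache=True, inline="always")
def mlp_delta_post(prm, W1, W2, x_i_short, x_j_long, w, v_avg, c_e, c_i):
    return mlp_forward(W1, W2, prm[5], prm[6], prm[7], prm[8], prm[9], prm[10],
                       x_i_short, x_j_long, w, v_avg, c_e, c_i)
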