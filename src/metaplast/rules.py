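"""Plasticity-rule parameterizations, codecs and the two-neuron pair simulator.

Three rule spaces of increasing expressivity are implemented, all applying
event-wise updates at pre-/postsynaptic spike times:

* ``small`` — first-order pair-based STDP,
  ``dw = alpha*S_i + beta*S_j + gamma*S_j*x_i + kappa*S_i*x_j``,
  with learnable trace time constants ``tau_pre``, ``tau_post``
  (optimized as natural logarithms; 6 parameters).
* ``big`` — separable polynomial over additional synaptic variables
  (weight, low-passed membrane potential, codependent conductance terms,
  short/long traces at fixed 10/100 ms; 21 parameters).
* ``mlp`` — the same variables fed through a mostly-frozen multilayer
  perceptron (6 -> 50 sigmoid -> 4 sigmoid -> linear); only the 4 output
  weights + 1 bias per MLP (pre and post) and a shared learning rate are
  tunable (11 parameters).

Conventions (shared with the network kernel):

* at a spike, the spiking neuron's own trace is read *before* its +1 bump;
* when a pre and a post spike land in the same time bin, the pre-triggered
  update is applied first, then the post-triggered one, and both read
  pre-bump traces;
* trace decay between events is exact exponential.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from ._deltas import (
    BIG, MLP, PRM_LEN, SMALL, STATIC, TAU_LONG, TAU_SHORT,
    big_delta_post, big_delta_pre, mlp_delta_post, mlp_delta_pre,
    small_delta_post, small_delta_pre,
)

__all__ = [
    "SmallPolyRule", "BigPolyRule", "MLPRule", "RuleAssignment",
    "encode_theta", "decode_theta", "space_dim", "init_quiescent",
    "apply_bounds", "frozen_mlp_weights", "simulate_pair", "ExpTraces",
    "rule_to_json", "rule_from_json",
]

SPACE_DIMS = {"small": 6, "big": 21, "mlp": 11}

#: default hard weight bounds per synapse block (unitless conductance weights)
DEFAULT_BOUNDS = (0.0, 10.0)


def space_dim(space: str) -> int:
    """Length of the encoded parameter vector for a rule space."""
    try:
        return SPACE_DIMS[space]
    except KeyError:
        raise ValueError(f"unknown rule space {space!r}") from None


@dataclass
class SmallPolyRule:
    """First-order pair-based STDP rule.

    ``alpha``/``beta`` are the non-Hebbian pre-only/post-only amplitudes,
    ``gamma``/``kappa`` the Hebbian amplitudes multiplying the pre trace at
    post spikes and the post trace at pre spikes.  Time constants in ms.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    kappa: float = 0.0
    tau_pre: float = 10.0
    tau_post: float = 10.0
    space = "small"

    def __post_init__(self):
        if self.tau_pre <= 0 or self.tau_post <= 0:
            raise ValueError("trace time constants must be positive")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.kappa])

    def encode(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.kappa,
                         np.log(self.tau_pre), np.log(self.tau_post)])

    def packed(self) -> np.ndarray:
        prm = np.zeros(PRM_LEN)
        prm[:4] = self.amplitudes
        prm[4] = self.tau_pre
        prm[5] = self.tau_post
        return prm

    kind = SMALL


@dataclass
class BigPolyRule:
    """Separable polynomial rule over extended synaptic variables.

    ``theta[0:10]`` weight the factors of pre-spike-triggered updates,
    ``theta[10:21]`` those of post-spike-triggered updates.  Trace time
    constants are fixed (10 ms short / 100 ms long).
    """

    theta: np.ndarray = field(default_factory=lambda: np.zeros(21))
    space = "big"

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (21,):
            raise ValueError("big polynomial rule takes exactly 21 parameters")

    @property
    def amplitudes(self) -> np.ndarray:
        return self.theta

    def encode(self) -> np.ndarray:
        return self.theta.copy()

    def packed(self) -> np.ndarray:
        return self.theta.copy()

    kind = BIG


@dataclass
class MLPRule:
    """Mostly-frozen MLP rule; tunables are the output layers + learning rate.

    The frozen hidden weights are a pure function of ``frozen_seed`` and are
    shared between the pre- and post-MLP.  A learned parameter vector is
    meaningless without its frozen seed, so the seed travels with the rule.
    """

    w_pre: np.ndarray = field(default_factory=lambda: np.zeros(4))
    b_pre: float = 0.0
    w_post: np.ndarray = field(default_factory=lambda: np.zeros(4))
    b_post: float = 0.0
    learning_rate: float = 0.0
    frozen_seed: int = 0
    space = "mlp"

    def __post_init__(self):
        self.w_pre = np.asarray(self.w_pre, dtype=float)
        self.w_post = np.asarray(self.w_post, dtype=float)
        if self.w_pre.shape != (4,) or self.w_post.shape != (4,):
            raise ValueError("each MLP output layer has exactly 4 weights")

    @property
    def amplitudes(self) -> np.ndarray:
        """Entries subject to L1 regularization (everything tunable)."""
        return self.encode()

    def encode(self) -> np.ndarray:
        return np.concatenate([self.w_pre, [self.b_pre], self.w_post,
                               [self.b_post], [self.learning_rate]])

    def packed(self) -> np.ndarray:
        prm = np.zeros(PRM_LEN)
        prm[:11] = self.encode()
        return prm

    def frozen_weights(self):
        return frozen_mlp_weights(self.frozen_seed)

    kind = MLP


Rule = Union[SmallPolyRule, BigPolyRule, MLPRule]


def frozen_mlp_weights(seed: int):
    """Frozen hidden-layer weights, U(-1/sqrt(n_inp), 1/sqrt(n_inp)) per layer.

    Identical for the pre- and post-MLP and for every candidate within one
    optimization (the seed is part of the experiment config).
    """
    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-1.0, 1.0, size=(50, 6)) / np.sqrt(6.0)
    W2 = rng.uniform(-1.0, 1.0, size=(4, 50)) / np.sqrt(50.0)
    return W1, W2


def encode_theta(rule: Rule) -> np.ndarray:
    """Flatten a rule to its optimization vector (log time constants)."""
    return rule.encode()


def decode_theta(vector: np.ndarray, space: str, frozen_seed: int = 0) -> Rule:
    """Inverse of :func:`encode_theta`; validates the vector length."""
    vector = np.asarray(vector, dtype=float)
    d = space_dim(space)
    if vector.shape != (d,):
        raise ValueError(f"space {space!r} expects a vector of length {d}, "
                         f"got shape {vector.shape}")
    if space == "small":
        return SmallPolyRule(*(float(v) for v in vector[:4]),
                             tau_pre=float(np.exp(vector[4])),
                             tau_post=float(np.exp(vector[5])))
    if space == "big":
        return BigPolyRule(theta=vector)
    return MLPRule(w_pre=vector[0:4], b_pre=float(vector[4]),
                   w_post=vector[5:9], b_post=float(vector[9]),
                   learning_rate=float(vector[10]), frozen_seed=frozen_seed)


def init_quiescent(space: str, frozen_seed: int = 0) -> Rule:
    """The do-nothing rule used to initialize the outer loop.

    All amplitudes are zero so no episode changes any weight; learnable time
    constants start at 10 ms (encoded as ln 10).
    """
    if space == "small":
        return SmallPolyRule()
    if space == "big":
        return BigPolyRule()
    if space == "mlp":
        return MLPRule(frozen_seed=frozen_seed)
    raise ValueError(f"unknown rule space {space!r}")


def apply_bounds(w, bounds=DEFAULT_BOUNDS):
    """Clip weights to the block's hard bounds (idempotent)."""
    lo, hi = bounds
    if lo > hi:
        raise ValueError(f"invalid weight bounds [{lo}, {hi}]")
    if lo < 0:
        raise ValueError("lower weight bound must be >= 0")
    return np.clip(w, lo, hi)


@dataclass
class RuleAssignment:
    """Mapping from synapse block to rule instance, with bounds and scale.

    Blocks are named ``"ee", "ei", "ie", "ii"`` (pre population first).
    A missing/None entry means the block is static.
    """

    rules: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    scale: dict = field(default_factory=dict)

    BLOCKS = ("ee", "ei", "ie", "ii")

    def __post_init__(self):
        for b in self.rules:
            if b not in self.BLOCKS:
                raise ValueError(f"unknown synapse block {b!r}")
        for b, (lo, hi) in self.bounds.items():
            if lo > hi or lo < 0:
                raise ValueError(f"invalid bounds for block {b!r}: [{lo}, {hi}]")

    def rule(self, block: str) -> Optional[Rule]:
        return self.rules.get(block)

    def block_bounds(self, block: str):
        return self.bounds.get(block, DEFAULT_BOUNDS)

    def block_scale(self, block: str) -> float:
        return self.scale.get(block, 1.0)

    @property
    def plastic_blocks(self):
        return [b for b in self.BLOCKS if self.rules.get(b) is not None]


class ExpTraces:
    """Vector of exponentially-decaying spike traces (exact decay).

    dx/dt = -x/tau + S(t): decays by ``exp(-dt/tau)`` between spikes and
    jumps by exactly 1 at each spike of its neuron.
    """

    def __init__(self, n: int, tau_ms: float):
        if tau_ms <= 0:
            raise ValueError("tau must be positive")
        self.x = np.zeros(n)
        self.tau = tau_ms

    def decay(self, dt_ms: float):
        self.x *= np.exp(-dt_ms / self.tau)

    def bump(self, indices):
        self.x[indices] += 1.0


# ---------------------------------------------------------------------------
# Two-neuron pair simulator (protocol curves, oracle tests)
# ---------------------------------------------------------------------------

#: auxiliary-variable clamps used when a rule depends on variables that a
#: two-neuron protocol does not constrain: mid-range weight, resting
#: membrane potential, zero codependent terms.
DEFAULT_CLAMPS = {"w": 5.0, "v_avg": -60.0, "c_e": 0.0, "c_i": 0.0}


def simulate_pair(rule: Rule, pre_times, post_times, dt: float = 0.1,
                  w0: Optional[float] = None, clamps: Optional[dict] = None,
                  bounds=None, scale: float = 1.0):
    """Step-based simulation of one plastic synapse given two spike trains.

    Spike times (ms) are snapped to the ``dt`` grid, and the update follows
    the same bookkeeping as the network kernel (lazy exact-exponential
    traces, pre-before-post tie-break, pre-bump trace sampling).  For the
    big-poly and MLP spaces the auxiliary variables (low-passed voltage and
    codependent terms) are clamped to ``clamps``; the weight fed to the rule
    is the evolving ``w`` itself (starting from ``w0``, which defaults to the
    ``w`` clamp).

    Returns ``(event_times, w_trajectory, total_dw)`` where ``w_trajectory``
    holds the weight after each spike event.
    """
    cl = dict(DEFAULT_CLAMPS)
    if clamps is not None:
        cl.update(clamps)
    if w0 is None:
        w0 = cl["w"]

    pre_bins = sorted({int(round(t / dt)) for t in np.atleast_1d(pre_times)})
    post_bins = sorted({int(round(t / dt)) for t in np.atleast_1d(post_times)})
    events = sorted(set(pre_bins) | set(post_bins))
    pre_set, post_set = set(pre_bins), set(post_bins)

    prm = rule.packed()
    kind = rule.kind
    if kind == MLP:
        W1, W2 = rule.frozen_weights()
    else:
        W1 = W2 = np.zeros((1, 1))

    # lazy traces: (value at t_last, t_last)
    if kind == SMALL:
        taus = {"pre": rule.tau_pre, "post": rule.tau_post}
        tr = {"pre": [0.0, 0.0], "post": [0.0, 0.0]}
    else:
        taus = {"pre_s": TAU_SHORT, "pre_l": TAU_LONG,
                "post_s": TAU_SHORT, "post_l": TAU_LONG}
        tr = {k: [0.0, 0.0] for k in taus}

    def read(name, t):
        v, t0 = tr[name]
        return v * np.exp(-(t - t0) / taus[name])

    def bump(name, t):
        tr[name] = [read(name, t) + 1.0, t]

    w = float(w0)
    times, traj = [], []
    for b in events:
        t = b * dt
        is_pre = b in pre_set
        is_post = b in post_set
        if is_pre:
            if kind == SMALL:
                dw = small_delta_pre(prm, read("post", t))
            elif kind == BIG:
                dw = big_delta_pre(prm, w, cl["v_avg"], cl["c_e"], cl["c_i"],
                                   read("pre_l", t), read("post_s", t))
            elif kind == MLP:
                dw = mlp_delta_pre(prm, W1, W2, read("pre_l", t),
                                   read("post_s", t), w, cl["v_avg"],
                                   cl["c_e"], cl["c_i"])
            else:
                dw = 0.0
            w += scale * dw
            if bounds is not None:
                w = float(apply_bounds(w, bounds))
        if is_post:
            if kind == SMALL:
                dw = small_delta_post(prm, read("pre", t))
            elif kind == BIG:
                dw = big_delta_post(prm, w, cl["v_avg"], cl["c_e"], cl["c_i"],
                                    read("pre_s", t), read("post_l", t))
            elif kind == MLP:
                dw = mlp_delta_post(prm, W1, W2, read("pre_s", t),
                                    read("post_l", t), w, cl["v_avg"],
                                    cl["c_e"], cl["c_i"])
            else:
                dw = 0.0
            w += scale * dw
            if bounds is not None:
                w = float(apply_bounds(w, bounds))
        # trace bumps after all updates of this bin
        if kind == SMALL:
            if is_pre:
                bump("pre", t)
            if is_post:
                bump("post", t)
        else:
            if is_pre:
                bump("pre_s", t)
                bump("pre_l", t)
            if is_post:
                bump("post_s", t)
                bump("post_l", t)
        times.append(t)
        traj.append(w)

    return np.array(times), np.array(traj), w - w0


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def rule_to_json(rule: Rule, bounds=DEFAULT_BOUNDS) -> str:
    payload = {"space": rule.space,
               "theta": encode_theta(rule).tolist(),
               "bounds": list(bounds)}
    if rule.space == "mlp":
        payload["frozen_seed"] = rule.frozen_seed
    return json.dumps(payload, indent=2)


def rule_from_json(text: str):
    """Returns ``(rule, bounds)`` from the JSON produced by rule_to_json."""
    payload = json.loads(text)
    rule = decode_theta(np.array(payload["theta"]), payload["space"],
                        frozen_seed=payload.get("frozen_seed", 0))
    return rule, tuple(payload.get("bounds", DEFAULT_BOUNDS))
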