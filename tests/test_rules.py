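"""Unit and property tests for the plasticity-rule module."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaplast.rules import (
    BigPolyRule, ExpTraces, MLPRule, RuleAssignment, SmallPolyRule,
    apply_bounds, decode_theta, encode_theta, frozen_mlp_weights,
    init_quiescent, rule_from_json, rule_to_json, simulate_pair, space_dim,
)


# ---------------------------------------------------------------------------
# codecs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("space,dim", [("small", 6), ("big", 21), ("mlp", 11)])
def test_space_dimensions(space, dim):
    assert space_dim(space) == dim
    assert encode_theta(init_quiescent(space)).shape == (dim,)


@pytest.mark.parametrize("space", ["small", "big", "mlp"])
def test_codec_round_trip(space, rng):
    vec = rng.normal(size=space_dim(space))
    rule = decode_theta(vec, space, frozen_seed=7)
    assert np.allclose(encode_theta(rule), vec)


def test_decode_rejects_wrong_length():
    with pytest.raises(ValueError, match="length"):
        decode_theta(np.zeros(7), "small")
    with pytest.raises(ValueError, match="unknown rule space"):
        decode_theta(np.zeros(6), "medium")


def test_time_constants_positive_for_any_encoding(rng):
    # log-parameterization: any real entry decodes to tau > 0
    for _ in range(20):
        vec = rng.normal(scale=5.0, size=6)
        rule = decode_theta(vec, "small")
        assert rule.tau_pre > 0 and rule.tau_post > 0


def test_small_rule_rejects_nonpositive_tau():
    with pytest.raises(ValueError):
        SmallPolyRule(tau_pre=0.0)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def test_trace_exact_exponential_decay():
    tr = ExpTraces(3, tau_ms=10.0)
    tr.bump([0, 1, 2])
    for _ in range(100):          # 100 x 0.1 ms = 10 ms
        tr.decay(0.1)
    assert np.allclose(tr.x, np.exp(-1.0))


def test_trace_bump_and_rest():
    tr = ExpTraces(2, tau_ms=25.0)
    tr.bump([1])
    tr.bump([1])
    assert tr.x[0] == 0.0 and tr.x[1] == 2.0
    tr.decay(1000.0)
    assert tr.x[0] == 0.0          # zero trace stays zero


@given(rate=st.floats(10.0, 80.0), tau=st.floats(20.0, 200.0))
@settings(max_examples=10, deadline=None, derandomize=True)
def test_trace_stationary_mean_is_rate_times_tau(rate, tau):
    """A neuron firing as a Poisson process at rate r has mean trace r*tau."""
    rng = np.random.default_rng(5)
    dt, T = 0.1, 200_000.0
    n_bins = int(T / dt)
    spikes = rng.random(n_bins) < rate * dt / 1000.0
    x, acc, dec = 0.0, 0.0, np.exp(-dt / tau)
    # skip a burn-in of 5 tau before averaging
    burn = int(5 * tau / dt)
    for k in range(n_bins):
        x = x * dec + (1.0 if spikes[k] else 0.0)
        if k >= burn:
            acc += x
    mean = acc / (n_bins - burn)
    expected = rate * tau / 1000.0
    assert mean == pytest.approx(expected, rel=0.15)


# ---------------------------------------------------------------------------
# small polynomial updates
# ---------------------------------------------------------------------------

def test_pre_event_alpha_only_is_constant():
    rule = SmallPolyRule(alpha=0.5)
    _, _, dw = simulate_pair(rule, pre_times=[10.0], post_times=[])
    assert dw == pytest.approx(0.5)


def test_all_zero_amplitudes_give_zero_update(rng):
    rule = SmallPolyRule()
    pre = np.sort(rng.uniform(0, 500, 20))
    post = np.sort(rng.uniform(0, 500, 20))
    _, _, dw = simulate_pair(rule, pre, post)
    assert dw == 0.0


def test_post_then_pre_samples_decayed_post_trace():
    # post at t, pre 10 ms later with kappa=1, tau_post=10 ms -> dw = e^-1
    rule = SmallPolyRule(kappa=1.0, tau_post=10.0)
    _, _, dw = simulate_pair(rule, pre_times=[30.0], post_times=[20.0])
    assert dw == pytest.approx(np.exp(-1.0), abs=1e-12)


def test_simultaneous_spikes_read_prebump_traces():
    # same-bin pre+post: both updates see the other's trace before its bump,
    # so only the non-Hebbian terms fire
    rule = SmallPolyRule(alpha=0.1, beta=0.2, gamma=5.0, kappa=7.0)
    _, _, dw = simulate_pair(rule, pre_times=[10.0], post_times=[10.0])
    assert dw == pytest.approx(0.3)


def small_poly_pair_oracle(rule, pre, post):
    """Independent closed form: sum of exponential kernels over spike pairs.

    Strict time ordering (same-bin pairs excluded) matches the read-before-
    bump convention.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    dw = rule.alpha * pre.size + rule.beta * post.size
    for tj in post:
        lags = tj - pre[pre < tj]
        dw += rule.gamma * np.exp(-lags / rule.tau_pre).sum()
    for ti in pre:
        lags = ti - post[post < ti]
        dw += rule.kappa * np.exp(-lags / rule.tau_post).sum()
    return dw


def test_step_simulation_matches_pairwise_oracle(rng):
    """Cumulative dw of the step-based path equals the event-driven closed
    form on random two-neuron spike trains."""
    for trial in range(100):
        rule = SmallPolyRule(*rng.normal(scale=0.3, size=4),
                             tau_pre=float(rng.uniform(5, 50)),
                             tau_post=float(rng.uniform(5, 50)))
        n_pre, n_post = rng.integers(1, 50, size=2)
        pre = np.unique(rng.integers(0, 10_000, n_pre)) * 0.1
        post = np.unique(rng.integers(0, 10_000, n_post)) * 0.1
        _, _, dw = simulate_pair(rule, pre, post)
        assert dw == pytest.approx(small_poly_pair_oracle(rule, pre, post),
                                   abs=1e-10)


# ---------------------------------------------------------------------------
# big polynomial
# ---------------------------------------------------------------------------

def test_big_poly_validates_length():
    with pytest.raises(ValueError):
        BigPolyRule(np.zeros(20))


def test_big_poly_theta0_alone_gives_constant_pre_update():
    th = np.zeros(21)
    th[0] = 0.7
    _, _, dw = simulate_pair(BigPolyRule(th), pre_times=[10.0], post_times=[])
    assert dw == pytest.approx(0.7)


def test_big_poly_reduces_to_small_poly(rng):
    """theta0=alpha, theta0*theta9=kappa, theta10=beta, theta10*theta18=gamma
    reproduces the small-poly trajectory at tau_pre=tau_post=10 ms."""
    for _ in range(10):
        a, b, g, k = rng.normal(scale=0.2, size=4)
        a = a if abs(a) > 1e-3 else 0.1
        b = b if abs(b) > 1e-3 else -0.1
        th = np.zeros(21)
        th[0], th[9], th[10], th[18] = a, k / a, b, g / b
        small = SmallPolyRule(a, b, g, k, tau_pre=10.0, tau_post=10.0)
        pre = np.unique(rng.integers(0, 20_000, 40)) * 0.1
        post = np.unique(rng.integers(0, 20_000, 40)) * 0.1
        _, traj_s, _ = simulate_pair(small, pre, post)
        _, traj_b, _ = simulate_pair(BigPolyRule(th), pre, post)
        assert np.max(np.abs(traj_s - traj_b)) < 1e-10


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

def test_frozen_weights_deterministic_and_bounded():
    W1a, W2a = frozen_mlp_weights(3)
    W1b, W2b = frozen_mlp_weights(3)
    assert np.array_equal(W1a, W1b) and np.array_equal(W2a, W2b)
    assert W1a.shape == (50, 6) and W2a.shape == (4, 50)
    assert np.abs(W1a).max() <= 1 / np.sqrt(6)
    assert np.abs(W2a).max() <= 1 / np.sqrt(50)


def test_mlp_zero_output_layer_is_quiescent(rng):
    rule = MLPRule(frozen_seed=9)
    pre = np.sort(rng.uniform(0, 300, 15))
    post = np.sort(rng.uniform(0, 300, 15))
    _, _, dw = simulate_pair(rule, pre, post)
    assert dw == 0.0


def test_mlp_update_bound(rng):
    """|dw| <= |lr| * (sum|w_out| + |b_out|) since penultimate sigmoids
    lie in (0, 1)."""
    for _ in range(20):
        rule = MLPRule(w_pre=rng.normal(size=4), b_pre=rng.normal(),
                       w_post=rng.normal(size=4), b_post=rng.normal(),
                       learning_rate=float(rng.normal()), frozen_seed=2)
        _, _, dw = simulate_pair(rule, pre_times=[5.0], post_times=[])
        bound = abs(rule.learning_rate) * (np.abs(rule.w_pre).sum()
                                           + abs(rule.b_pre))
        assert abs(dw) <= bound + 1e-12


# ---------------------------------------------------------------------------
# bounds, assignment, serialization
# ---------------------------------------------------------------------------

def test_apply_bounds_clips_and_is_idempotent():
    assert apply_bounds(12.0) == 10.0
    assert apply_bounds(-0.3) == 0.0
    assert apply_bounds(5.0) == 5.0
    w = np.array([-1.0, 3.0, 11.0])
    once = apply_bounds(w)
    assert np.array_equal(apply_bounds(once), once)


def test_apply_bounds_rejects_bad_interval():
    with pytest.raises(ValueError):
        apply_bounds(1.0, (5.0, 2.0))


def test_rule_assignment_validation():
    with pytest.raises(ValueError):
        RuleAssignment(rules={"xx": SmallPolyRule()})
    with pytest.raises(ValueError):
        RuleAssignment(bounds={"ie": (3.0, 1.0)})
    a = RuleAssignment(rules={"ie": SmallPolyRule(alpha=-0.1)})
    assert a.plastic_blocks == ["ie"]
    assert a.block_bounds("ie") == (0.0, 10.0)


@pytest.mark.parametrize("space", ["small", "big", "mlp"])
def test_json_round_trip(space, rng):
    rule = decode_theta(rng.normal(size=space_dim(space)), space,
                        frozen_seed=13)
    back, bounds = rule_from_json(rule_to_json(rule, bounds=(0.0, 8.0)))
    assert bounds == (0.0, 8.0)
    assert np.allclose(encode_theta(back), encode_theta(rule))
    if space == "mlp":
        assert back.frozen_seed == 13
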