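"""Inner-loop task protocols, loss functions and candidate evaluation.

Two network-level objectives are defined:

* **stability** — the excitatory population rate must settle at a target
  (10 Hz) under plasticity, across trials that randomize the external drive,
  the initial mean weights and the connectivity realization;
* **familiarity detection** — after repeated presentations of one stimulus
  (a subset of input neurons firing at a multiple of the background rate),
  the network must respond more strongly to that familiar stimulus than to a
  disjoint novel one, probed with plasticity frozen.

The underlying study never prints its loss formulas, so the forms below are
this package's own documented choices (normalized squared rate error;
hinge + rate-plausibility band), kept term-by-term configurable.  Both
losses add an L1 penalty on the rule amplitudes, and any diverged episode
maps to one fixed penalty cap so the evolutionary ranking stays defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .networks import (
    EpisodeResult, InputSegment, TopologyConfig, build_network,
    constant_input, desk_topology, simulate_episode,
)
from .rules import RuleAssignment, decode_theta, space_dim

__all__ = [
    "StabilityTask", "FamiliarityTask", "StimulusSet",
    "run_stability_episode", "stability_loss",
    "make_familiarity_protocol", "run_familiarity_episode",
    "familiarity_loss", "evaluate_candidate", "trial_seed",
]


@dataclass(frozen=True)
class StabilityTask:
    """Firing-rate homeostasis protocol and loss settings."""

    target_rate: float = 10.0          # Hz
    duration_ms: float = 60_000.0      # training episode length
    eval_start_frac: float = 0.5       # loss evaluated after this fraction
    rate_bin_ms: float = 100.0
    ext_rate_range: tuple = (4.0, 10.0)      # Hz, per-trial uniform draw
    weight_mean_range: tuple = (0.05, 0.5)   # per-trial uniform block means
    lambda_l1: float = 0.01
    #: 10x the loss of an all-silent network (normalized error of 1)
    penalty_cap: float = 10.0
    kind = "stability"


@dataclass(frozen=True)
class StimulusSet:
    """Familiar/novel input subsets (disjoint) and their drive parameters."""

    familiar: np.ndarray
    novel: np.ndarray
    multiplier: float
    present_ms: float
    n_reps: int
    isi_ms: float
    break_ms: float
    probe_ms: float

    def __post_init__(self):
        if np.intersect1d(self.familiar, self.novel).size:
            raise ValueError("familiar and novel subsets must be disjoint")
        if self.multiplier <= 1.0:
            raise ValueError("stimulus multiplier must exceed 1")


@dataclass(frozen=True)
class FamiliarityTask:
    """Familiarity-detection protocol and loss settings.

    Training: ``n_reps`` presentations of the familiar stimulus separated by
    background; then a break; then novel and familiar probes with plasticity
    frozen, so the probes measure the learned state.
    """

    frac_stim: float = 0.10         # fraction of input neurons per stimulus
    multiplier: float = 4.0         # stimulus rate / background rate
    n_reps: int = 10
    present_ms: float = 1000.0
    isi_ms: float = 500.0
    break_ms: float = 2000.0
    probe_ms: float = 1000.0
    probe_gap_ms: float = 500.0
    rate_bin_ms: float = 100.0
    margin_hz: float = 5.0          # required familiar-over-novel margin
    rate_band: tuple = (1.0, 30.0)  # plausible mean training rates, Hz
    ext_rate_range: tuple = (4.0, 10.0)
    weight_mean_range: tuple = (0.05, 0.5)
    lambda_l1: float = 0.01
    penalty_cap: float = 10.0
    kind = "familiarity"


def trial_seed(seed_base: int, trial: int) -> int:
    """Deterministic per-trial seed below 2**31 (seed ladder)."""
    return int(np.random.SeedSequence([seed_base, trial]).generate_state(1)[0]
               % (2**31 - 1))


def _randomized_build(variant: str, base_config: TopologyConfig, task,
                      seed: int):
    """Per-trial randomization: ext rate, initial mean weights, connectivity."""
    rng = np.random.default_rng(seed)
    r_ext = float(rng.uniform(*task.ext_rate_range))
    w_mean = {b: float(rng.uniform(*task.weight_mean_range))
              for b in ("ee", "ei", "ie", "ii")}
    cfg = replace(base_config, r_ext=r_ext, w_mean=w_mean)
    conn_seed = int(rng.integers(2**31 - 1))
    topology, state = build_network(variant, cfg, seed=conn_seed)
    input_seed = int(rng.integers(2**31 - 1))
    return topology, state, r_ext, input_seed


# ---------------------------------------------------------------------------
# Stability task
# ---------------------------------------------------------------------------

def run_stability_episode(assignment: RuleAssignment, seed: int,
                          task: StabilityTask = StabilityTask(),
                          variant: str = "vogels",
                          base_config: Optional[TopologyConfig] = None,
                          record_rasters: bool = False) -> EpisodeResult:
    """One randomized stability trial: build, drive at a random rate, record."""
    if base_config is None:
        base_config = desk_topology(variant)
    topology, state, r_ext, input_seed = _randomized_build(
        variant, base_config, task, seed)
    segments = constant_input(r_ext, task.duration_ms)
    return simulate_episode(topology, state, assignment, segments,
                            seed=input_seed, rate_bin_ms=task.rate_bin_ms,
                            record_rasters=record_rasters)


def stability_loss(result: EpisodeResult, task: StabilityTask,
                   amplitudes: Optional[np.ndarray] = None,
                   lambda_l1: Optional[float] = None) -> float:
    """Normalized squared deviation of the E rate from target, plus L1.

    ``mean_t[(r_E(t) - target)^2] / target^2`` over the evaluation window
    (the trailing ``1 - eval_start_frac`` of the episode), so an all-silent
    network scores exactly 1 before regularization.  Diverged episodes get
    the fixed penalty cap; regular losses are clipped to the same cap so it
    dominates every achievable loss and the evolutionary ranking stays
    well-defined.
    """
    lam = task.lambda_l1 if lambda_l1 is None else lambda_l1
    l1 = lam * float(np.abs(amplitudes).sum()) if amplitudes is not None else 0.0
    if result.diverged:
        return task.penalty_cap
    t0 = task.eval_start_frac * result.duration_ms
    mask = result.rate_times >= t0
    err = (result.e_rates[mask] - task.target_rate) ** 2
    return float(min(err.mean() / task.target_rate**2 + l1,
                     task.penalty_cap))


# ---------------------------------------------------------------------------
# Familiarity task
# ---------------------------------------------------------------------------

def make_familiarity_protocol(task: FamiliarityTask, n_ext: int,
                              base_rate_hz: float, seed: int):
    """Sample disjoint stimulus subsets and lay out the input schedule.

    Returns ``(StimulusSet, segments)``; segment labels mark the probe and
    training windows used by the loss.
    """
    n_stim = int(round(task.frac_stim * n_ext))
    if 2 * n_stim > n_ext:
        raise ValueError("stimulus subsets do not fit in the input population")
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_ext, size=2 * n_stim, replace=False)
    stim = StimulusSet(
        familiar=np.sort(pick[:n_stim]), novel=np.sort(pick[n_stim:]),
        multiplier=task.multiplier, present_ms=task.present_ms,
        n_reps=task.n_reps, isi_ms=task.isi_ms, break_ms=task.break_ms,
        probe_ms=task.probe_ms)

    def rates(subset=None):
        r = np.full(n_ext, base_rate_hz)
        if subset is not None:
            r[subset] = task.multiplier * base_rate_hz
        return r

    segments = []
    for rep in range(task.n_reps):
        segments.append(InputSegment(task.present_ms, rates(stim.familiar),
                                     plastic=True, label=f"train{rep}"))
        segments.append(InputSegment(task.isi_ms, rates(), plastic=True,
                                     label=f"isi{rep}"))
    segments.append(InputSegment(task.break_ms, rates(), plastic=True,
                                 label="break"))
    # probes with plasticity frozen: they measure the learned state
    segments.append(InputSegment(task.probe_ms, rates(stim.novel),
                                 plastic=False, label="probe_novel"))
    segments.append(InputSegment(task.probe_gap_ms, rates(), plastic=False,
                                 label="probe_gap"))
    segments.append(InputSegment(task.probe_ms, rates(stim.familiar),
                                 plastic=False, label="probe_familiar"))
    return stim, segments


def run_familiarity_episode(assignment: RuleAssignment, seed: int,
                            task: FamiliarityTask = FamiliarityTask(),
                            variant: str = "zenke",
                            base_config: Optional[TopologyConfig] = None,
                            record_rasters: bool = False):
    """One randomized familiarity trial.

    Returns ``(result, r_familiar, r_novel)`` with the probe-window mean
    excitatory rates appended.
    """
    if base_config is None:
        base_config = desk_topology(variant)
    topology, state, r_ext, input_seed = _randomized_build(
        variant, base_config, task, seed)
    stim_seed = trial_seed(seed, 104729)
    stim, segments = make_familiarity_protocol(
        task, base_config.n_ext, r_ext, stim_seed)
    result = simulate_episode(topology, state, assignment, segments,
                              seed=input_seed, rate_bin_ms=task.rate_bin_ms,
                              record_rasters=record_rasters)
    r_fam = result.mean_rate("e", *result.segment_window("probe_familiar"))
    r_nov = result.mean_rate("e", *result.segment_window("probe_novel"))
    return result, r_fam, r_nov


def familiarity_loss(result: EpisodeResult, r_familiar: float,
                     r_novel: float, task: FamiliarityTask,
                     amplitudes: Optional[np.ndarray] = None,
                     lambda_l1: Optional[float] = None) -> float:
    """Hinge on the familiar-over-novel margin plus a rate-plausibility term.

    ``max(0, r_novel + margin - r_familiar) / margin`` is 0 once the familiar
    response exceeds the novel one by the margin; the plausibility term
    penalizes mean training-phase rates outside ``rate_band`` (relative
    excursion), discouraging silent or runaway solutions.
    """
    lam = task.lambda_l1 if lambda_l1 is None else lambda_l1
    l1 = lam * float(np.abs(amplitudes).sum()) if amplitudes is not None else 0.0
    if result.diverged:
        return task.penalty_cap
    hinge = max(0.0, r_novel + task.margin_hz - r_familiar) / task.margin_hz
    t_train_end = result.segment_window("break")[1]
    r_train = result.mean_rate("e", 0.0, t_train_end)
    lo, hi = task.rate_band
    plaus = max(0.0, lo - r_train) / lo + max(0.0, r_train - hi) / hi
    return float(min(hinge + plaus + l1, task.penalty_cap))


# ---------------------------------------------------------------------------
# Candidate evaluation (outer-loop objective)
# ---------------------------------------------------------------------------

def evaluate_candidate(theta: np.ndarray, space: str, task,
                       plastic_blocks: Sequence[str] = ("ie",),
                       n_trials: int = 4, seed_base: int = 0,
                       variant: Optional[str] = None,
                       base_config: Optional[TopologyConfig] = None,
                       frozen_seed: int = 0, bounds: Optional[dict] = None,
                       trial_seeds: Optional[Sequence[int]] = None) -> float:
    """Mean loss of one rule candidate over randomized trials.

    ``theta`` holds one encoded parameter vector per plastic block,
    concatenated in block order.  Deterministic given ``(theta, seed_base)``;
    pass explicit ``trial_seeds`` to share trial randomization across the
    candidates of one generation (common random numbers).
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    theta = np.asarray(theta, dtype=float)
    d = space_dim(space)
    if theta.size != d * len(plastic_blocks):
        raise ValueError(
            f"theta length {theta.size} does not match {len(plastic_blocks)} "
            f"block(s) of dimension {d}")
    rules = {}
    amplitudes = []
    for k, block in enumerate(plastic_blocks):
        rule = decode_theta(theta[k * d:(k + 1) * d], space,
                            frozen_seed=frozen_seed)
        rules[block] = rule
        amplitudes.append(rule.amplitudes)
    amplitudes = np.concatenate(amplitudes)
    assignment = RuleAssignment(rules=rules, bounds=bounds or {})

    if variant is None:
        variant = "vogels" if task.kind == "stability" else "zenke"
    if trial_seeds is None:
        trial_seeds = [trial_seed(seed_base, k) for k in range(n_trials)]
    losses = []
    for ts in trial_seeds:
        if task.kind == "stability":
            res = run_stability_episode(assignment, ts, task, variant,
                                        base_config)
            losses.append(stability_loss(res, task, amplitudes))
        else:
            res, r_fam, r_nov = run_familiarity_episode(
                assignment, ts, task, variant, base_config)
            losses.append(familiarity_loss(res, r_fam, r_nov, task,
                                           amplitudes))
    return float(np.mean(losses))
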