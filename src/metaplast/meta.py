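"""CMA-ES outer loop: sample candidate rules, evaluate, adapt, record.

The optimizer is a self-contained (mu/mu_w, lambda)-CMA-ES with weighted
recombination, rank-one + rank-mu covariance adaptation and cumulative
step-size adaptation, following the standard tutorial formulation.  The
ask/tell interface is owned here so alternative backends could be swapped in
without touching the experiment driver.

Candidate fitness is the mean episode loss over randomized trials; within
one generation all candidates share the same trial seeds (common random
numbers), which tightens the ranking the rank-based update consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .rules import decode_theta, encode_theta, init_quiescent, space_dim
from .tasks import evaluate_candidate, trial_seed

__all__ = ["CMAES", "MetaTrajectory", "run_meta_learning",
           "correlation_matrix"]


class CMAES:
    """Minimal, deterministic CMA-ES with an ask/tell interface.

    Minimizes: lower loss is better.  ``popsize`` defaults to twice the
    problem dimension (the generation-size convention used throughout this
    package); the canonical ``4 + 3 ln d`` floor is applied so tiny
    dimensions still recombine sensibly.
    """

    def __init__(self, x0, sigma0: float = 0.3, popsize: Optional[int] = None,
                 seed: int = 0):
        self.mean = np.asarray(x0, dtype=float).copy()
        self.dim = self.mean.size
        if sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        self.sigma = float(sigma0)
        self.popsize = int(popsize) if popsize else max(
            2 * self.dim, 4 + int(3 * np.log(self.dim)))
        if self.popsize < 2:
            raise ValueError("popsize must be at least 2")
        self.rng = np.random.default_rng(seed)

        d, lam = self.dim, self.popsize
        mu = lam // 2
        w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
        self.weights = w / w.sum()
        self.mu = mu
        self.mu_eff = 1.0 / np.sum(self.weights**2)

        self.c_sigma = (self.mu_eff + 2) / (d + self.mu_eff + 5)
        self.d_sigma = (1 + 2 * max(0.0, np.sqrt((self.mu_eff - 1) / (d + 1))
                                    - 1) + self.c_sigma)
        self.c_c = (4 + self.mu_eff / d) / (d + 4 + 2 * self.mu_eff / d)
        self.c_1 = 2 / ((d + 1.3) ** 2 + self.mu_eff)
        self.c_mu = min(1 - self.c_1,
                        2 * (self.mu_eff - 2 + 1 / self.mu_eff)
                        / ((d + 2) ** 2 + self.mu_eff))
        self.chi_n = np.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d**2))

        self.C = np.eye(d)
        self.p_sigma = np.zeros(d)
        self.p_c = np.zeros(d)
        self.generation = 0
        self._eigen()

    def _eigen(self):
        """Eigendecomposition of C with PSD repair (eigenvalue floor)."""
        self.C = (self.C + self.C.T) / 2
        vals, vecs = np.linalg.eigh(self.C)
        floor = 1e-20
        if np.any(vals < floor):
            vals = np.maximum(vals, floor)
            self.C = (vecs * vals) @ vecs.T
        self.B = vecs
        self.D = np.sqrt(vals)

    def ask(self) -> np.ndarray:
        """Sample ``popsize`` candidates ~ N(mean, sigma^2 C)."""
        z = self.rng.standard_normal((self.popsize, self.dim))
        self._last_z = z
        return self.mean + self.sigma * (z * self.D) @ self.B.T

    def state_dict(self) -> dict:
        """JSON-serializable snapshot of the full optimizer state."""
        return {
            "mean": self.mean.tolist(),
            "C": self.C.tolist(),
            "sigma": self.sigma,
            "p_sigma": self.p_sigma.tolist(),
            "p_c": self.p_c.tolist(),
            "generation": self.generation,
            "popsize": self.popsize,
            "rng_state": self.rng.bit_generator.state,
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "CMAES":
        es = cls(np.array(state["mean"]), sigma0=state["sigma"],
                 popsize=state["popsize"], seed=0)
        es.C = np.array(state["C"])
        es.p_sigma = np.array(state["p_sigma"])
        es.p_c = np.array(state["p_c"])
        es.generation = int(state["generation"])
        es.rng.bit_generator.state = state["rng_state"]
        es._eigen()
        return es

    def tell(self, candidates: np.ndarray, losses) -> None:
        """Rank-based distribution update; ties keep sampling order."""
        losses = np.asarray(losses, dtype=float)
        if not np.all(np.isfinite(losses)):
            raise ValueError("losses must be finite (use a penalty cap)")
        candidates = np.asarray(candidates, dtype=float)
        order = np.argsort(losses, kind="stable")[:self.mu]
        sel = candidates[order]

        old_mean = self.mean
        self.mean = self.weights @ sel

        d = self.dim
        y = (self.mean - old_mean) / self.sigma
        c_inv_sqrt_y = self.B @ ((self.B.T @ y) / self.D)
        self.p_sigma = ((1 - self.c_sigma) * self.p_sigma
                        + np.sqrt(self.c_sigma * (2 - self.c_sigma)
                                  * self.mu_eff) * c_inv_sqrt_y)
        h_sigma = (np.linalg.norm(self.p_sigma)
                   / np.sqrt(1 - (1 - self.c_sigma)
                             ** (2 * (self.generation + 1)))
                   < (1.4 + 2 / (d + 1)) * self.chi_n)
        self.p_c = ((1 - self.c_c) * self.p_c
                    + h_sigma * np.sqrt(self.c_c * (2 - self.c_c)
                                        * self.mu_eff) * y)

        ys = (sel - old_mean) / self.sigma
        rank_mu = (ys.T * self.weights) @ ys
        delta_h = (1 - h_sigma) * self.c_c * (2 - self.c_c)
        self.C = ((1 - self.c_1 - self.c_mu) * self.C
                  + self.c_1 * (np.outer(self.p_c, self.p_c)
                                + delta_h * self.C)
                  + self.c_mu * rank_mu)
        self.sigma *= np.exp((self.c_sigma / self.d_sigma)
                             * (np.linalg.norm(self.p_sigma) / self.chi_n - 1))
        self.generation += 1
        self._eigen()


def correlation_matrix(C: np.ndarray) -> np.ndarray:
    """Covariance normalized to unit diagonal (the interpretation panels).

    Rows/columns with zero variance are masked with NaN off-diagonal.
    """
    C = np.asarray(C, dtype=float)
    d = np.sqrt(np.diag(C))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = C / np.outer(d, d)
    R[~np.isfinite(R)] = np.nan
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0, out=R) if np.isfinite(R).all() else R


@dataclass
class MetaTrajectory:
    """Per-iteration record of one meta-learning run."""

    iterations: list = field(default_factory=list)   # dict records
    snapshots: dict = field(default_factory=dict)    # iter -> C copy
    best_theta: Optional[np.ndarray] = None
    best_loss: float = np.inf
    best_iteration: int = -1

    def record(self, i, es: CMAES, losses, best_candidate):
        self.iterations.append({
            "iteration": i,
            "loss_min": float(np.min(losses)),
            "loss_mean": float(np.mean(losses)),
            "loss_best_so_far": float(min(self.best_loss, np.min(losses))),
            "sigma": es.sigma,
            "mean": es.mean.copy(),
            "best_candidate": np.asarray(best_candidate).copy(),
        })

    def to_frame(self):
        import pandas as pd
        rows = []
        for rec in self.iterations:
            row = {k: v for k, v in rec.items()
                   if k not in ("mean", "best_candidate")}
            row.update({f"theta_{j}": v for j, v in enumerate(rec["mean"])})
            rows.append(row)
        return pd.DataFrame(rows)

    def state_dict(self) -> dict:
        return {
            "iterations": [dict(rec, mean=rec["mean"].tolist(),
                                best_candidate=rec["best_candidate"].tolist())
                           for rec in self.iterations],
            "snapshots": {str(k): v.tolist()
                          for k, v in self.snapshots.items()},
            "best_theta": (None if self.best_theta is None
                           else self.best_theta.tolist()),
            "best_loss": self.best_loss,
            "best_iteration": self.best_iteration,
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "MetaTrajectory":
        traj = cls()
        traj.iterations = [
            dict(rec, mean=np.array(rec["mean"]),
                 best_candidate=np.array(rec["best_candidate"]))
            for rec in state["iterations"]]
        traj.snapshots = {int(k): np.array(v)
                          for k, v in state["snapshots"].items()}
        traj.best_theta = (None if state["best_theta"] is None
                           else np.array(state["best_theta"]))
        traj.best_loss = state["best_loss"]
        traj.best_iteration = state["best_iteration"]
        return traj


def run_meta_learning(
    space: str = "small",
    task=None,
    plastic_blocks=("ie",),
    variant: Optional[str] = None,
    base_config=None,
    n_trials: int = 4,
    popsize: Optional[int] = None,
    sigma0: float = 0.3,
    max_iterations: int = 40,
    converge_loss: Optional[float] = 0.02,
    seed: int = 0,
    frozen_seed: int = 0,
    snapshot_iterations=(10, 15, 20),
    lambda_l1: Optional[float] = None,
    callback: Optional[Callable] = None,
    objective: Optional[Callable] = None,
    refine_top: int = 3,
    refine_trials: int = 8,
    checkpoint: Optional[dict] = None,
):
    """Full outer loop: quiescent start, ask/evaluate/tell, trajectory log.

    Starts from the quiescent rule (no weight changes), runs CMA-ES with
    generation size ``popsize`` (default twice the parameter count) for up
    to ``max_iterations`` generations, and stops early once the best
    candidate loss falls below ``converge_loss``.  Candidates that raise
    are scored at the task's penalty cap so the run continues.

    Because each candidate is scored on only ``n_trials`` randomized
    networks, the generation-best loss is a noisy estimate; the run
    therefore ends with a refinement pass that re-evaluates the
    ``refine_top`` best candidates on ``refine_trials`` fresh trials and
    returns the winner, which markedly reduces winner's-curse bias in the
    reported rule.

    Returns ``(trajectory, best_rules)`` where ``best_rules`` maps each
    plastic block to its decoded best rule.  ``objective(theta, trial_seeds)``
    may replace the episode-based loss (used by optimizer benchmarks).

    ``checkpoint`` (a dict of ``{"es": CMAES.state_dict(), "trajectory":
    MetaTrajectory.state_dict()}``, as written by the experiment driver)
    resumes an interrupted run at the recorded generation; the seed ladder
    is reconstructed from ``seed``, so a resumed run matches an
    uninterrupted one.
    """
    from .tasks import StabilityTask

    if task is None:
        task = StabilityTask()
    d = space_dim(space) * len(plastic_blocks)
    x0 = np.concatenate([encode_theta(init_quiescent(space, frozen_seed))
                         for _ in plastic_blocks])
    master = np.random.SeedSequence(seed)
    es_seed, eval_seed = (int(s.generate_state(1)[0] % (2**31 - 1))
                          for s in master.spawn(2))
    if checkpoint is not None:
        es = CMAES.from_state_dict(checkpoint["es"])
        traj = MetaTrajectory.from_state_dict(checkpoint["trajectory"])
        start = es.generation
    else:
        es = CMAES(x0, sigma0=sigma0, popsize=popsize or 2 * d, seed=es_seed)
        traj = MetaTrajectory()
        start = 0
    if lambda_l1 is not None and hasattr(task, "lambda_l1"):
        from dataclasses import replace as _replace
        task = _replace(task, lambda_l1=lambda_l1)

    for i in range(start, max_iterations):
        candidates = es.ask()
        # common random numbers: one trial-seed set per generation
        gen_base = trial_seed(eval_seed, i)
        seeds = [trial_seed(gen_base, k) for k in range(n_trials)]
        losses = np.empty(es.popsize)
        for k, theta in enumerate(candidates):
            if objective is not None:
                losses[k] = objective(theta, seeds)
            else:
                try:
                    losses[k] = evaluate_candidate(
                        theta, space, task, plastic_blocks,
                        n_trials=n_trials, variant=variant,
                        base_config=base_config, frozen_seed=frozen_seed,
                        trial_seeds=seeds)
                except Exception:
                    losses[k] = getattr(task, "penalty_cap", 10.0)
        k_best = int(np.argmin(losses))
        if losses[k_best] < traj.best_loss:
            traj.best_loss = float(losses[k_best])
            traj.best_theta = candidates[k_best].copy()
            traj.best_iteration = i
        traj.record(i, es, losses, candidates[k_best])
        es.tell(candidates, losses)
        if i in snapshot_iterations:
            traj.snapshots[i] = es.C.copy()
        if callback is not None:
            callback(i, es, losses, traj)
        if converge_loss is not None and traj.best_loss <= converge_loss:
            break

    # refinement pass: re-score the strongest candidates on fresh trials
    top_candidates = sorted(
        ((rec["loss_min"], rec["iteration"], rec["best_candidate"])
         for rec in traj.iterations), key=lambda rec: rec[0])
    finalists = top_candidates[:max(1, refine_top)]
    if len(finalists) > 1 and objective is None and refine_trials > 0:
        seeds = [trial_seed(eval_seed, 1_000_003 + k)
                 for k in range(refine_trials)]
        refined = []
        for loss0, it, th in finalists:
            try:
                loss = evaluate_candidate(
                    th, space, task, plastic_blocks,
                    n_trials=refine_trials, variant=variant,
                    base_config=base_config, frozen_seed=frozen_seed,
                    trial_seeds=seeds)
            except Exception:
                loss = getattr(task, "penalty_cap", 10.0)
            refined.append((loss, it, th))
        refined.sort(key=lambda rec: rec[0])
        traj.best_loss, traj.best_iteration, traj.best_theta = refined[0]

    if traj.best_theta is None:
        traj.best_theta = x0
        traj.best_loss = np.inf
    dd = space_dim(space)
    best_rules = {
        block: decode_theta(traj.best_theta[k * dd:(k + 1) * dd], space,
                            frozen_seed=frozen_seed)
        for k, block in enumerate(plastic_blocks)}
    return traj, best_rules
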