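"""Experiment configuration: YAML schema, validation, hashing, artifacts.

A single config file drives a whole meta-learning (or evaluation) run.  The
resolved config — defaults filled in — is dumped next to the results
together with a content hash and the seed ladder, so every output file is
reproducible from (config, master seed) alone.

Schema (all keys optional unless noted)::

    variant: vogels | zenke          # default depends on task
    scale: desk | full               # topology preset (default desk)
    topology:                        # overrides of the preset
      n_exc: 400
      ...
    space: small | big | mlp         # rule space (required for meta-learn)
    plastic_blocks: [ie]             # subset of ee, ei, ie, ii
    task:
      kind: stability | familiarity  # required
      duration_ms: 10000             # any StabilityTask/FamiliarityTask field
      ...
    es:
      popsize: 12                    # default 2 * parameter count
      n_trials: 4
      sigma0: 0.3
      max_iterations: 40
      converge_loss: 0.02
      snapshot_iterations: [10, 15, 20]
    lambda_l1: 0.01
    frozen_seed: 0                   # MLP hidden-layer seed
    seed: 1                          # master seed
    outdir: results/run1
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .networks import TopologyConfig, desk_topology, full_topology
from .rules import RuleAssignment, space_dim
from .tasks import FamiliarityTask, StabilityTask

__all__ = ["ExperimentConfig", "load_config", "run_experiment"]

_ES_DEFAULTS = dict(popsize=None, n_trials=4, sigma0=0.3, max_iterations=40,
                    converge_loss=0.02, snapshot_iterations=[10, 15, 20])


@dataclass
class ExperimentConfig:
    task_kind: str = "stability"
    variant: Optional[str] = None
    scale: str = "desk"
    topology_overrides: dict = field(default_factory=dict)
    space: str = "small"
    plastic_blocks: tuple = ("ie",)
    task_overrides: dict = field(default_factory=dict)
    es: dict = field(default_factory=lambda: dict(_ES_DEFAULTS))
    lambda_l1: float = 0.01
    frozen_seed: int = 0
    seed: int = 1
    outdir: str = "results/run"

    def __post_init__(self):
        if self.task_kind not in ("stability", "familiarity"):
            raise ValueError(f"unknown task kind {self.task_kind!r}")
        if self.scale not in ("desk", "full"):
            raise ValueError(f"unknown scale preset {self.scale!r}")
        space_dim(self.space)   # validates
        for b in self.plastic_blocks:
            if b not in RuleAssignment.BLOCKS:
                raise ValueError(f"unknown plastic block {b!r}")
        if not self.plastic_blocks:
            raise ValueError("meta-learning needs at least one plastic block")
        if self.variant is None:
            self.variant = "vogels" if self.task_kind == "stability" else "zenke"
        es = dict(_ES_DEFAULTS)
        es.update(self.es)
        self.es = es

    # -- derived objects ----------------------------------------------------
    def topology(self) -> TopologyConfig:
        make = desk_topology if self.scale == "desk" else full_topology
        return make(self.variant, **self.topology_overrides)

    def task(self):
        cls = StabilityTask if self.task_kind == "stability" else FamiliarityTask
        return cls(lambda_l1=self.lambda_l1, **self.task_overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["plastic_blocks"] = list(self.plastic_blocks)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> ExperimentConfig:
    """Parse and schema-validate a YAML experiment config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {
        "variant": raw.get("variant"),
        "scale": raw.get("scale", "desk"),
        "topology_overrides": raw.get("topology", {}) or {},
        "space": raw.get("space", "small"),
        "plastic_blocks": tuple(raw.get("plastic_blocks", ["ie"])),
        "task_overrides": dict(raw.get("task", {}) or {}),
        "es": dict(raw.get("es", {}) or {}),
        "lambda_l1": raw.get("lambda_l1", 0.01),
        "frozen_seed": raw.get("frozen_seed", 0),
        "seed": raw.get("seed", 1),
        "outdir": raw.get("outdir", "results/run"),
    }
    task = known["task_overrides"]
    if "kind" not in task:
        raise ValueError("config requires task.kind")
    kind = task.pop("kind")
    unknown = set(raw) - {"variant", "scale", "topology", "space",
                          "plastic_blocks", "task", "es", "lambda_l1",
                          "frozen_seed", "seed", "outdir"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentConfig(task_kind=kind, **known)


def run_experiment(config: ExperimentConfig, seed: Optional[int] = None,
                   resume: bool = False):
    """Execute a meta-learning run and write all artifacts.

    Writes to ``config.outdir``: the resolved config + manifest, the
    per-iteration trajectory CSV, the best rule JSON per plastic block,
    covariance snapshots (square CSV), and a per-iteration checkpoint.
    With ``resume=True`` an interrupted run continues from its checkpoint
    (refused if the stored config hash differs).  Returns
    (trajectory, best_rules).
    """
    from .meta import run_meta_learning
    from .rules import rule_to_json

    if seed is not None:
        config.seed = seed
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    ckpt_path = out / "checkpoint.json"
    checkpoint = None
    if resume and ckpt_path.exists():
        checkpoint = json.loads(ckpt_path.read_text())
        if checkpoint.get("config_hash") != config.hash():
            raise ValueError(
                "checkpoint was produced by a different configuration; "
                "refusing to resume")

    def _save_checkpoint(i, es, losses, traj):
        ckpt_path.write_text(json.dumps({
            "config_hash": config.hash(),
            "es": es.state_dict(),
            "trajectory": traj.state_dict(),
        }))

    traj, best = run_meta_learning(
        space=config.space, task=config.task(),
        plastic_blocks=config.plastic_blocks, variant=config.variant,
        base_config=config.topology(),
        n_trials=config.es["n_trials"], popsize=config.es["popsize"],
        sigma0=config.es["sigma0"],
        max_iterations=config.es["max_iterations"],
        converge_loss=config.es["converge_loss"],
        seed=config.seed, frozen_seed=config.frozen_seed,
        snapshot_iterations=tuple(config.es["snapshot_iterations"]),
        callback=_save_checkpoint, checkpoint=checkpoint)

    traj.to_frame().to_csv(out / "trajectory.csv", index=False)
    for block, rule in best.items():
        (out / f"best_rule_{block}.json").write_text(rule_to_json(rule))
    for it, C in traj.snapshots.items():
        np.savetxt(out / f"covariance_iter{it:03d}.csv", C, delimiter=",")
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "best_loss": traj.best_loss,
        "best_iteration": traj.best_iteration,
        "iterations_run": len(traj.iterations),
    }
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return traj, best
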