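# metaplast

**Meta-learning synaptic plasticity rules in recurrent E/I spiking
networks with evolutionary strategies.**

The rules by which synapses change remain one of neuroscience's central
unknowns: rules fitted to single-synapse experiments often fail to produce
the network-level functions they are supposed to explain. `metaplast`
inverts the problem. Instead of hand-tuning a plasticity rule and checking
what a network does with it, it *searches* for rules that make a network do
something — hold its firing rate at a set point, or respond more strongly
to a familiar stimulus than to a novel one — and then provides the tools to
interpret what was found. It is aimed at computational neuroscientists
studying plasticity function, homeostasis and memory in spiking networks.

## What it does

Two nested loops:

* **Inner loop** — recurrent networks of conductance-based
  leaky-integrate-and-fire neurons (two variants: an AMPA/GABA network with
  fixed thresholds and a NMDA/adaptive-threshold network), driven by
  Poisson inputs, with spike-triggered plasticity on any subset of the four
  synapse types (E→E, E→I, I→E, I→I). Simulated with a numba kernel at
  dt = 0.1 ms; bit-reproducible under seeds.
* **Outer loop** — CMA-ES over the parameters θ of the plasticity rule:
  sample a generation of candidate rules from N(θ*, σ²C), score each by the
  mean task loss over randomized networks, update mean, covariance and step
  size from the ranking. The adapted covariance, normalized to correlation
  form, doubles as a readout of parameter interdependencies.

Three rule parameterizations of increasing expressivity are built in:

| space   | θ dim | form |
|---------|-------|------|
| `small` | 6     | dw/dt = αS_i + βS_j + γS_j x_i + κS_i x_j, learnable trace τ's (log-encoded) |
| `big`   | 21    | separable polynomial factors in weight, ⟨V_j⟩, codependent terms C_E, C_I, and 10/100 ms traces |
| `mlp`   | 11    | the same variables through a frozen 6→50→4 sigmoid MLP; only output weights, bias and a shared learning rate are tuned |

A mean-field module gives closed-form fixed-point rates for the small
polynomial space (e.g. I→E: r*_exc = −α r_inh / (β + H r_inh) with
H = κτ_post + γτ_pre) and inverts them to construct rules with a prescribed
set point — the analytic anchor the simulations are validated against.

## Worked example: discovering a homeostatic I→E rule

```python
import metaplast as mp
from metaplast.tasks import StabilityTask, run_stability_episode

task = StabilityTask(duration_ms=10_000.0)      # 10 s episodes, 10 Hz target
traj, best = mp.run_meta_learning(
    space="small", task=task, plastic_blocks=("ie",), variant="vogels",
    base_config=mp.desk_topology("vogels"),     # 400 E / 100 I / 500 inputs
    n_trials=4, popsize=12, max_iterations=40, seed=1)

rule = best["ie"]
print(f"best loss {traj.best_loss:.3f} after {len(traj.iterations)} iterations")
print(rule)

res = run_stability_episode(mp.RuleAssignment(rules={"ie": rule}),
                            seed=mp.trial_seed(1, 777), task=task)
print(f"fresh-episode E rate, final 5 s: {res.mean_rate('e', 5000.0):.2f} Hz")
```

Output from this exact invocation:

```
best loss 0.042 after 40 iterations
SmallPolyRule(alpha=-0.3224245655370023, beta=0.6297331729465167,
              gamma=0.5667998424624576, kappa=0.7664472811871474,
              tau_pre=8.599921866663234, tau_post=11.549815786891193)
fresh-episode E rate, final 5 s: 8.85 Hz
```

The loss is the normalized squared deviation of the excitatory population
rate from the 10 Hz target (an all-silent network scores 1), plus an L1
penalty on the amplitudes; 0.042 means the discovered rule holds the
population within about 2 Hz RMS of target across randomized networks. The
fresh episode — new connectivity, new weights, new drive — confirms the
rule generalizes: 8.85 Hz, within the ±2 Hz band used by the acceptance
suite. Note the learned rule is *one* member of a degenerate family:
different seeds return different parameter vectors with the same network
behavior, while α < 0 (the mean-field stability condition: depression on
presynaptic-only activity) tends to be conserved along with the
anti-correlation between the non-Hebbian amplitudes in the adapted
covariance.

Interpretation tools:

```python
curve = mp.pre_post_curve(rule)                 # STDP-style pairing curve
pred  = mp.meanfield_rate("ie", rule, counterpart_rate_hz=20.0)
R     = mp.correlation_matrix(traj.snapshots[15])
```

The same machinery runs from the shell via the `metaplast` CLI
(`meta-learn`, `evaluate`, `protocol-curve`, `meanfield`, `summarize`) with
YAML experiment configs; every run dumps its resolved config, seed ladder
and a content hash next to its artifacts, so outputs are reproducible from
the config file alone.

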