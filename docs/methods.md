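# Methods

`metaplast` meta-learns synaptic plasticity rules in recurrent spiking
networks: an inner loop embeds parameterized rules in conductance-based
excitatory/inhibitory (E/I) networks performing a task, and an outer
evolutionary loop (CMA-ES) adapts the rule parameters to minimize a task
loss. This note records the models, the numerical scheme, the defaults and
why they were chosen, and what the package's synthetic benchmarks do and do
not establish.

## Network models

Both variants are recurrent networks of conductance-based leaky
integrate-and-fire neurons driven by external Poisson inputs, with sparse
Bernoulli connectivity and unitless synaptic weights that scale conductance
increments.

**Vogels-style network.** Membrane potential of neuron *j* follows

    tau_m dV_j/dt = -(V_j - V_rest) - g_j^AMPA (V_j - E_AMPA)
                                    - g_j^GABA (V_j - E_GABA)

with tau_m = 20 ms, V_rest = -60 mV, E_AMPA = 0 mV, E_GABA = -80 mV,
threshold -50 mV, reset to rest, refractory 5 ms (clamped to rest, no
integration). Conductances decay exponentially (tau_AMPA = 5 ms,
tau_GABA = 10 ms) and jump by the presynaptic weight at spikes. Full scale:
8000 E / 2000 I, 2% recurrent connectivity, 5000 Poisson inputs at 5%
connectivity and 7 Hz.

**Zenke-style network.** Same membrane equation with V_rest = -70 mV and a
composite excitatory conductance g_E = a g_AMPA + (1-a) g_NMDA (a = 0.23),
where g_NMDA low-passes g_AMPA with tau_NMDA = 100 ms. Spiking uses an
adaptive threshold: base -50 mV, incremented by 100 mV at each spike,
relaxing back exponentially. The relaxation time constant is not fixed by
the model definition we follow; the default here is 5 ms (the order of
magnitude of fast spike-threshold adaptation) and it is exposed in
`ZenkeNeuronParams`. Full scale: 4096 E / 1024 I, 10% recurrent
connectivity, 5% input connectivity. Reset is to -70 mV with no refractory
period.

Self-connections are excluded (standard practice; avoids autapse
pathologies). External inputs project to both populations at the same
density. Synaptic delays are not modeled.

## Integration scheme

Forward Euler at dt = 0.1 ms on the membrane equation, using start-of-step
conductances; conductance, adaptive-threshold and synaptic-trace decay use
the exact exponential factor per step, so pure decay is exact and only the
membrane update carries Euler error. Spike effects (conductance increments,
plasticity updates, trace bumps) are applied at the end of the step in
which the spike occurs. A step's event order is: membrane update and spike
detection -> decay -> conductance increments -> auxiliary-variable updates
-> plasticity (all pre-triggered updates, then all post-triggered updates)
-> trace bumps of the step's spikers. Non-finite membrane potentials or
weight updates truncate the episode and set a divergence flag that the loss
maps to a penalty cap.

The simulation kernel is compiled with numba and is RNG-free: external
Poisson spikes are pre-generated (per-bin Bernoulli semantics, sampled
exactly via per-neuron Binomial counts over bins), so an episode is a pure
function of its inputs and seeds, bit-identical across runs.

## Plasticity rule spaces

All rules apply event-wise updates at pre-/postsynaptic spikes and hard-clip
weights to per-block bounds (default [0, 10]).

**Small polynomial (6 parameters).** dw/dt = alpha S_i + beta S_j +
gamma S_j x_i + kappa S_i x_j with traces x integrating the spike trains
with learnable tau_pre, tau_post (optimized as natural logarithms so any
real parameter decodes to a positive time constant). alpha/beta are
non-Hebbian (single-sided), gamma/kappa Hebbian (coincidence-sensitive).

**Big polynomial (21 parameters).** Spike-triggered updates multiply
separable factors in: the weight (up to quadratic), the low-passed membrane
potential <V_j> (tau 100 ms), codependent terms C_E = <g_E (E_E - V_j)> and
C_I = <g_I (E_I - V_j)> (tau 10 / 100 ms) representing neighboring-synapse
activity, and short/long traces (tau fixed at 10 / 100 ms), with a cubic
term in the postsynaptic long trace of the post factor. Setting theta_0 =
alpha, theta_0 theta_9 = kappa, theta_10 = beta, theta_10 theta_18 = gamma
and all else to zero recovers the small polynomial at 10 ms time constants;
this reduction is enforced by test to < 1e-10.

**MLP (11 parameters).** The same six synaptic variables feed two
feedforward networks (pre- and post-triggered), each 6 -> 50 sigmoid -> 4
sigmoid -> linear. Hidden weights are drawn once from
U(-1/sqrt(n_in), 1/sqrt(n_in)) under a recorded seed, frozen, and shared
between the two MLPs; only the 4 output weights + 1 bias of each MLP and a
common learning rate are optimized. The frozen seed is serialized with the
rule because a learned parameter vector is meaningless without it. Hidden
biases are fixed at zero.

**Conventions.** At a spike, the spiking neuron's own trace is read before
its +1 increment; when pre and post spikes share a time bin, pre-triggered
updates are applied first, and both read pre-bump traces. These choices
change same-bin interactions and are pinned by tests. Weight updates are
scaled by a per-block factor (default 1.0, no hidden renormalization).

## Tasks and losses

The loss formulas are this package's own documented choices — the inner-loop
objective is only constrained qualitatively by the experimental design the
package reproduces — and each term can be swapped via configuration without
touching the optimizer.

**Stability.** Each trial randomizes the external rate (U[4, 10] Hz), the
initial mean weight of every block (U[0.05, 0.5]) and the connectivity
realization; the network then runs with plasticity on. Loss =
mean over 100-ms bins in the trailing half of the episode of
(r_E - target)^2 / target^2, plus lambda * ||amplitudes||_1
(lambda = 0.01), clipped to the penalty cap. Target 10 Hz. An all-silent
network scores exactly 1. The cap (10 = ten times the all-silent loss) is
assigned to diverged episodes and bounds all regular losses, keeping the
rank-based optimizer well-defined.

**Familiarity detection.** A familiar stimulus (10% of input neurons at 4x
background rate) is presented 10 times for 1 s with 0.5 s gaps, followed by
a 2 s break and then 1 s novel and familiar probes (disjoint subsets);
plasticity is frozen during probes so they measure the learned state. Loss
= hinge max(0, r_novel + margin - r_familiar)/margin (margin 5 Hz) + a
plausibility term penalizing mean training rates outside [1, 30] Hz + the
same L1 term, capped identically. Without plasticity the protocol is
symmetric by construction; a paired test across seeds verifies no
familiar/novel asymmetry, which pins any learned asymmetry on the rule.

## Outer loop

CMA-ES ((mu/mu_w, lambda) with weighted recombination, rank-one + rank-mu
covariance adaptation and cumulative step-size adaptation, in the standard
tutorial formulation) is implemented in `metaplast.meta`; no third-party
optimizer backs it. Generation size defaults to twice the parameter count
(12 / 42 / 22 for the three spaces), sigma_0 = 0.3 in encoded units, start
at the quiescent rule (all amplitudes zero, so the first generation
explores around "no plasticity"). Each candidate's fitness is the mean loss
over N_trials randomized networks (default 4, within the 4-10 convention);
all candidates of a generation share trial seeds (common random numbers),
which sharpens the ranking the update consumes. The seed ladder (master ->
per-generation -> per-trial) is deterministic, making whole trajectories
pure functions of (config, master seed). A run stops early once the best
candidate loss reaches 0.02 (about the noise floor of the stability loss at
desk scale: bin-level Poisson fluctuations contribute ~0.003-0.01 and the
L1 term ~0.01).

Because 4-trial fitness is noisy, the generation-best candidate suffers
winner's-curse bias; the run ends with a refinement pass re-evaluating the
three best candidates on 8 fresh trials and returning the winner. The
covariance matrix is snapshotted at configurable iterations (default 10,
15, 20, before the loss typically plateaus) and normalized to correlation
form for interpretation; near convergence most entries approach +/-1.

## Mean-field module

For the small polynomial space, setting the expected drift of the rule to
zero under independent Poisson firing gives closed-form fixed points per
synapse type (see `metaplast.meanfield`), e.g. for I->E:
r_exc* = -alpha r_inh / (beta + H r_inh) with H = kappa tau_post +
gamma tau_pre (tau in seconds; the ms -> s conversion is centralized and
tested), stable when alpha < 0 and the denominator is positive. The E->E
and I->I expressions coincide and pin the inhibitory rate; they are
implemented exactly as derived. `solve_for_target` inverts these relations
for one free amplitude and refuses solutions violating the sign conditions.
The derivation ignores pre/post spike correlations and finite-size effects,
so simulated fixed points sit slightly above the prediction (about +1 Hz at
desk scale, within the +/-2 Hz acceptance band used by the validation
test).

## Scale presets and problem sizes

Full-scale networks (8000+2000 neurons, minutes of simulated time per
episode, thousands of episodes per optimization) are the production
setting. The package's tests and benchmarks run on the `desk` preset:
400 E / 100 I neurons, 500 Poisson inputs, 10 s episodes, 100-ms rate bins.
Two desk parameters deliberately deviate from proportional down-scaling:

* recurrent density is 10% rather than 2% for the Vogels variant. At 100
  inhibitory neurons, 2% density leaves each E neuron ~2 inhibitory
  afferents and ~13% of E neurons with none at all; those neurons are
  uncontrollable by I->E plasticity and place a ~20 Hz floor on the
  population rate. 10% density restores meaningful inhibitory in-degrees
  (~10) while keeping the network small.
* the external weight is 0.8 (vs ~0.3 at full scale) to compensate the
  10-fold smaller input in-degree and keep the drive fluctuation-driven,
  with static-network rates of roughly 30-60 Hz across the randomized
  drive range — comfortably above target, so homeostatic rules must act.

## What the synthetic benchmarks show — and what they do not

The generators emulate homogeneous Poisson drive, Bernoulli connectivity
and piecewise-constant stimulus schedules. Passing tests demonstrate that
the meta-learning machinery discovers rules that control population
dynamics in these conditions, that the plasticity implementation is exact
against closed-form oracles, and that mean-field predictions agree with
simulation at the stated tolerance. They do not show robustness to
structured (correlated, non-Poisson) input, metabolically realistic
weights, long-term retention beyond the simulated horizon, or that the
discovered rules match biological plasticity: the solution space is
degenerate, and distinct runs legitimately return different rules with
similar network behavior (only the parameter interdependencies, read from
the adapted covariance matrix, tend to be conserved — prominently the
anti-correlation between the non-Hebbian amplitudes).

## Known limitations

* The familiarity task can be solved by implausible dynamics (silent or
  saturated subpopulations); the plausibility band discourages but cannot
  exclude this, mirroring the general difficulty of fully constraining
  network dynamics through a scalar loss.
* CMA-ES is a local strategy: one solution per run, no systematic
  exploration of the degenerate solution manifold.
* Desk-scale rate control is granular (in-degree ~10); per-neuron rates
  fluctuate more than at full scale, which the +/-2 Hz tolerances of the
  validation tests absorb.
* The Euler membrane step at dt = 0.1 ms biases spike times by O(dt);
  tests compare against oracles that use the same step where exactness
  matters and use rate-level tolerances elsewhere.
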