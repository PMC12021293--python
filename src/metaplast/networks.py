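"""Recurrent conductance-based LIF E/I networks driven by Poisson inputs.

Two network variants are provided, differing in neuron model details:

* ``vogels`` — AMPA/GABA conductances, fixed threshold, 5 ms refractory
  clamp to rest (8000 E / 2000 I at full scale, 2% recurrent density).
* ``zenke`` — composite excitatory conductance ``g_E = a*g_AMPA +
  (1-a)*g_NMDA`` with the NMDA channel low-passing the AMPA channel, and an
  adaptive spike threshold incremented by 100 mV per spike (4096 E / 1024 I
  at full scale, 10% recurrent density, 5% input connectivity).

All simulations use forward Euler at dt = 0.1 ms with exact-exponential
conductance/trace decay; spike effects land at the end of their step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernel
from ._deltas import PRM_LEN, STATIC
from .rules import RuleAssignment

__all__ = [
    "VogelsNeuronParams", "ZenkeNeuronParams", "TopologyConfig",
    "NetworkTopology", "NetworkState", "SpikeRaster", "InputSegment",
    "EpisodeResult", "MembraneState", "build_network", "poisson_spikes",
    "step_network", "simulate_episode", "population_rate", "constant_input",
    "desk_topology", "full_topology",
]


@dataclass(frozen=True)
class VogelsNeuronParams:
    """Neuron constants of the Vogels-style network (mV, ms)."""

    tau_m: float = 20.0
    v_rest: float = -60.0
    e_ampa: float = 0.0
    e_gaba: float = -80.0
    v_th: float = -50.0
    tau_ref: float = 5.0
    tau_ampa: float = 5.0
    tau_gaba: float = 10.0

    def __post_init__(self):
        for name in ("tau_m", "tau_ref", "tau_ampa", "tau_gaba"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.e_gaba < self.v_rest < self.v_th < self.e_ampa):
            raise ValueError("require E_GABA < V_rest < V_th < E_AMPA")


@dataclass(frozen=True)
class ZenkeNeuronParams:
    """Neuron constants of the Zenke-style network (mV, ms).

    ``tau_th`` (threshold relaxation) is not fixed by the model definition
    we follow; the 5 ms default is the order of magnitude of fast spike-
    threshold adaptation and is exposed here for configuration.
    """

    tau_m: float = 20.0
    v_rest: float = -70.0
    e_exc: float = 0.0
    e_inh: float = -80.0
    v_reset: float = -70.0
    v_th_base: float = -50.0
    v_th_spike: float = 100.0
    tau_th: float = 5.0
    a_ampa_fraction: float = 0.23
    tau_ampa: float = 5.0
    tau_nmda: float = 100.0
    tau_gaba: float = 10.0

    def __post_init__(self):
        for name in ("tau_m", "tau_th", "tau_ampa", "tau_nmda", "tau_gaba"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.a_ampa_fraction <= 1.0:
            raise ValueError("a_ampa_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TopologyConfig:
    """Sizes, densities and initial-weight settings of one network build."""

    n_exc: int = 8000
    n_inh: int = 2000
    n_ext: int = 5000
    p_rec: float = 0.02
    p_ext: float = 0.05
    r_ext: float = 7.0          # Hz, background Poisson rate
    w_ext: float = 0.3          # external synaptic weight (unitless)
    #: mean initial weight per recurrent block; individual weights are drawn
    #: U(0.5*mean, 1.5*mean)
    w_mean: dict = field(default_factory=lambda: {
        "ee": 0.1, "ei": 0.1, "ie": 0.5, "ii": 0.5})

    def __post_init__(self):
        if not (0.0 < self.p_rec <= 1.0 and 0.0 < self.p_ext <= 1.0):
            raise ValueError("densities must lie in (0, 1]")
        if min(self.n_exc, self.n_inh, self.n_ext) <= 0:
            raise ValueError("population sizes must be positive")


def full_topology(variant: str = "vogels", **overrides) -> TopologyConfig:
    """Full-scale topology defaults for a network variant."""
    if variant == "vogels":
        base = dict(n_exc=8000, n_inh=2000, n_ext=5000, p_rec=0.02,
                    p_ext=0.05, w_ext=0.3)
    elif variant == "zenke":
        base = dict(n_exc=4096, n_inh=1024, n_ext=5000, p_rec=0.10,
                    p_ext=0.05, w_ext=0.3)
    else:
        raise ValueError(f"unknown network variant {variant!r}")
    base.update(overrides)
    return TopologyConfig(**base)


def desk_topology(variant: str = "vogels", **overrides) -> TopologyConfig:
    """Desk-scale preset: 400 E / 100 I / 500 Poisson inputs.

    Recurrent density is raised to 10% so that per-neuron in-degrees stay
    meaningful (at full-scale densities an appreciable fraction of desk-
    scale neurons would receive zero inhibitory afferents and be
    uncontrollable by I-to-E plasticity), and the external weight is raised
    to keep the external drive in the fluctuation-driven regime despite the
    smaller input in-degree.
    """
    if variant == "vogels":
        base = dict(n_exc=400, n_inh=100, n_ext=500, p_rec=0.10,
                    p_ext=0.05, w_ext=0.8)
    elif variant == "zenke":
        base = dict(n_exc=400, n_inh=100, n_ext=500, p_rec=0.10,
                    p_ext=0.05, w_ext=0.8)
    else:
        raise ValueError(f"unknown network variant {variant!r}")
    base.update(overrides)
    return TopologyConfig(**base)


@dataclass
class NetworkTopology:
    """Sparse connectivity of one network instance (CSR by presynaptic
    neuron, plus CSC synapse maps for the recurrent blocks)."""

    variant: str
    config: TopologyConfig
    csr: dict    # block -> (ptr, idx); blocks ee, ei, ie, ii, xe, xi
    csc: dict    # block -> (cptr, cidx, cpre); recurrent blocks only

    def n_synapses(self, block: str) -> int:
        return int(self.csr[block][1].size)


@dataclass
class NetworkState:
    """Mutable per-synapse weights of one network instance.

    Membrane/conductance state always starts at rest (V = V_rest, zero
    conductances, thresholds at base) and lives inside the episode kernel.
    """

    weights: dict          # block -> float64 array aligned with CSR idx
    ext_weights: dict      # "xe"/"xi" -> float64 array

    def copy(self) -> "NetworkState":
        return NetworkState({k: v.copy() for k, v in self.weights.items()},
                            {k: v.copy() for k, v in self.ext_weights.items()})


@dataclass
class SpikeRaster:
    """Spike events of one population as parallel (neuron, time) arrays."""

    neuron: np.ndarray
    time_ms: np.ndarray
    n_neurons: int
    duration_ms: float

    @property
    def n_spikes(self) -> int:
        return int(self.neuron.size)

    def spike_times(self, j: int) -> np.ndarray:
        return np.sort(self.time_ms[self.neuron == j])

    def to_text(self, path):
        np.savetxt(path, np.column_stack([self.neuron, self.time_ms]),
                   fmt="%d %.1f", header="neuron_id time_ms")


def _sparse_rows(rng, n_pre, n_post, p, exclude_self=False):
    """Bernoulli(p) block as CSR rows; optionally skips the diagonal."""
    counts = np.empty(n_pre, dtype=np.int64)
    cols = []
    avail = n_post - 1 if exclude_self else n_post
    for i in range(n_pre):
        k = rng.binomial(avail, p)
        c = rng.choice(avail, size=k, replace=False)
        if exclude_self:
            c = np.where(c >= i, c + 1, c)
        counts[i] = k
        cols.append(c)
    ptr = np.zeros(n_pre + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    idx = (np.concatenate(cols) if ptr[-1] else np.empty(0, np.int64)).astype(np.int64)
    return ptr, idx


def _csc_from_csr(ptr, idx, n_pre, n_post):
    """Synapse map grouped by postsynaptic neuron: (cptr, cidx, cpre)."""
    order = np.argsort(idx, kind="stable").astype(np.int64)
    cpre = np.repeat(np.arange(n_pre, dtype=np.int64), np.diff(ptr))[order]
    cptr = np.zeros(n_post + 1, dtype=np.int64)
    np.cumsum(np.bincount(idx, minlength=n_post), out=cptr[1:])
    return cptr, order, cpre


def build_network(variant: str, config: Optional[TopologyConfig] = None,
                  seed: int = 0):
    """Instantiate topology and initial state of one network.

    Connectivity is Bernoulli-sparse at the configured densities (self-
    connections excluded), initial recurrent weights are uniform around the
    per-block means, and the membrane state starts at rest.  Identical seeds
    give identical networks.
    """
    if variant not in ("vogels", "zenke"):
        raise ValueError(f"unknown network variant {variant!r}")
    if config is None:
        config = full_topology(variant)
    rng = np.random.default_rng(seed)
    n_e, n_i, n_x = config.n_exc, config.n_inh, config.n_ext

    csr, csc, weights = {}, {}, {}
    shapes = {"ee": (n_e, n_e, True), "ei": (n_e, n_i, False),
              "ie": (n_i, n_e, False), "ii": (n_i, n_i, True)}
    for block, (npre, npost, excl) in shapes.items():
        ptr, idx = _sparse_rows(rng, npre, npost, config.p_rec, excl)
        if idx.size == 0:
            raise ValueError(
                f"block {block!r} received zero connections; increase "
                "density or population sizes")
        csr[block] = (ptr, idx)
        csc[block] = _csc_from_csr(ptr, idx, npre, npost)
        m = config.w_mean[block]
        weights[block] = rng.uniform(0.5 * m, 1.5 * m, size=idx.size)

    ext_weights = {}
    for block, npost in (("xe", n_e), ("xi", n_i)):
        ptr, idx = _sparse_rows(rng, n_x, npost, config.p_ext)
        if idx.size == 0:
            raise ValueError(f"external block {block!r} has zero connections")
        csr[block] = (ptr, idx)
        ext_weights[block] = np.full(idx.size, config.w_ext)

    topology = NetworkTopology(variant, config, csr, csc)
    state = NetworkState(weights, ext_weights)
    return topology, state


def poisson_spikes(n_neurons: int, rate_hz: float, duration_ms: float,
                   dt_ms: float = 0.1, seed: int = 0,
                   rng: Optional[np.random.Generator] = None) -> SpikeRaster:
    """Homogeneous Poisson population raster, per-bin Bernoulli semantics.

    Each neuron spikes independently in each ``dt`` bin with probability
    ``rate * dt``.  Sampling draws a Binomial spike count per neuron and
    places the spikes in distinct bins, which is distributionally identical
    to looping over bins but much faster at realistic rates.
    """
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    p = rate_hz * dt_ms / 1000.0
    if p >= 1.0:
        raise ValueError(
            f"rate*dt = {p:.3f} >= 1: time bin too coarse for Bernoulli "
            "thinning")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_bins = int(round(duration_ms / dt_ms))
    neurons, times = [], []
    if p > 0:
        for j in range(n_neurons):
            k = rng.binomial(n_bins, p)
            if k:
                bins = rng.choice(n_bins, size=k, replace=False)
                neurons.append(np.full(k, j, dtype=np.int64))
                times.append(bins * dt_ms)
    if neurons:
        neuron = np.concatenate(neurons)
        time = np.concatenate(times)
        order = np.lexsort((neuron, time))
        neuron, time = neuron[order], time[order]
    else:
        neuron = np.empty(0, dtype=np.int64)
        time = np.empty(0)
    return SpikeRaster(neuron, time, n_neurons, duration_ms)


@dataclass(frozen=True)
class InputSegment:
    """Piecewise-constant external drive: per-neuron rates for a stretch of
    the episode, with plasticity optionally frozen (probe windows)."""

    duration_ms: float
    rates_hz: np.ndarray        # scalar or per-ext-neuron array
    plastic: bool = True
    label: str = ""


def constant_input(rate_hz: float, duration_ms: float,
                   label: str = "background") -> list:
    return [InputSegment(duration_ms, np.asarray(rate_hz, dtype=float),
                         plastic=True, label=label)]


@dataclass
class EpisodeResult:
    """Everything recorded from one inner-loop episode."""

    duration_ms: float
    dt_ms: float
    rate_bin_ms: float
    rate_times: np.ndarray       # bin centers, ms
    e_rates: np.ndarray          # Hz, population average per bin
    i_rates: np.ndarray
    weight_times: np.ndarray
    weight_means: np.ndarray     # (n_samples, 4): ee, ei, ie, ii
    e_raster: Optional[SpikeRaster]
    i_raster: Optional[SpikeRaster]
    initial_weights: dict
    final_weights: dict
    diverged: bool
    segments: list               # (label, t_start_ms, t_end_ms)

    def mean_rate(self, population: str = "e", t0: float = 0.0,
                  t1: Optional[float] = None) -> float:
        """Time-averaged population rate (Hz) over [t0, t1)."""
        if t1 is None:
            t1 = self.duration_ms
        r = self.e_rates if population == "e" else self.i_rates
        mask = (self.rate_times >= t0) & (self.rate_times < t1)
        if not mask.any():
            raise ValueError("empty rate window")
        return float(r[mask].mean())

    def segment_window(self, label: str):
        for lab, t0, t1 in self.segments:
            if lab == label:
                return t0, t1
        raise KeyError(f"no input segment labelled {label!r}")

    def weights_to_csv(self, path):
        """Write the per-block mean-weight traces as (time_ms, block, w)."""
        with open(path, "w") as fh:
            fh.write("time_ms,block,mean_w\n")
            for k, block in enumerate(("ee", "ei", "ie", "ii")):
                for t, w in zip(self.weight_times, self.weight_means[:, k]):
                    fh.write(f"{t},{block},{w}\n")


def _generate_ext_events(segments, n_ext, dt, rng):
    """Pre-generate external Poisson events (step-sorted) per segment."""
    steps_list, idx_list = [], []
    seg_end, seg_plastic, seg_bounds = [], [], []
    start_step = 0
    for seg in segments:
        n_steps = int(round(seg.duration_ms / dt))
        rates = np.broadcast_to(np.asarray(seg.rates_hz, dtype=float),
                                (n_ext,))
        p = rates * dt / 1000.0
        if np.any(p >= 1.0):
            raise ValueError("segment rate too high for the time step")
        for j in range(n_ext):
            if p[j] <= 0:
                continue
            k = rng.binomial(n_steps, p[j])
            if k:
                b = rng.choice(n_steps, size=k, replace=False)
                steps_list.append(start_step + b.astype(np.int64))
                idx_list.append(np.full(k, j, dtype=np.int64))
        seg_bounds.append((seg.label, start_step * dt,
                           (start_step + n_steps) * dt))
        start_step += n_steps
        seg_end.append(start_step)
        seg_plastic.append(1 if seg.plastic else 0)
    if steps_list:
        steps = np.concatenate(steps_list)
        idx = np.concatenate(idx_list)
        order = np.argsort(steps, kind="stable")
        steps, idx = steps[order], idx[order]
    else:
        steps = np.empty(0, dtype=np.int64)
        idx = np.empty(0, dtype=np.int64)
    return (steps, idx, np.asarray(seg_end, dtype=np.int64),
            np.asarray(seg_plastic, dtype=np.uint8), seg_bounds, start_step)


def simulate_episode(topology: NetworkTopology, state: NetworkState,
                     assignment: Optional[RuleAssignment] = None,
                     input_segments: Optional[list] = None,
                     dt_ms: float = 0.1, seed: int = 0,
                     neuron_params=None,
                     rate_bin_ms: float = 100.0,
                     weight_sample_ms: float = 500.0,
                     record_rasters: bool = False,
                     max_raster_events: int = 2_000_000) -> EpisodeResult:
    """Run one episode: Poisson drive, spiking dynamics, plasticity, recording.

    ``state`` is not mutated; the evolved weights are returned in the result.
    Fixed ``seed`` (driving only the external input realization) plus fixed
    inputs give bit-identical results.
    """
    if assignment is None:
        assignment = RuleAssignment()
    cfg = topology.config
    if input_segments is None:
        input_segments = constant_input(cfg.r_ext, 1000.0)

    rng = np.random.default_rng(seed)
    (ext_steps, ext_idx, seg_end, seg_plastic, seg_bounds,
     n_steps) = _generate_ext_events(input_segments, cfg.n_ext, dt_ms, rng)

    kinds = np.zeros(4, dtype=np.int64)
    prms = np.zeros((4, PRM_LEN))
    scales = np.ones(4)
    lo = np.zeros(4)
    hi = np.full(4, 10.0)
    mlp_W1 = np.zeros((1, 1))
    mlp_W2 = np.zeros((1, 1))
    frozen_seed = None
    for bi, block in enumerate(RuleAssignment.BLOCKS):
        rule = assignment.rule(block)
        lo[bi], hi[bi] = assignment.block_bounds(block)
        scales[bi] = assignment.block_scale(block)
        if rule is None:
            kinds[bi] = STATIC
            continue
        kinds[bi] = rule.kind
        prms[bi] = rule.packed()
        if rule.space == "mlp":
            if frozen_seed is not None and rule.frozen_seed != frozen_seed:
                raise ValueError("all MLP rules in one episode must share "
                                 "their frozen seed")
            frozen_seed = rule.frozen_seed
            mlp_W1, mlp_W2 = rule.frozen_weights()

    work = state.copy()
    if variant_code(topology.variant) == _kernel.VOGELS:
        p = neuron_params or VogelsNeuronParams()
        args = (p.tau_m, p.v_rest, p.e_ampa, p.e_gaba, p.v_th, p.v_rest,
                p.tau_ref, p.tau_ampa, p.tau_gaba, 1.0, 1.0, 0.0, 1.0)
    else:
        p = neuron_params or ZenkeNeuronParams()
        args = (p.tau_m, p.v_rest, p.e_exc, p.e_inh, p.v_th_base, p.v_reset,
                0.0, p.tau_ampa, p.tau_gaba, p.tau_nmda, p.a_ampa_fraction,
                p.v_th_spike, p.tau_th)

    rate_bin_steps = max(1, int(round(rate_bin_ms / dt_ms)))
    w_sample_steps = max(1, int(round(weight_sample_ms / dt_ms)))
    max_raster = max_raster_events if record_rasters else 0

    c = topology.csr
    cc = topology.csc
    out = _kernel.run_episode_kernel(
        variant_code(topology.variant), dt_ms, n_steps, *args,
        cfg.n_exc, cfg.n_inh,
        ext_steps, ext_idx, seg_end, seg_plastic,
        c["xe"][0], c["xe"][1], work.ext_weights["xe"],
        c["xi"][0], c["xi"][1], work.ext_weights["xi"],
        c["ee"][0], c["ee"][1], *cc["ee"],
        c["ei"][0], c["ei"][1], *cc["ei"],
        c["ie"][0], c["ie"][1], *cc["ie"],
        c["ii"][0], c["ii"][1], *cc["ii"],
        work.weights["ee"], work.weights["ei"],
        work.weights["ie"], work.weights["ii"],
        kinds, prms, scales, lo, hi, mlp_W1, mlp_W2,
        rate_bin_steps, w_sample_steps, max_raster)

    (e_counts, i_counts, w_times, w_means,
     re_n, re_t, ri_n, ri_t, diverged) = out

    duration = n_steps * dt_ms
    bin_ms = rate_bin_steps * dt_ms
    rate_times = (np.arange(e_counts.size) + 0.5) * bin_ms
    e_rates = e_counts / cfg.n_exc / (bin_ms / 1000.0)
    i_rates = i_counts / cfg.n_inh / (bin_ms / 1000.0)

    e_raster = i_raster = None
    if record_rasters:
        e_raster = SpikeRaster(re_n, re_t, cfg.n_exc, duration)
        i_raster = SpikeRaster(ri_n, ri_t, cfg.n_inh, duration)

    return EpisodeResult(
        duration_ms=duration, dt_ms=dt_ms, rate_bin_ms=bin_ms,
        rate_times=rate_times, e_rates=e_rates, i_rates=i_rates,
        weight_times=w_times, weight_means=w_means,
        e_raster=e_raster, i_raster=i_raster,
        initial_weights={k: v.copy() for k, v in state.weights.items()},
        final_weights=work.weights, diverged=bool(diverged),
        segments=seg_bounds)


def variant_code(variant: str) -> int:
    return _kernel.VOGELS if variant == "vogels" else _kernel.ZENKE


@dataclass
class MembraneState:
    """Plain-array membrane/conductance state of one neuron population.

    Reference (numpy) counterpart of the state the episode kernel evolves
    internally; :func:`step_network` advances it with the identical scheme,
    which lets single-step dynamics be inspected and tested directly.
    """

    v: np.ndarray
    g_ampa: np.ndarray
    g_gaba: np.ndarray
    g_nmda: np.ndarray
    v_th: np.ndarray
    refractory_steps: np.ndarray
    t_ms: float = 0.0

    @classmethod
    def at_rest(cls, n: int, params) -> "MembraneState":
        v_rest = params.v_rest
        v_th = getattr(params, "v_th", None) or params.v_th_base
        return cls(np.full(n, float(v_rest)), np.zeros(n), np.zeros(n),
                   np.zeros(n), np.full(n, float(v_th)),
                   np.zeros(n, np.int64))


def step_network(state: MembraneState, params, dt_ms: float = 0.1,
                 ampa_input: Optional[np.ndarray] = None,
                 gaba_input: Optional[np.ndarray] = None):
    """Advance one population by one time step; returns spiker indices.

    Mirrors the episode kernel exactly: forward-Euler membrane update with
    start-of-step conductances, threshold crossing and reset (refractory
    clamp for the fixed-threshold variant, threshold increment + exponential
    relaxation for the adaptive variant), exact-exponential conductance
    decay, then spike-triggered conductance increments (``ampa_input`` /
    ``gaba_input``: summed presynaptic weights arriving this step).
    """
    adaptive = isinstance(params, ZenkeNeuronParams)
    e_exc = params.e_exc if adaptive else params.e_ampa
    e_inh = params.e_inh if adaptive else params.e_gaba

    if adaptive:
        a = params.a_ampa_fraction
        g_e = a * state.g_ampa + (1.0 - a) * state.g_nmda
    else:
        g_e = state.g_ampa
    active = (state.refractory_steps == 0) if not adaptive else slice(None)

    v = state.v
    dv = (dt_ms / params.tau_m) * (-(v - params.v_rest)
                                   - g_e * (v - e_exc)
                                   - state.g_gaba * (v - e_inh))
    if adaptive:
        v = v + dv
    else:
        v = np.where(active, v + dv, params.v_rest)
        state.refractory_steps = np.maximum(state.refractory_steps - 1, 0)

    if adaptive:
        spikers = np.flatnonzero(v >= state.v_th)
        v[spikers] = params.v_reset
        state.v_th[spikers] += params.v_th_spike
        state.v_th = (params.v_th_base
                      + (state.v_th - params.v_th_base)
                      * np.exp(-dt_ms / params.tau_th))
    else:
        spikers = np.flatnonzero(active & (v >= params.v_th))
        v[spikers] = params.v_rest
        state.refractory_steps[spikers] = int(round(params.tau_ref / dt_ms))
    state.v = v

    state.g_ampa = state.g_ampa * np.exp(-dt_ms / params.tau_ampa)
    state.g_gaba = state.g_gaba * np.exp(-dt_ms / params.tau_gaba)
    if adaptive:
        state.g_nmda = state.g_nmda + (dt_ms / params.tau_nmda) * (
            state.g_ampa - state.g_nmda)
    if ampa_input is not None:
        state.g_ampa = state.g_ampa + ampa_input
    if gaba_input is not None:
        state.g_gaba = state.g_gaba + gaba_input
    if not np.all(np.isfinite(state.v)):
        raise FloatingPointError("membrane potential diverged")
    state.t_ms += dt_ms
    return spikers


def population_rate(raster: SpikeRaster, window_ms: float = 100.0,
                    sliding: bool = False):
    """Population firing rate (Hz) from a raster, tumbling or sliding window.

    Returns ``(times_ms, rates_hz)`` with times at window centers.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    if raster.n_neurons <= 0:
        raise ValueError("empty population")
    n_bins = max(1, int(np.ceil(raster.duration_ms / window_ms)))
    counts, edges = np.histogram(
        raster.time_ms, bins=n_bins, range=(0.0, n_bins * window_ms))
    rates = counts / raster.n_neurons / (window_ms / 1000.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if not sliding:
        return centers, rates
    # sliding = tumbling at dt resolution smoothed by a boxcar
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(rates, kernel, mode="same")
    return centers, smooth
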