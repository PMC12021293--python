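"""Interpretation of learned rules: pairing-protocol curves and episode
summaries (rates, regularity, weight-distribution shape)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .networks import EpisodeResult
from .rules import DEFAULT_CLAMPS, Rule, simulate_pair

__all__ = ["PrePostCurve", "pre_post_curve", "episode_summary",
           "EpisodeSummary"]


@dataclass
class PrePostCurve:
    """Weight change of an isolated pre/post spike pair versus delay.

    ``dt_grid`` is post-minus-pre delay in ms (symmetric around 0); for
    rules that depend on variables a two-spike protocol does not constrain
    (weight, low-passed voltage, codependent terms), the clamp values are
    explicit metadata of the curve.
    """

    dt_grid: np.ndarray
    dw: np.ndarray
    clamps: dict
    pair_count: int = 1
    pairing_interval_ms: float = 0.0

    def to_csv(self, path):
        np.savetxt(path, np.column_stack([self.dt_grid, self.dw]),
                   delimiter=",", header="dt_ms,dw", comments="")


def pre_post_curve(rule: Rule, dt_grid=None, dt_ms: float = 0.1,
                   clamps: Optional[dict] = "default",
                   pair_count: int = 1,
                   pairing_interval_ms: float = 1000.0) -> PrePostCurve:
    """Map pairing delay to total weight change from zeroed traces.

    For each delay ``Dt`` (post minus pre), ``pair_count`` pre/post spike
    pairs are simulated and the cumulative weight change of all
    spike-triggered updates is reported.  The default protocol uses a
    single pair; pair trains repeat at ``pairing_interval_ms``.
    """
    if dt_grid is None:
        dt_grid = np.arange(-50.0, 50.0 + 1e-9, 2.0)
    dt_grid = np.asarray(dt_grid, dtype=float)
    if clamps is None and rule.space in ("big", "mlp"):
        raise ValueError(
            f"{rule.space} rules depend on clamped auxiliary variables; "
            "pass explicit clamp values")
    cl = dict(DEFAULT_CLAMPS)
    if isinstance(clamps, dict):
        cl.update(clamps)

    t0 = 500.0   # settle offset so negative delays stay positive in time
    dw = np.empty_like(dt_grid)
    for n, delta in enumerate(dt_grid):
        pre = t0 + np.arange(pair_count) * pairing_interval_ms
        post = pre + delta
        _, _, total = simulate_pair(rule, pre, post, dt=dt_ms, clamps=cl)
        dw[n] = total
    return PrePostCurve(dt_grid, dw, clamps=cl, pair_count=pair_count,
                        pairing_interval_ms=pairing_interval_ms)


@dataclass
class EpisodeSummary:
    mean_rate_e: float
    mean_rate_i: float
    isi_cv_e: Optional[float]
    isi_cv_i: Optional[float]
    fraction_silent_e: Optional[float]
    weight_stats: dict            # block -> dict(mean, std, bimodality,
    #                               fraction_saturated)
    diverged: bool


def _isi_cv(raster) -> Optional[float]:
    """Mean per-neuron ISI coefficient of variation (needs >= 3 spikes)."""
    if raster is None or raster.n_spikes == 0:
        return None
    cvs = []
    for j in np.unique(raster.neuron):
        t = np.sort(raster.time_ms[raster.neuron == j])
        if t.size >= 3:
            isi = np.diff(t)
            m = isi.mean()
            if m > 0:
                cvs.append(isi.std() / m)
    return float(np.mean(cvs)) if cvs else None


def _bimodality(w: np.ndarray) -> float:
    """Sarle's bimodality coefficient: (skew^2 + 1) / adjusted kurtosis.

    Values above ~0.555 (the uniform distribution's score) suggest
    bimodality; a weight distribution split between 0 and the cap scores
    near 1.
    """
    n = w.size
    if n < 4 or np.allclose(w, w[0]):
        return np.nan
    g1 = stats.skew(w)
    g2 = stats.kurtosis(w)   # excess kurtosis
    return float((g1**2 + 1) / (g2 + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def episode_summary(result: EpisodeResult, bounds: Optional[dict] = None,
                    saturation_tol: float = 1e-6) -> EpisodeSummary:
    """Per-population activity metrics and per-block weight-shape metrics.

    All metrics are invariant under relabelling of neuron indices.
    """
    weight_stats = {}
    for k, block in enumerate(("ee", "ei", "ie", "ii")):
        w = result.final_weights[block]
        hi = (bounds or {}).get(block, (0.0, 10.0))[1]
        weight_stats[block] = {
            "mean": float(w.mean()),
            "std": float(w.std()),
            "bimodality": _bimodality(w),
            "fraction_saturated": float(np.mean(w >= hi - saturation_tol)),
        }
    frac_silent = None
    if result.e_raster is not None:
        active = np.unique(result.e_raster.neuron).size
        frac_silent = 1.0 - active / result.e_raster.n_neurons
    return EpisodeSummary(
        mean_rate_e=result.mean_rate("e"),
        mean_rate_i=result.mean_rate("i"),
        isi_cv_e=_isi_cv(result.e_raster),
        isi_cv_i=_isi_cv(result.i_raster),
        fraction_silent_e=frac_silent,
        weight_stats=weight_stats,
        diverged=result.diverged)
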