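"""Mean-field fixed points of the small polynomial rule per synapse type.

Setting the expected weight drift of the pair-based rule to zero under
independent Poisson pre/post activity links the amplitudes to steady-state
population rates.  With the effective Hebbian combination

    H = kappa * tau_post + gamma * tau_pre        (tau in seconds)

the fixed points for each synapse type plastic in isolation are

    I->E:  r_exc* = -alpha * r_inh / (beta + H * r_inh)
    E->E:  r_inh* = -(alpha + beta) / H
    E->I:  r_inh* = -alpha * r_exc / (beta + H * r_exc)
    I->I:  r_inh* = -(alpha + beta) / H

with the additional stability conditions, for I->E, ``alpha < 0`` and
``beta + H * r_inh > 0``.  The E->E and I->I expressions both pin the
*inhibitory* rate; they are implemented exactly as derived, not
reinterpreted.  Time constants are stored in ms throughout the package and
converted to seconds here (centralized in :func:`hebbian_combination`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .rules import SmallPolyRule

__all__ = ["MeanFieldPrediction", "hebbian_combination", "meanfield_rate",
           "solve_for_target"]

SYNAPSE_TYPES = ("ie", "ee", "ei", "ii")
#: synapse types whose fixed point needs the counterpart population's rate
NEEDS_COUNTERPART = ("ie", "ei")


def hebbian_combination(rule: SmallPolyRule) -> float:
    """H = kappa*tau_post + gamma*tau_pre with tau converted ms -> s."""
    return rule.kappa * rule.tau_post / 1000.0 + rule.gamma * rule.tau_pre / 1000.0


@dataclass(frozen=True)
class MeanFieldPrediction:
    synapse_type: str
    rate_hz: Optional[float]       # None when the fixed point is undefined
    stable: Optional[bool]         # None when no printed condition applies
    hebbian_combination: float
    conditions: dict

    @property
    def defined(self) -> bool:
        return self.rate_hz is not None


def meanfield_rate(synapse_type: str, rule: SmallPolyRule,
                   counterpart_rate_hz: Optional[float] = None
                   ) -> MeanFieldPrediction:
    """Predicted steady-state rate for one synapse type plastic in isolation.

    ``ie``/``ei`` predictions generally require the counterpart population
    rate (inhibitory/excitatory respectively); when ``beta == 0`` the
    dependence cancels and the counterpart may be omitted.  A vanishing
    denominator yields an undefined prediction rather than an error.
    """
    if synapse_type not in SYNAPSE_TYPES:
        raise ValueError(f"unknown synapse type {synapse_type!r}")
    H = hebbian_combination(rule)
    a, b = rule.alpha, rule.beta
    conditions = {}

    if synapse_type in ("ee", "ii"):
        rate = None if H == 0 else -(a + b) / H
        return MeanFieldPrediction(synapse_type, rate, None, H, conditions)

    r = counterpart_rate_hz
    if r is None:
        if b != 0:
            raise ValueError(
                f"{synapse_type!r} prediction needs the counterpart rate "
                "when beta != 0")
        rate = None if H == 0 else -a / H
        denom_pos = H > 0            # beta + H*r > 0 for any r > 0
    else:
        denom = b + H * r
        rate = None if denom == 0 else -a * r / denom
        denom_pos = denom > 0
    denom_pos = bool(denom_pos)
    if synapse_type == "ie":
        conditions = {"alpha_negative": bool(a < 0),
                      "denominator_positive": denom_pos}
        stable = bool(a < 0) and denom_pos
    else:
        conditions = {"denominator_positive": denom_pos}
        stable = None
    return MeanFieldPrediction(synapse_type, rate,
                               stable, H if H == 0 else float(H), conditions)


def solve_for_target(synapse_type: str, target_rate_hz: float,
                     fixed: SmallPolyRule, free: str = "alpha",
                     counterpart_rate_hz: Optional[float] = None
                     ) -> SmallPolyRule:
    """Complete a small-poly rule so its mean-field fixed point hits a target.

    Exactly one amplitude (``free`` in alpha/beta/gamma/kappa) is solved
    for; the remaining parameters are taken from ``fixed``.  For ``ie``/
    ``ei`` with nonzero beta the counterpart rate must be supplied.  Raises
    when the required fixed point does not exist or, for ``ie``, when the
    completed rule violates the printed stability conditions.
    """
    if synapse_type not in SYNAPSE_TYPES:
        raise ValueError(f"unknown synapse type {synapse_type!r}")
    if free not in ("alpha", "beta", "gamma", "kappa"):
        raise ValueError(f"free parameter must be an amplitude, got {free!r}")
    if target_rate_hz <= 0:
        raise ValueError("target rate must be positive")
    rho = target_rate_hz
    tpre_s = fixed.tau_pre / 1000.0
    tpost_s = fixed.tau_post / 1000.0
    a, b, g, k = fixed.alpha, fixed.beta, fixed.gamma, fixed.kappa

    def with_H(H):
        """Split a required Hebbian combination into the free amplitude."""
        if free == "kappa":
            return replace(fixed, kappa=(H - g * tpre_s) / tpost_s)
        return replace(fixed, gamma=(H - k * tpost_s) / tpre_s)

    if synapse_type in ("ee", "ii"):
        H = hebbian_combination(fixed)
        if free == "alpha":
            out = replace(fixed, alpha=-rho * H - b)
        elif free == "beta":
            out = replace(fixed, beta=-rho * H - a)
        else:
            if rho == 0:
                raise ValueError("target rate must be nonzero")
            out = with_H(-(a + b) / rho)
    else:
        r = counterpart_rate_hz
        if free == "alpha":
            if r is None:
                if b != 0:
                    raise ValueError("counterpart rate required when beta != 0")
                out = replace(fixed, alpha=-rho * hebbian_combination(fixed))
            else:
                out = replace(fixed,
                              alpha=-rho * (b + hebbian_combination(fixed) * r) / r)
        elif free == "beta":
            if r is None:
                raise ValueError("solving for beta requires the counterpart rate")
            out = replace(fixed, beta=-a * r / rho - hebbian_combination(fixed) * r)
        else:
            if r is None:
                raise ValueError("solving a Hebbian amplitude requires the "
                                 "counterpart rate")
            out = with_H((-a * r / rho - b) / r)

    pred = meanfield_rate(synapse_type, out,
                          counterpart_rate_hz=counterpart_rate_hz)
    if not pred.defined or not np.isclose(pred.rate_hz, rho):
        raise ValueError("no consistent solution for the requested target")
    if pred.stable is False:
        raise ValueError(
            "completed rule violates the stability conditions "
            f"({pred.conditions}); no solution with the required signs")
    return out
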