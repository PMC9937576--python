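"""Closed-form invasion and maintenance conditions.

These thresholds summarize when reciprocal helping can carry stage-1
cooperation and which kind of cooperation wins.  They are dimensionless
shares in [0, 1]; where reciprocity confers no net benefit the threshold is
the sentinel :data:`UNATTAINABLE` (``math.inf``), meaning cooperation
cannot proliferate at any composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import StrategyType, validate_state

__all__ = [
    "UNATTAINABLE",
    "cooperation_share_threshold",
    "parochial_invasion_threshold",
    "universalist_majority_predicts_dominance",
    "MajorityPrediction",
]

#: Sentinel returned when no cooperator share can sustain cooperation
#: (net helping benefit ``b_h - c_h <= 0``).
UNATTAINABLE = math.inf


def cooperation_share_threshold(c_c: float, b_h: float, c_h: float) -> float:
    """Minimal cooperator share for cooperation to proliferate.

    Cooperative types spread once the share of their kind among potential
    helping partners exceeds the cost-to-net-benefit ratio
    ``c_c / (b_h - c_h)``.  Values above 1 are reported as computed (no
    feasible share exists then); ``b_h <= c_h`` yields
    :data:`UNATTAINABLE`.
    """
    if b_h <= c_h:
        return UNATTAINABLE
    return c_c / (b_h - c_h)


def parochial_invasion_threshold(b_h: float, c_h: float, b_CG: float) -> float:
    """Minimal parochialist share in the opposing group to beat universalists.

    With solid boundaries and one group entirely universalist,
    parochialists proliferate once their share of the other group exceeds
    ``(b_h - c_h) / (b_h - c_h + b_CG)``: the club-good return then more
    than offsets the forgone reciprocal help.
    """
    if b_h <= c_h:
        return 0.0 if b_CG > 0 else UNATTAINABLE
    if b_CG <= 0:
        raise ValueError("b_CG must be positive")
    net = b_h - c_h
    return net / (net + b_CG)


@dataclass(frozen=True)
class MajorityPrediction:
    """Outcome of the simple-majority dominance condition at ``p = 0.5``."""

    in_scope: bool
    predicts_universal: bool | None
    n_universalists_total: int
    max_parochialists_per_group: int
    reason: str


def universalist_majority_predicts_dominance(
    state: np.ndarray, p: float
) -> MajorityPrediction:
    """Predict whether universal cooperation outcompetes parochialism.

    Stated for fully fluid boundaries (``p = 0.5``) only: universalists
    win when their total number exceeds the number of parochialists within
    every single group (a simple population majority suffices).  Exact
    equality in the binding group predicts no advantage
    (``predicts_universal=None``); other ``p`` values are out of scope for
    this condition.
    """
    counts = validate_state(state)
    n_u_total = int(counts[:, StrategyType.UNIVERSALIST].sum())
    max_p = int(counts[:, StrategyType.PAROCHIALIST].max())
    if p != 0.5:
        return MajorityPrediction(
            in_scope=False,
            predicts_universal=None,
            n_universalists_total=n_u_total,
            max_parochialists_per_group=max_p,
            reason=f"condition stated only for fully fluid boundaries (p=0.5), got p={p}",
        )
    if n_u_total > max_p:
        verdict, why = True, "total universalists exceed parochialists in every group"
    elif n_u_total < max_p:
        verdict, why = False, "some group holds more parochialists than there are universalists"
    else:
        verdict, why = None, "exact tie: neither type has the advantage"
    return MajorityPrediction(
        in_scope=True,
        predicts_universal=verdict,
        n_universalists_total=n_u_total,
        max_parochialists_per_group=max_p,
        reason=why,
    )
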