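"""Rate/probability conversions and hazard-adjusted annual death probabilities.

Annual death probabilities for stroke survivors combine age-specific
background mortality from a life table with an mRS-specific hazard ratio.
Hazard ratios act on the instantaneous rate scale (convert the annual
probability to a rate, multiply, convert back); risk ratios act directly on
the probability scale with a cap at 1. Both conventions are explicit and
selectable per adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import LifeTable, ParameterSet, ParameterError


@dataclass(frozen=True)
class HazardAdjustment:
    """A multiplicative adjustment with its scale of application.

    ``space="rate"`` multiplies the instantaneous event rate (a hazard
    ratio); ``space="prob"`` multiplies the probability itself, capped at 1
    (a risk ratio).
    """

    ratio: float
    space: str = "rate"

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ParameterError("adjustment ratio must be positive")
        if self.space not in ("rate", "prob"):
            raise ParameterError("space must be 'rate' or 'prob'")


def prob_to_rate(p: float, t: float = 1.0) -> float:
    """Constant instantaneous rate implying event probability ``p`` over ``t`` years."""
    if t <= 0:
        raise ParameterError("duration must be positive")
    if not 0.0 <= p < 1.0:
        if p == 1.0:
            raise ParameterError("p = 1 implies an infinite rate")
        raise ParameterError(f"probability {p} outside [0, 1)")
    return -math.log1p(-p) / t


def rate_to_prob(rate: float, t: float = 1.0) -> float:
    """Event probability over ``t`` years under a constant rate."""
    if t <= 0:
        raise ParameterError("duration must be positive")
    if rate < 0:
        raise ParameterError("rate must be non-negative")
    return -math.expm1(-rate * t)


def apply_adjustment(p: float, adj: HazardAdjustment) -> float:
    """Apply a hazard ratio (rate scale) or risk ratio (probability scale) to ``p``."""
    if adj.space == "rate":
        if p >= 1.0:
            return 1.0  # certain event stays certain under any positive hazard
        return rate_to_prob(prob_to_rate(p) * adj.ratio)
    return min(1.0, p * adj.ratio)


def background_death_prob(lt: LifeTable, age: int) -> float:
    """Life-table annual death probability q(age); ages past the terminal row are 1."""
    return lt.q(age)


def mrs_adjusted_death_prob(lt: LifeTable, age: int, mrs: int, p: ParameterSet) -> float:
    """Annual death probability at ``age`` for a survivor in state ``mrs``.

    The mRS-specific hazard ratio multiplies background mortality in the
    space configured by ``p.hr_space`` (rate scale by default).
    """
    if not 0 <= mrs <= 5:
        raise ParameterError(f"mrs must be 0..5, got {mrs}")
    q = background_death_prob(lt, age)
    if q >= 1.0:
        return 1.0
    return apply_adjustment(q, HazardAdjustment(p.death_hr_by_mrs[mrs], p.hr_space))
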