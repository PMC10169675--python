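"""Incremental cost-effectiveness comparison and net monetary benefit."""

from __future__ import annotations

from dataclasses import dataclass

from .params import ParameterError

#: Comparison labels. "dominant": the alternative costs less and yields more
#: QALYs (no ICER is reported); "dominated": the reverse; "icer": more costly
#: and more effective, the usual north-east quadrant; "icer_inverted": cheaper
#: and less effective (savings per QALY forgone).
DOMINANT = "dominant"
DOMINATED = "dominated"
EQUIVALENT = "equivalent"
ICER = "icer"
ICER_INVERTED = "icer_inverted"


@dataclass(frozen=True)
class CEAResult:
    cost_ref: float
    cost_alt: float
    qaly_ref: float
    qaly_alt: float

    @property
    def incr_cost(self) -> float:
        return self.cost_alt - self.cost_ref

    @property
    def incr_qaly(self) -> float:
        return self.qaly_alt - self.qaly_ref

    @property
    def kind(self) -> str:
        dc, dq = self.incr_cost, self.incr_qaly
        if dc == 0 and dq == 0:
            return EQUIVALENT
        if dq == 0:
            return DOMINATED if dc > 0 else DOMINANT
        if dq > 0:
            return DOMINANT if dc <= 0 else ICER
        return DOMINATED if dc >= 0 else ICER_INVERTED

    @property
    def icer(self) -> float | None:
        """Incremental cost per incremental QALY; None when a dominance label
        applies (checked before division to avoid sign-flip misreads)."""
        if self.kind in (ICER, ICER_INVERTED):
            return self.incr_cost / self.incr_qaly
        return None

    def icer_or_signed_ratio(self) -> float:
        """Numeric ratio for sensitivity plots even under dominance
        (negative when the alternative is cost-saving)."""
        if self.incr_qaly == 0:
            raise ParameterError("ratio undefined at zero incremental QALYs")
        return self.incr_cost / self.incr_qaly

    @property
    def label(self) -> str:
        k = self.kind
        if k == ICER:
            return f"${self.icer:,.0f}/QALY"
        if k == ICER_INVERTED:
            return f"${-self.icer:,.0f} saved/QALY forgone"
        return {DOMINANT: "Dominance (alt)", DOMINATED: "Dominated",
                EQUIVALENT: "Equivalent"}[k]


def incremental_analysis(ref, alt) -> CEAResult:
    """Compare an alternative strategy against a reference.

    ``ref``/``alt`` may be anything exposing ``.cost`` and ``.qaly`` (e.g.
    :class:`~baocea.markov.StrategyResult`) or ``(cost, qaly)`` pairs.
    """
    cr, qr = _cost_qaly(ref)
    ca, qa = _cost_qaly(alt)
    for x in (cr, ca, qr, qa):
        if not _finite(x):
            raise ParameterError("strategy results must be finite")
    return CEAResult(cost_ref=cr, cost_alt=ca, qaly_ref=qr, qaly_alt=qa)


def net_monetary_benefit(r: CEAResult, wtp: float) -> float:
    """NMB = WTP * incremental QALYs - incremental cost (alt preferred iff > 0)."""
    if wtp < 0:
        raise ParameterError("willingness to pay must be non-negative")
    return wtp * r.incr_qaly - r.incr_cost


def _cost_qaly(x) -> tuple[float, float]:
    if hasattr(x, "cost") and hasattr(x, "qaly"):
        return float(x.cost), float(x.qaly)
    c, q = x
    return float(c), float(q)


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")
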