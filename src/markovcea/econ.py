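"""Incremental cost-effectiveness analysis: ICER, dominance, net monetary benefit.

Negative ICERs (one strategy cheaper AND more effective) are reported with
their dominance class rather than interpreted as bare ratios; net monetary
benefit ``NMB = lambda * effect - cost`` is the primary decision output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .engine import StrategyOutcome

#: Willingness-to-pay used for NMB (China GDP per capita, 2015, USD/QALY).
DEFAULT_WTP_NMB = 34_240.0
#: Willingness-to-pay axis value highlighted on the acceptability curves.
DEFAULT_WTP_CEAC = 20_000.0

Dominance = Literal["none", "a_dominates", "b_dominates"]


@dataclass(frozen=True)
class EconResult:
    """Pairwise incremental comparison of strategy a versus strategy b."""

    label_a: str
    label_b: str
    delta_cost: float
    delta_effect: float
    icer: float | None          # None when delta_effect == 0
    dominance: Dominance

    @property
    def icer_defined(self) -> bool:
        return self.icer is not None


def classify_dominance(delta_cost: float, delta_effect: float) -> Dominance:
    """Dominance from the signs of (cost_a - cost_b, effect_a - effect_b).

    a dominates b when a is no more costly and no less effective, with at
    least one strict inequality; symmetrically for b.
    """
    if delta_cost <= 0 and delta_effect >= 0 and (delta_cost < 0 or delta_effect > 0):
        return "a_dominates"
    if delta_cost >= 0 and delta_effect <= 0 and (delta_cost > 0 or delta_effect < 0):
        return "b_dominates"
    return "none"


def incremental(a: StrategyOutcome, b: StrategyOutcome) -> EconResult:
    """Incremental analysis of a versus b (deltas are a minus b)."""
    delta_cost = a.cost - b.cost
    delta_effect = a.effect - b.effect
    icer = delta_cost / delta_effect if delta_effect != 0 else None
    return EconResult(
        label_a=a.label, label_b=b.label,
        delta_cost=delta_cost, delta_effect=delta_effect,
        icer=icer, dominance=classify_dominance(delta_cost, delta_effect),
    )


def nmb(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp`` per QALY."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be >= 0, got {wtp}")
    return wtp * outcome.effect - outcome.cost
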