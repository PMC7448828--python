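"""Comparative economics: ICER, dominance labelling, net monetary benefit."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["EconResult", "icer", "nmb", "DOMINANT", "DOMINATED", "UNDEFINED"]

DOMINANT = "dominant"      # cheaper and more effective
DOMINATED = "dominated"    # costlier and less effective
UNDEFINED = "undefined"    # incremental QALYs ~ 0, ratio meaningless

_QALY_EPS = 1e-12


def icer(delta_cost: float, delta_qaly: float) -> tuple[float, str]:
    """Incremental cost-effectiveness ratio with a dominance label.

    The signed ratio is reported even under dominance (the conventional
    presentation prints e.g. "-12 369 (dominant)"); when incremental QALYs
    are numerically zero the ratio is NaN with an ``undefined`` label.
    """
    if abs(delta_qaly) < _QALY_EPS:
        return math.nan, UNDEFINED
    ratio = delta_cost / delta_qaly
    if delta_cost < 0 and delta_qaly > 0:
        return ratio, DOMINANT
    if delta_cost > 0 and delta_qaly < 0:
        return ratio, DOMINATED
    return ratio, ""


def nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Incremental net monetary benefit at willingness-to-pay ``wtp`` per QALY."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be >= 0, got {wtp}")
    return wtp * delta_qaly - delta_cost


@dataclass(frozen=True)
class EconResult:
    """One strategy comparison (intervention minus comparator)."""

    delta_cost: float
    delta_qaly: float
    icer: float
    dominance: str
    wtp: float
    nmb: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def from_deltas(cls, delta_cost: float, delta_qaly: float, wtp: float = 100_000.0,
                    ci: dict[str, tuple[float, float]] | None = None) -> "EconResult":
        ratio, label = icer(delta_cost, delta_qaly)
        return cls(
            delta_cost=delta_cost, delta_qaly=delta_qaly, icer=ratio,
            dominance=label, wtp=wtp, nmb=nmb(delta_cost, delta_qaly, wtp),
            ci=ci or {},
        )

    @property
    def icer_display(self) -> str:
        if self.dominance == UNDEFINED:
            return "undefined"
        s = f"{self.icer:.0f}"
        return f"{s} ({self.dominance})" if self.dominance else s
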