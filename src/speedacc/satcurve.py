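"""Exponential speed-accuracy curve for two-alternative choice.

Conceptual utility: percentage correct as an exponential approach to an
asymptote in mean RT,

    PC(RTbar) = 50                                          if RTbar < delta
    PC(RTbar) = (lam / 2) * (1 - exp(-gamma*(RTbar-delta))) + 50   otherwise

with x-offset ``delta`` (below it responses are guesses, PC = 50%),
steepness ``gamma`` and asymptote span ``lam`` (PC tends to lam/2 + 50).
The time unit follows the caller (delta and 1/gamma share RTbar's unit);
no hidden conversion is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["SATCurveParams", "wickelgren_pc"]


@dataclass(frozen=True)
class SATCurveParams:
    """Curve parameters: x-offset, steepness, and asymptote span (percent)."""

    delta: float
    gamma: float
    lam: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(x) for x in (self.delta, self.gamma, self.lam)):
            raise ValueError("curve parameters must be finite")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not 0 <= self.lam <= 100:
            raise ValueError(f"lam must lie in [0, 100], got {self.lam}")


def wickelgren_pc(rt_bar: float, params: SATCurveParams) -> float:
    """Percentage correct at mean RT ``rt_bar`` (guessing floor at 50%).

    Continuous at ``rt_bar = delta``; monotone non-decreasing in ``rt_bar``;
    bounded in [50, lam/2 + 50].
    """
    if not math.isfinite(rt_bar):
        raise ValueError(f"rt_bar must be finite, got {rt_bar}")
    if rt_bar < params.delta:
        return 50.0
    return (params.lam / 2.0) * (1.0 - math.exp(-params.gamma * (rt_bar - params.delta))) + 50.0
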