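"""Packaged study scenarios.

Three parameterizations exercised throughout the numerical analyses:

* ``case1``: alpha = 1, gamma = 0.5, initial state (0.33, 0.64) -- trivial
  point behaviour and the diagram over r.
* ``case2``: alpha = 2, gamma = 1 -- the degenerate surface det = 1, where
  the interior multipliers sit on the unit circle for every r and invariant
  closed curves are observed.
* ``case3``: alpha = 0.5, gamma = 0.3 -- the period-doubling route: stable
  p1, flip near r = 3.9255, cascade, chaos before r = 6.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import State

__all__ = ["Scenario", "SCENARIOS"]


@dataclass(frozen=True)
class Scenario:
    name: str
    alpha: float
    gamma: float
    x0: State
    r_default: float
    r_range: tuple[float, float]


SCENARIOS: dict[str, Scenario] = {
    "case1": Scenario("case1", alpha=1.0, gamma=0.5, x0=State(0.33, 0.64),
                      r_default=1.0, r_range=(0.1, 6.0)),
    "case2": Scenario("case2", alpha=2.0, gamma=1.0, x0=State(0.33, 0.64),
                      r_default=3.598768, r_range=(0.3, 4.0)),
    "case3": Scenario("case3", alpha=0.5, gamma=0.3, x0=State(0.33, 0.64),
                      r_default=3.5, r_range=(3.0, 6.0)),
}
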