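"""Parameter sweeps in r: bifurcation diagrams, flip location, cascades.

The growth rate r is the bifurcation parameter, swept over a uniform grid.
For each grid value the orbit is simulated past a transient, attractor
samples are recorded, the period is detected, and the maximal Lyapunov
exponent is estimated.  Warm starting (seeding each r with the final state
of the previous one) is the default, which follows the stable branch as
diagrams conventionally do; cold starts from a fixed initial state are
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .dynamics import (
    APERIODIC,
    MAX_PERIOD,
    PERIOD_TOL,
    detect_period,
    max_lyapunov,
    simulate,
)
from .model import DomainError, ModelParams, State
from .stability import critical_r_flip, flip_condition

__all__ = [
    "DiagramRow",
    "SweepSettings",
    "sweep",
    "locate_flip_numeric",
    "cascade_detect",
    "CHAOS_MLE_THRESHOLD",
]

#: rows flagged aperiodic are labelled chaotic when mle exceeds this
CHAOS_MLE_THRESHOLD = 0.01


@dataclass(frozen=True)
class SweepSettings:
    """Shared per-row simulation settings of a sweep."""

    transient: int = 1000
    n_samples: int = 200
    mle_steps: int = 2000
    period_tol: float = PERIOD_TOL
    max_period: int = MAX_PERIOD
    warm_start: bool = True
    seed: int = 0


@dataclass(frozen=True)
class DiagramRow:
    r: float
    attractor_x: np.ndarray
    attractor_y: np.ndarray
    period: int | None          # None = aperiodic (or divergent)
    mle: float
    diverged: bool
    admissible: bool

    @property
    def chaotic(self) -> bool:
        return (not self.diverged) and self.period is APERIODIC and self.mle > CHAOS_MLE_THRESHOLD


def sweep(
    alpha: float,
    gamma: float,
    r_min: float,
    r_max: float,
    n_r: int,
    x0: State = State(0.33, 0.64),
    settings: SweepSettings = SweepSettings(),
) -> list[DiagramRow]:
    """Bifurcation-diagram data over a uniform r grid (rows sorted by r)."""
    if not r_min < r_max:
        raise DomainError("sweep requires r_min < r_max")
    if n_r < 2:
        raise DomainError("sweep requires n_r >= 2")
    grid = np.linspace(r_min, r_max, n_r)
    n_record = max(settings.n_samples, 4 * settings.max_period)
    rows: list[DiagramRow] = []
    start = State(float(x0[0]), float(x0[1]))
    for r in grid:
        p = ModelParams(r=float(r), alpha=alpha, gamma=gamma)
        orbit = simulate(start, p, n=n_record, transient=settings.transient)
        if orbit.diverged or len(orbit) < n_record:
            rows.append(
                DiagramRow(
                    r=float(r),
                    attractor_x=orbit.points[-settings.n_samples:, 0].copy()
                    if len(orbit) else np.empty(0),
                    attractor_y=orbit.points[-settings.n_samples:, 1].copy()
                    if len(orbit) else np.empty(0),
                    period=APERIODIC, mle=math.inf,
                    diverged=True, admissible=orbit.admissible,
                )
            )
            start = State(float(x0[0]), float(x0[1]))  # re-seed after blow-up
            continue
        period = detect_period(orbit, tol=settings.period_tol, max_period=settings.max_period)
        est = max_lyapunov(
            orbit.last, p, n=settings.mle_steps, transient=0, seed=settings.seed
        )
        rows.append(
            DiagramRow(
                r=float(r),
                attractor_x=orbit.points[-settings.n_samples:, 0].copy(),
                attractor_y=orbit.points[-settings.n_samples:, 1].copy(),
                period=period,
                mle=est.mle,
                diverged=False,
                admissible=orbit.admissible,
            )
        )
        if settings.warm_start:
            start = orbit.last
    return rows


def locate_flip_numeric(
    alpha: float,
    gamma: float,
    bracket: tuple[float, float],
    tol: float = 1e-8,
) -> float:
    """Root of R(-1) = 1 + trace + det at p1 by bracketed bisection.

    Agrees with :func:`rickerholling.stability.critical_r_flip` to the
    requested tolerance wherever both are defined.  Raises
    :class:`DomainError` when the residual does not change sign across the
    bracket.
    """
    r_lo, r_hi = bracket
    if not 0.0 < r_lo < r_hi:
        raise DomainError("bracket must satisfy 0 < r_lo < r_hi")

    def residual(r: float) -> float:
        return flip_condition(ModelParams(r=r, alpha=alpha, gamma=gamma)).residual

    f_lo, f_hi = residual(r_lo), residual(r_hi)
    if f_lo * f_hi > 0.0:
        raise DomainError(
            f"no flip crossing in bracket ({r_lo}, {r_hi}): R(-1) has the same sign "
            f"at both ends ({f_lo:.6g}, {f_hi:.6g})"
        )
    return float(brentq(residual, r_lo, r_hi, xtol=tol))


def cascade_detect(rows: list[DiagramRow]) -> list[tuple[float, int]]:
    """Onsets of the period-doubling cascade from sorted diagram rows.

    Returns the increasing sequence of (r_onset, period) at which the
    detected period first exactly doubles relative to the previous plateau
    (1 -> 2 -> 4 -> ...), ending where period detection fails (chaos) or the
    rows end.
    """
    onsets: list[tuple[float, int]] = []
    prev: int | None = None
    for row in rows:
        if row.diverged:
            break
        if row.period is APERIODIC:
            break
        if prev is None:
            prev = row.period
            continue
        if row.period == 2 * prev:
            onsets.append((row.r, row.period))
            prev = row.period
        elif row.period != prev and row.period % (2 * prev) == 0:
            # grid skipped a plateau; still a doubling cascade step
            onsets.append((row.r, row.period))
            prev = row.period
    return onsets
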