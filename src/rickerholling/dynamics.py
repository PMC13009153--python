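"""Orbit simulation, period detection and maximal Lyapunov exponents.

Orbits iterate the raw map over the reals; leaving the non-negative
quadrant clears an "admissible" flag, and coordinates exceeding 1e6 in
magnitude mark the orbit divergent (data, not an exception).  The maximal
Lyapunov exponent is estimated by the tangent-vector method: a unit vector
is propagated through the analytic Jacobian along the orbit and
renormalized each step; the exponent is the average log stretch after the
transient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import DIVERGENCE_BOUND, DomainError, ModelParams, State, jacobian, step

__all__ = [
    "OrbitResult",
    "LyapunovEstimate",
    "simulate",
    "detect_period",
    "max_lyapunov",
    "PERIOD_TOL",
    "MAX_PERIOD",
    "APERIODIC",
]

#: default recurrence tolerance for period detection
PERIOD_TOL = 1e-6
#: default maximum detectable period
MAX_PERIOD = 64
#: sentinel returned by detect_period when no period <= max_period is found
APERIODIC = None


@dataclass(frozen=True)
class OrbitResult:
    """Post-transient orbit segment with divergence/admissibility flags."""

    points: np.ndarray          # shape (n, 2), consecutive map iterates
    diverged: bool
    diverged_at: int | None     # global step index of first divergence
    admissible: bool            # stayed in the non-negative quadrant

    def __len__(self) -> int:
        return len(self.points)

    @property
    def last(self) -> State:
        return State(*self.points[-1])


@dataclass(frozen=True)
class LyapunovEstimate:
    mle: float        # nats per iteration; +inf sentinel on divergence
    n_steps: int
    transient: int
    seed: int


def simulate(x0: State, p: ModelParams, n: int, transient: int = 0) -> OrbitResult:
    """Iterate the map, discarding ``transient`` steps, recording ``n``.

    Stops early (with the divergence flag and step index) when a coordinate
    magnitude exceeds 1e6.
    """
    if n < 0 or transient < 0:
        raise DomainError("n and transient must be non-negative")
    s = State(float(x0[0]), float(x0[1]))
    admissible = s.x >= 0.0 and s.y >= 0.0
    pts: list[State] = []
    diverged_at = None
    total = transient + n
    for i in range(total):
        s = step(s, p)
        if not (abs(s.x) <= DIVERGENCE_BOUND and abs(s.y) <= DIVERGENCE_BOUND):
            diverged_at = i + 1
            break
        if s.x < 0.0 or s.y < 0.0:
            admissible = False
        if i >= transient:
            pts.append(s)
    points = np.asarray(pts, dtype=float).reshape(-1, 2)
    return OrbitResult(
        points=points,
        diverged=diverged_at is not None,
        diverged_at=diverged_at,
        admissible=admissible,
    )


def detect_period(
    orbit: OrbitResult,
    tol: float = PERIOD_TOL,
    max_period: int = MAX_PERIOD,
) -> int | None:
    """Smallest period k <= max_period of the attractor, else ``APERIODIC``.

    k is accepted when every one of the last 2k points recurs after k steps
    to within ``tol`` in the maximum norm.  Requires a converged orbit of at
    least 4 * max_period points.
    """
    if orbit.diverged:
        raise DomainError("cannot detect a period on a divergent orbit")
    pts = orbit.points
    if len(pts) < 4 * max_period:
        raise DomainError(
            f"orbit too short for period detection: need >= {4 * max_period} points, "
            f"got {len(pts)}"
        )
    for k in range(1, max_period + 1):
        tail = pts[-(2 * k):]
        if np.max(np.abs(tail[k:] - tail[:-k])) < tol:
            return k
    return APERIODIC


def max_lyapunov(
    x0: State,
    p: ModelParams,
    n: int,
    transient: int = 1000,
    seed: int = 0,
) -> LyapunovEstimate:
    """Maximal Lyapunov exponent along the orbit from ``x0``.

    The tangent vector (random initial direction drawn from ``seed``) is
    propagated through the Jacobian during the transient as well, but log
    stretches are accumulated only over the ``n`` post-transient steps.
    A divergent orbit yields an estimate with ``mle = +inf``.
    """
    if n < 1:
        raise DomainError("max_lyapunov requires n >= 1")
    rng = np.random.default_rng(seed)
    angle = rng.uniform(0.0, 2.0 * math.pi)
    w = np.array([math.cos(angle), math.sin(angle)])
    s = State(float(x0[0]), float(x0[1]))
    log_sum = 0.0
    for i in range(transient + n):
        try:
            jac = jacobian(s, p)
        except DomainError:
            return LyapunovEstimate(mle=math.inf, n_steps=n, transient=transient, seed=seed)
        w = np.array([jac.j11 * w[0] + jac.j12 * w[1], jac.j21 * w[0] + jac.j22 * w[1]])
        norm = math.hypot(w[0], w[1])
        if norm == 0.0 or not math.isfinite(norm):
            return LyapunovEstimate(mle=math.inf, n_steps=n, transient=transient, seed=seed)
        w /= norm
        if i >= transient:
            log_sum += math.log(norm)
        s = step(s, p)
        if not (abs(s.x) <= DIVERGENCE_BOUND and abs(s.y) <= DIVERGENCE_BOUND):
            return LyapunovEstimate(mle=math.inf, n_steps=n, transient=transient, seed=seed)
    return LyapunovEstimate(mle=log_sum / n, n_steps=n, transient=transient, seed=seed)
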