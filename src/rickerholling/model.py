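"""Core discrete-time predator-prey map.

The map couples Ricker-type prey growth with a Holling type II functional
response and linear predator mortality::

    x_{n+1} = x_n + r x_n e^{1-x_n} - alpha x_n y_n / (1 + x_n)
    y_{n+1} = y_n + alpha x_n y_n / (1 + x_n) - gamma y_n

with intrinsic prey growth rate ``r``, predation/conversion rate ``alpha``
and predator mortality ``gamma``, all strictly positive and dimensionless.

This module provides exact single-step iteration, the two fixed points
(extinction p0 and coexistence p1), the analytic Jacobian, and the
characteristic-polynomial data (trace, determinant, multipliers).

Sign convention used throughout the package: the characteristic polynomial
of a 2x2 Jacobian is R(rho) = rho^2 - trace*rho + det, so the jury values
are R(1) = 1 - trace + det and R(-1) = 1 + trace + det.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

__all__ = [
    "DomainError",
    "ModelParams",
    "State",
    "FixedPointKind",
    "FixedPoint",
    "JacobianEval",
    "step",
    "fixed_points",
    "interior_fixed_point",
    "jacobian",
    "interior_trace_det",
    "FIXED_POINT_TOL",
]

#: absolute per-coordinate tolerance for "state is a fixed point"
FIXED_POINT_TOL = 1e-10

#: orbits whose coordinates exceed this magnitude are flagged divergent
DIVERGENCE_BOUND = 1e6


class DomainError(ValueError):
    """A quantity was requested outside its domain of definition."""


@dataclass(frozen=True)
class ModelParams:
    """Parameter triple (r, alpha, gamma) of the map.

    All three rates are dimensionless and strictly positive.  The interior
    (coexistence) fixed point exists iff ``alpha > gamma``.
    """

    r: float
    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("r", "alpha", "gamma"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0.0):
                raise DomainError(f"parameter {name!r} must be finite and > 0, got {value!r}")

    @property
    def has_interior(self) -> bool:
        """Whether the coexistence fixed point p1 exists (alpha > gamma)."""
        return self.alpha > self.gamma

    @property
    def exp_factor(self) -> float:
        """e^{(alpha - 2 gamma)/(alpha - gamma)}, the e^{1-x*} factor at p1."""
        if not self.has_interior:
            raise DomainError("exp_factor requires alpha > gamma")
        return math.exp((self.alpha - 2.0 * self.gamma) / (self.alpha - self.gamma))

    def with_r(self, r: float) -> "ModelParams":
        return ModelParams(r=r, alpha=self.alpha, gamma=self.gamma)


class State(NamedTuple):
    """A point (x, y) of the phase plane: prey and predator density.

    The raw map is defined on all of R^2; biological admissibility
    (x, y >= 0) is tracked as a flag by the orbit utilities, never enforced.
    """

    x: float
    y: float


class FixedPointKind(Enum):
    TRIVIAL = "trivial"
    INTERIOR = "interior"


@dataclass(frozen=True)
class FixedPoint:
    state: State
    kind: FixedPointKind


@dataclass(frozen=True)
class JacobianEval:
    """Linearization of the map at a state, with multiplier data.

    ``rho1`` is the multiplier of larger modulus; a complex-conjugate pair
    is stored with the positive-imaginary-part member first.
    """

    j11: float
    j12: float
    j21: float
    j22: float
    trace: float
    det: float
    rho1: complex
    rho2: complex

    @property
    def discriminant(self) -> float:
        return self.trace * self.trace - 4.0 * self.det


def step(s: State, p: ModelParams) -> State:
    """Apply the map once.  Deterministic; the input state is not mutated.

    Exponential overflow (very negative x) is signalled by returning
    infinite coordinates rather than raising, so orbit code can flag
    divergence as data.
    """
    x, y = s
    try:
        growth = p.r * x * math.exp(1.0 - x)
    except OverflowError:
        return State(math.inf if x > 0 else -math.inf, y)
    predation = p.alpha * x * y / (1.0 + x)
    return State(x + growth - predation, y + predation - p.gamma * y)


def interior_fixed_point(p: ModelParams) -> FixedPoint:
    """The coexistence point p1 = (gamma/(alpha-gamma), r/(alpha-gamma) e^{(alpha-2gamma)/(alpha-gamma)}).

    Raises :class:`DomainError` when alpha <= gamma.
    """
    if not p.has_interior:
        raise DomainError(
            f"interior fixed point requires alpha > gamma (alpha={p.alpha}, gamma={p.gamma})"
        )
    d = p.alpha - p.gamma
    return FixedPoint(State(p.gamma / d, p.r / d * p.exp_factor), FixedPointKind.INTERIOR)


def fixed_points(p: ModelParams) -> list[FixedPoint]:
    """All fixed points of the map: always p0 = (0, 0); p1 iff alpha > gamma."""
    pts = [FixedPoint(State(0.0, 0.0), FixedPointKind.TRIVIAL)]
    if p.has_interior:
        pts.append(interior_fixed_point(p))
    return pts


def jacobian(s: State, p: ModelParams) -> JacobianEval:
    """Analytic Jacobian of the map at a state.

    Raises :class:`DomainError` at the Holling-term pole x = -1.
    """
    x, y = s
    if not (math.isfinite(x) and math.isfinite(y)):
        raise DomainError(f"Jacobian requires a finite state, got {s!r}")
    if x == -1.0:
        raise DomainError("Jacobian undefined at the Holling-term pole x = -1")
    e1x = math.exp(1.0 - x)
    opx = 1.0 + x
    j11 = 1.0 + p.r * e1x * (1.0 - x) - p.alpha * y / opx**2
    j12 = -p.alpha * x / opx
    j21 = p.alpha * y / opx**2
    j22 = (1.0 - p.gamma) + p.alpha * x / opx
    trace = j11 + j22
    det = j11 * j22 - j12 * j21
    rho1, rho2 = _quadratic_multipliers(trace, det)
    return JacobianEval(j11=j11, j12=j12, j21=j21, j22=j22, trace=trace, det=det, rho1=rho1, rho2=rho2)


def _quadratic_multipliers(trace: float, det: float) -> tuple[complex, complex]:
    """Roots of rho^2 - trace*rho + det, ordered per package convention."""
    disc = trace * trace - 4.0 * det
    if disc >= 0.0:
        sq = math.sqrt(disc)
        # numerically stable real-root pair
        if trace >= 0.0:
            r1 = (trace + sq) / 2.0
        else:
            r1 = (trace - sq) / 2.0
        r2 = det / r1 if r1 != 0.0 else (trace - math.copysign(sq, trace)) / 2.0
        a, b = complex(r1), complex(r2)
    else:
        sq = math.sqrt(-disc)
        a = complex(trace / 2.0, sq / 2.0)
        b = a.conjugate()
        return a, b  # positive-imaginary first; equal moduli
    if abs(a) >= abs(b):
        return a, b
    return b, a


def interior_trace_det(p: ModelParams) -> tuple[float, float]:
    """Closed-form (trace, det) of the Jacobian at p1.

    trace = 2 - r e^{(a-2g)/(a-g)} g^2 / (a(a-g))
    det   = 1 + r e^{(a-2g)/(a-g)} g (g^2 - g + a^2 - 2 a g) / (a(a-g))

    These are the P and q of the characteristic quadratic at p1 under the
    R(rho) = rho^2 - trace*rho + det convention.
    """
    a, g = p.alpha, p.gamma
    if not p.has_interior:
        raise DomainError("interior trace/det require alpha > gamma")
    re = p.r * p.exp_factor
    denom = a * (a - g)
    trace = 2.0 - re * g * g / denom
    det = 1.0 + re * g * (g * g - g + a * a - 2.0 * a * g) / denom
    return trace, det


def is_fixed_point(s: State, p: ModelParams, tol: float = FIXED_POINT_TOL) -> bool:
    """Whether ``step`` maps ``s`` to itself within ``tol`` per coordinate."""
    nxt = step(s, p)
    return abs(nxt.x - s.x) <= tol and abs(nxt.y - s.y) <= tol
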