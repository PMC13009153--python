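"""Stability classification of fixed points and critical parameter values.

Classification follows the jury conditions for a real 2x2 map with
characteristic polynomial R(rho) = rho^2 - trace*rho + det:

* locally asymptotically stable (LAS)  <=>  R(1) > 0, R(-1) > 0, det < 1
* a flip (period-doubling) boundary is R(-1) = 0
* a Neimark-Sacker boundary is det = 1 with a complex pair (trace^2 < 4 det)

Two corrections of printed source material are applied and surfaced via
``corrections_applied`` in the JSON report:

* The extinction point p0 has multipliers {1 + r e, 1 - gamma}; since
  1 + r e > 1 for every r > 0, p0 is a saddle for 0 < gamma < 2 (and a
  source for gamma > 2), never stable.  The classification here is always
  computed from the multipliers; the printed stability inequality
  r e (1 - gamma) < gamma is exposed, clearly labelled, by
  :func:`prop_trivial_condition_as_printed`.
* Flip criticality at p1 is the root of R(-1) = 1 + trace + det = 0 (the
  condition whose root matches the numerically observed period-doubling),
  not R(1) = 0 which is unsatisfiable for r > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .model import (
    DomainError,
    FixedPoint,
    FixedPointKind,
    JacobianEval,
    ModelParams,
    interior_trace_det,
    jacobian,
    _quadratic_multipliers,
)

__all__ = [
    "Classification",
    "StabilityReport",
    "BifurcationCondition",
    "jury_values",
    "jury_classify",
    "classify_fixed_point",
    "prop_interior_conditions",
    "prop_trivial_condition_as_printed",
    "critical_r_flip",
    "flip_condition",
    "ns_condition",
    "ANALYTIC_TOL",
    "NUMERIC_TOL",
    "CORRECTION_TRIVIAL_POINT",
    "CORRECTION_FLIP_SIGN",
]

#: unit-circle tolerance for analytic classification
ANALYTIC_TOL = 1e-9
#: looser tolerance when classification feeds numerical continuation
NUMERIC_TOL = 1e-6

CORRECTION_TRIVIAL_POINT = (
    "trivial-point-classified-from-multipliers:"
    " {1 + r e, 1 - gamma} always contains a modulus > 1 for r > 0"
)
CORRECTION_FLIP_SIGN = (
    "flip-criticality-is-R(-1)=0:"
    " 1 + trace + det = 0 under the R(rho) = rho^2 - trace rho + det convention"
)


class Classification(Enum):
    LAS = "LAS"
    SOURCE = "source"
    SADDLE = "saddle"
    NON_HYPERBOLIC = "non_hyperbolic"


@dataclass(frozen=True)
class JuryValues:
    R1: float   # R(1)  = 1 - trace + det
    Rm1: float  # R(-1) = 1 + trace + det
    det: float


@dataclass(frozen=True)
class StabilityReport:
    fixed_point: FixedPoint
    jac: JacobianEval
    classification: Classification
    jury: JuryValues
    tol: float
    corrections_applied: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        fp = self.fixed_point
        return {
            "fixed_point": {"kind": fp.kind.value, "x": fp.state.x, "y": fp.state.y},
            "multipliers": [
                {"re": self.jac.rho1.real, "im": self.jac.rho1.imag},
                {"re": self.jac.rho2.real, "im": self.jac.rho2.imag},
            ],
            "jury": {"R1": self.jury.R1, "Rm1": self.jury.Rm1, "det": self.jury.det},
            "trace": self.jac.trace,
            "classification": self.classification.value,
            "tol": self.tol,
            "corrections_applied": list(self.corrections_applied),
        }


@dataclass(frozen=True)
class BifurcationCondition:
    """A scalar residual whose zero marks criticality, plus side checks."""

    kind: str  # "flip" | "neimark_sacker"
    residual: float
    side_conditions: dict = field(default_factory=dict)


def jury_values(trace: float, det: float) -> JuryValues:
    return JuryValues(R1=1.0 - trace + det, Rm1=1.0 + trace + det, det=det)


def jury_classify(trace: float, det: float, tol: float = ANALYTIC_TOL) -> Classification:
    """Classify a fixed point from (trace, det) of its Jacobian.

    The classification is made from the multiplier moduli directly (which
    is equivalent to the jury sign pattern R(1) > 0, R(-1) > 0, det < 1 for
    LAS), with any modulus within ``tol`` of the unit circle reported as
    non-hyperbolic regardless of the other multiplier.
    """
    if not (math.isfinite(trace) and math.isfinite(det)):
        raise DomainError("jury_classify requires finite trace and det")
    if not 0.0 < tol < 0.1:
        raise DomainError(f"tol must lie in (0, 0.1), got {tol}")
    rho1, rho2 = _quadratic_multipliers(trace, det)
    m1, m2 = abs(rho1), abs(rho2)
    if abs(m1 - 1.0) <= tol or abs(m2 - 1.0) <= tol:
        return Classification.NON_HYPERBOLIC
    inside = (m1 < 1.0) + (m2 < 1.0)
    if inside == 2:
        return Classification.LAS
    if inside == 0:
        return Classification.SOURCE
    return Classification.SADDLE


def classify_fixed_point(
    fp: FixedPoint, p: ModelParams, tol: float = ANALYTIC_TOL
) -> StabilityReport:
    """Full stability report for a fixed point of the map."""
    jac = jacobian(fp.state, p)
    cls = jury_classify(jac.trace, jac.det, tol)
    corrections: tuple[str, ...] = ()
    if fp.kind is FixedPointKind.TRIVIAL:
        corrections = (CORRECTION_TRIVIAL_POINT,)
    return StabilityReport(
        fixed_point=fp,
        jac=jac,
        classification=cls,
        jury=jury_values(jac.trace, jac.det),
        tol=tol,
        corrections_applied=corrections,
    )


def prop_interior_conditions(p: ModelParams) -> tuple[float, float, float]:
    """The three closed-form stability expressions at p1.

    Returns (R(1), R(-1), det - 1) evaluated via the closed forms

      R(1)    = r E g (g^2 + a^2 - 2 a g) / (a (a - g))
      R(-1)   = 4 + r E g (g^2 - 2 g + a^2 - 2 a g) / (a (a - g))
      det - 1 = r E g (g^2 - g + a^2 - 2 a g) / (a (a - g))

    with E = e^{(a-2g)/(a-g)}.  The sign pattern (+, +, -) is equivalent to
    local asymptotic stability of p1.
    """
    a, g = p.alpha, p.gamma
    if not p.has_interior:
        raise DomainError("interior stability conditions require alpha > gamma")
    re = p.r * p.exp_factor
    denom = a * (a - g)
    c1 = re * g * (g * g + a * a - 2.0 * a * g) / denom
    c2 = 4.0 + re * g * (g * g - 2.0 * g + a * a - 2.0 * a * g) / denom
    c3 = re * g * (g * g - g + a * a - 2.0 * a * g) / denom
    return c1, c2, c3


def prop_trivial_condition_as_printed(p: ModelParams) -> tuple[float, float]:
    """The printed stability inequality for p0, labelled as-printed.

    Returns the pair (r e (1 - gamma), gamma) whose comparison the source
    proposition uses; it conflicts with the direct multipliers
    {1 + r e, 1 - gamma} and is provided for transparency only.
    """
    return p.r * math.e * (1.0 - p.gamma), p.gamma


def _flip_coefficient(alpha: float, gamma: float) -> float:
    """Slope (per unit r E) of R(-1) at p1: g (g^2 - 2g + a^2 - 2ag)/(a(a-g))."""
    a, g = alpha, gamma
    return g * (g * g - 2.0 * g + a * a - 2.0 * a * g) / (a * (a - g))


def critical_r_flip(alpha: float, gamma: float) -> float:
    """The unique r > 0 at which a multiplier of J(p1) equals -1.

    Closed form: root of R(-1) = 4 + r E k = 0 with
    k = gamma (gamma^2 - 2 gamma + alpha^2 - 2 alpha gamma)/(alpha (alpha - gamma)),
    which requires k < 0.  A degenerate crossing where the second multiplier
    also sits on the unit circle (det = 1 at the root, a 1:2 resonance, e.g.
    alpha = 2, gamma = 1) is rejected as a domain error because no generic
    period-doubling occurs there.
    """
    if not alpha > gamma > 0.0:
        raise DomainError("flip analysis requires alpha > gamma > 0")
    E = math.exp((alpha - 2.0 * gamma) / (alpha - gamma))
    k = _flip_coefficient(alpha, gamma)
    if k >= 0.0:
        raise DomainError(
            "no period-doubling in r for alpha={}, gamma={}: R(-1) = 4 + r E k with "
            "k = {:.6g} >= 0 never vanishes for r > 0".format(alpha, gamma, k)
        )
    r_c = -4.0 / (E * k)
    _, det = interior_trace_det(ModelParams(r=r_c, alpha=alpha, gamma=gamma))
    if abs(det - 1.0) <= NUMERIC_TOL:
        raise DomainError(
            "degenerate flip for alpha={}, gamma={}: at the R(-1)=0 root r={:.6g} the "
            "second multiplier is also -1 (det=1, 1:2 resonance); no generic "
            "period-doubling in r".format(alpha, gamma, r_c)
        )
    return r_c


def flip_condition(p: ModelParams) -> BifurcationCondition:
    """Flip criticality residual R(-1) = 1 + trace + det at p1."""
    trace, det = interior_trace_det(p)
    return BifurcationCondition(
        kind="flip",
        residual=1.0 + trace + det,
        side_conditions={"det_not_one": abs(det - 1.0) > NUMERIC_TOL, "det": det},
    )


def ns_condition(p: ModelParams) -> BifurcationCondition:
    """Neimark-Sacker criticality residual det - 1 at p1, with side checks.

    For this map det - 1 = r E g (g^2 - g + a^2 - 2ag)/(a(a-g)) is
    proportional to r times a parameter-only factor, so for r > 0 the
    residual vanishes identically in r exactly on the degenerate surface
    g^2 - g + a^2 - 2ag = 0 (where det = 1 for every r).
    """
    trace, det = interior_trace_det(p)
    a, g = p.alpha, p.gamma
    surface = g * g - g + a * a - 2.0 * a * g
    return BifurcationCondition(
        kind="neimark_sacker",
        residual=det - 1.0,
        side_conditions={
            "complex_pair": trace * trace - 4.0 * det < 0.0,
            "abs_trace_lt_2": abs(trace) < 2.0,
            "degenerate_surface": abs(surface) <= 1e-12,
            "surface_value": surface,
        },
    )
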