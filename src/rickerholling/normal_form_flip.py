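"""Period-doubling (flip) normal form at the coexistence point p1.

At the critical rate r_c (where one multiplier of J(p1) equals -1 and the
other, rho_2, lies off the unit circle) the map is reduced to a
one-dimensional map on the center manifold:

    L(X) = -X + n1 X^2 + n2 X s + n3 X^2 s + n4 X s^2 + n5 X^3 + O(4),

where s = r - r_c is the deviation of the growth rate.  The criticality
quantities are

    w1 = n2          (transversality: d rho_1 / dr at the crossing)
    w2 = n5 + n1^2   (direction: > 0 stable period-2 branch, < 0 unstable)

Construction.  Coordinates are shifted to the r-dependent fixed point
(x*, y*(r)); because x* = gamma/(alpha - gamma) does not move with r and
y*(r) is linear in r, the shifted map has no constant term and is linear in
s, so the center-manifold ansatz Y = k1 X^2 + k2 X s holds with k0 = k3 = 0
exactly.  The s-linear data are then simply the r-derivatives of the
Jacobian and of the quadratic Taylor coefficients at p1.  The reduction
itself is the standard substitution: transform with the eigenbasis
M = [[B12, B12], [-1 - B11, rho2 - B11]], solve the manifold invariance
equation order by order, and collect the X-equation coefficients.  The
reduced-map coefficients are derived from this procedure (validated
symbolically and against numerical restriction oracles in the test suite)
rather than transcribed from printed expressions, which carry
typographical defects.  In particular n2 equals the eigenvalue derivative
d rho_1/dr obtained by implicit differentiation of the characteristic
polynomial -- an identity used as an independent cross-check.

The growth-term-only parameter coefficients that printed treatments list,
Bt17 = (1 - x*) e^{1 - x*} and Bt18 = (x* - 2) e^{1 - x*} / 2, are exposed
on :class:`FlipTaylor`; the reduction's s-couplings additionally carry the
y*(r) drift (see ``d_j11``, ``d_j21``, ``d_b13``, ``d_b23``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .model import DomainError, ModelParams, interior_fixed_point, interior_trace_det, jacobian
from .normal_form_ns import taylor_coeffs_B
from .stability import critical_r_flip

__all__ = [
    "FlipSetup",
    "FlipTaylor",
    "FlipCoefficients",
    "FlipVerdict",
    "flip_setup",
    "flip_taylor_coeffs",
    "center_manifold",
    "reduced_map_coeffs",
    "flip_analysis",
    "DEGENERACY_TOL",
]

#: |w1| or |w2| below this is reported as a degenerate flip
DEGENERACY_TOL = 1e-10


class FlipVerdict(Enum):
    STABLE_PERIOD2 = "stable_period2"
    UNSTABLE_PERIOD2 = "unstable_period2"
    DEGENERATE = "degenerate"


@dataclass(frozen=True)
class FlipSetup:
    """Critical rate and second multiplier for a flip at p1."""

    alpha: float
    gamma: float
    r_c: float       # rate at which a multiplier equals -1
    rho2: float      # the other multiplier at criticality (|rho2| != 1)
    r_dev: float = 0.0

    @property
    def params(self) -> ModelParams:
        return ModelParams(r=self.r_c + self.r_dev, alpha=self.alpha, gamma=self.gamma)


@dataclass(frozen=True)
class FlipTaylor:
    """Taylor data of the p1-shifted map at r_c, plus its r-derivatives.

    ``B`` is the (2, 6) state-Taylor array of :func:`taylor_coeffs_B`
    evaluated at r_c.  ``bt17``/``bt18`` are the growth-term u s and u^2 s
    coefficients as conventionally printed; the d_* fields are the full
    r-derivatives (fixed point tracked) actually used by the reduction.
    """

    B: np.ndarray
    bt17: float   # (1 - x*) e^{1 - x*}
    bt18: float   # (x* - 2) e^{1 - x*} / 2
    d_j11: float  # d J11 / dr at p1(r_c)
    d_j21: float  # d J21 / dr
    d_b13: float  # d B13 / dr
    d_b23: float  # d B23 / dr


def flip_setup(alpha: float, gamma: float) -> FlipSetup:
    """Locate the flip at p1 and the off-circle multiplier rho_2.

    By Vieta, at r_c the multipliers are (-1, rho2) with
    rho2 = trace + 1 = -det.  Raises :class:`DomainError` when no
    non-degenerate flip in r exists.
    """
    r_c = critical_r_flip(alpha, gamma)
    p = ModelParams(r=r_c, alpha=alpha, gamma=gamma)
    trace, det = interior_trace_det(p)
    rho2 = trace + 1.0
    if abs(abs(rho2) - 1.0) <= 1e-8:
        raise DomainError("flip is degenerate: |rho2| = 1 at r_c")
    return FlipSetup(alpha=alpha, gamma=gamma, r_c=r_c, rho2=rho2)


def flip_taylor_coeffs(setup: FlipSetup) -> FlipTaylor:
    """Taylor coefficients and parameter-derivative data at r_c."""
    p = ModelParams(r=setup.r_c, alpha=setup.alpha, gamma=setup.gamma)
    B = taylor_coeffs_B(p)
    fp = interior_fixed_point(p)
    x, _ = fp.state
    a, g = setup.alpha, setup.gamma
    e1x = math.exp(1.0 - x)   # equals e^{(a-2g)/(a-g)}
    opx = 1.0 + x
    dy = e1x / (a - g)        # d y*/dr
    bt17 = (1.0 - x) * e1x
    bt18 = (x - 2.0) * e1x / 2.0
    d_j11 = bt17 - a * dy / opx**2          # = -e1x g^2/(a(a-g))
    d_j21 = a * dy / opx**2
    d_b13 = bt18 + a * dy / opx**3
    d_b23 = -a * dy / opx**3
    return FlipTaylor(B=B, bt17=bt17, bt18=bt18, d_j11=d_j11, d_j21=d_j21,
                      d_b13=d_b13, d_b23=d_b23)


def _composed_coefficients(setup: FlipSetup, bt: FlipTaylor) -> dict:
    """Monomial coefficients of the transformed system in (X, Y, s).

    With (u, v) = M (X, Y), M = [[b, b], [p, q]], p = -1 - B11,
    q = rho2 - B11, the nonlinearity rows transform as
    Psi = (q N1 - b N2)/(b (1 + rho2)), Phi = ((1 + B11) N1 + b N2)/(b (1 + rho2)).
    """
    (B11, B12, B13, B14, B15, B16), (_, _, B23, B24, B25, B26) = bt.B
    b = B12
    if b == 0.0:
        raise DomainError("flip transform requires B12 != 0")
    rho2 = setup.rho2
    pc = -1.0 - B11
    qc = rho2 - B11
    # N_h monomial coefficients after u = b(X+Y), v = pc X + qc Y
    def row(q3, q4, q5, q6, dlin, dquad):
        return {
            "X2": q3 * b * b + q4 * b * pc,
            "XY": 2.0 * q3 * b * b + q4 * b * (pc + qc),
            "X3": q5 * b**3 + q6 * b * b * pc,
            "Xs": dlin * b,
            "Ys": dlin * b,
            "X2s": dquad * b * b,
        }

    n1row = row(B13, B14, B15, B16, bt.d_j11, bt.d_b13)
    n2row = row(B23, B24, B25, B26, bt.d_j21, bt.d_b23)
    den = b * (1.0 + rho2)
    psi = {k: (qc * n1row[k] - b * n2row[k]) / den for k in n1row}
    phi = {k: ((1.0 + B11) * n1row[k] + b * n2row[k]) / den for k in n1row}
    return {"psi": psi, "phi": phi}


def center_manifold(setup: FlipSetup, bt: FlipTaylor) -> tuple[float, float]:
    """Center-manifold coefficients (k1, k2) of Y = k1 X^2 + k2 X s.

    k0 = k3 = 0 hold exactly in the tracked-fixed-point frame.  Requires
    rho2 != +/- 1 (guarded in :func:`flip_setup`).
    """
    if abs(setup.rho2 * setup.rho2 - 1.0) <= 1e-12:
        raise DomainError("center manifold undefined: rho2^2 = 1")
    cc = _composed_coefficients(setup, bt)
    k1 = cc["phi"]["X2"] / (1.0 - setup.rho2)
    k2 = -cc["phi"]["Xs"] / (1.0 + setup.rho2)
    return k1, k2


@dataclass(frozen=True)
class FlipCoefficients:
    """Reduced-map coefficients and criticality quantities of the flip."""

    setup: FlipSetup
    taylor: FlipTaylor
    k1: float
    k2: float
    n1: float
    n2: float
    n3: float
    n4: float
    n5: float
    w1: float       # = n2 (transversality)
    w2: float       # = n5 + n1^2 (direction/stability)
    verdict: FlipVerdict

    def to_dict(self) -> dict:
        return {
            "alpha": self.setup.alpha,
            "gamma": self.setup.gamma,
            "r_c": self.setup.r_c,
            "rho2": self.setup.rho2,
            "k1": self.k1,
            "k2": self.k2,
            "n": [self.n1, self.n2, self.n3, self.n4, self.n5],
            "w1": self.w1,
            "w2": self.w2,
            "verdict": self.verdict.value,
        }


def reduced_map_coeffs(
    setup: FlipSetup, bt: FlipTaylor, k1: float, k2: float
) -> FlipCoefficients:
    """Coefficients n1..n5 of the reduced map L and the flip verdict."""
    cc = _composed_coefficients(setup, bt)
    psi = cc["psi"]
    n1 = psi["X2"]
    n2 = psi["Xs"]
    n5 = psi["X3"] + psi["XY"] * k1
    n3 = psi["X2s"] + psi["XY"] * k2 + psi["Ys"] * k1
    n4 = psi["Ys"] * k2
    w1 = n2
    w2 = n5 + n1 * n1
    if abs(w1) < DEGENERACY_TOL or abs(w2) < DEGENERACY_TOL:
        verdict = FlipVerdict.DEGENERATE
    elif w2 > 0.0:
        verdict = FlipVerdict.STABLE_PERIOD2
    else:
        verdict = FlipVerdict.UNSTABLE_PERIOD2
    return FlipCoefficients(
        setup=setup, taylor=bt, k1=k1, k2=k2,
        n1=n1, n2=n2, n3=n3, n4=n4, n5=n5, w1=w1, w2=w2, verdict=verdict,
    )


def flip_analysis(alpha: float, gamma: float) -> FlipCoefficients:
    """Full flip normal-form pipeline at p1 for the given (alpha, gamma)."""
    setup = flip_setup(alpha, gamma)
    bt = flip_taylor_coeffs(setup)
    k1, k2 = center_manifold(setup, bt)
    return reduced_map_coeffs(setup, bt, k1, k2)
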