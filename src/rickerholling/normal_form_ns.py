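"""Neimark-Sacker normal-form data at the coexistence point p1.

Pipeline, for parameters (alpha, gamma) and rate r = r* + eps:

1. linear data: the complex multiplier pair rho = eta +/- i zeta of J(p1),
   its modulus sqrt(det), the transversality derivative d|rho|/d eps, and
   strong-resonance flags (rho^m != 1 for m = 1..4);
2. Taylor coefficients B_ij of the map shifted so p1 sits at the origin,
   through third order;
3. the coefficients A_ij of the nonlinearity after the real eigenbasis
   transformation (u, v) = T (X, Y) with T = [[B12, 0], [eta - B11, -zeta]],
   which brings the linear part to the rotation [[eta, -zeta], [zeta, eta]];
4. the complex normal-form combinations delta_11, delta_20, delta_02,
   delta_21 and the first Lyapunov coefficient chi.  chi < 0 means an
   attracting invariant closed curve bifurcates from p1, chi > 0 a
   repelling one.

The A_ij are the exact transformed Taylor coefficients (derived from the
transformation itself and cross-checked against a numerical Taylor oracle
of the actually-transformed map in the test suite).  In the delta formulas
the symbol printed as "l" in source material is the imaginary unit.

Because det - 1 at p1 is proportional to r times a parameter-only factor,
criticality in r is degenerate for this map: det = 1 either for no r > 0 or
for every r (on the surface gamma^2 - gamma + alpha^2 - 2 alpha gamma = 0).
chi is therefore exposed as a standalone computation at user-supplied
(alpha, gamma, r) rather than tied to a solved critical rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import DomainError, ModelParams, interior_fixed_point, interior_trace_det
from .stability import NUMERIC_TOL

__all__ = [
    "NSLinearData",
    "NSCoefficients",
    "ns_linear_data",
    "taylor_coeffs_B",
    "transform_coeffs_A",
    "deltas_from_A",
    "chi_from_deltas",
    "first_lyapunov_chi",
    "RESONANCE_TOL",
]

#: |rho^m - 1| must exceed this for m = 1..4 (strong-resonance exclusion)
RESONANCE_TOL = 1e-6


@dataclass(frozen=True)
class NSLinearData:
    """Linearization of the map at p1 in the complex-pair regime."""

    eta: float           # real part of the critical multiplier pair
    zeta: float          # imaginary part (> 0)
    rho: complex         # eta + i zeta
    modulus: float       # |rho| = sqrt(det)
    dmod_deps: float     # d|rho|/d eps at the given deviation
    resonance_ok: dict   # {m: |rho^m - 1| > RESONANCE_TOL} for m = 1..4
    epsilon: float       # deviation eps with r = r* + eps


@dataclass(frozen=True)
class NSCoefficients:
    """Normal-form data: Taylor B, transformed A, deltas and chi."""

    B: np.ndarray        # shape (2, 6): rows u/v-equation, cols B_*1..B_*6
    A: np.ndarray        # shape (2, 4): rows Psi/Phi, cols A_*1..A_*4
    delta11: complex
    delta20: complex
    delta02: complex
    delta21: complex
    chi: float
    linear: NSLinearData
    verdict: str

    def to_dict(self) -> dict:
        c = lambda z: {"re": z.real, "im": z.imag}
        return {
            "B": self.B.tolist(),
            "A": self.A.tolist(),
            "delta11": c(self.delta11),
            "delta20": c(self.delta20),
            "delta02": c(self.delta02),
            "delta21": c(self.delta21),
            "chi": self.chi,
            "rho": c(self.linear.rho),
            "modulus": self.linear.modulus,
            "transversality": self.linear.dmod_deps,
            "resonance_ok": {str(m): bool(v) for m, v in self.linear.resonance_ok.items()},
            "verdict": self.verdict,
        }


def ns_linear_data(p: ModelParams, eps: float = 0.0) -> NSLinearData:
    """Multiplier pair and transversality data at p1 for rate r = p.r + eps.

    Raises :class:`DomainError` when the multipliers are real (flip regime)
    or when det <= 0.
    """
    pr = p.with_r(p.r + eps)
    trace, det = interior_trace_det(pr)
    disc = 4.0 * det - trace * trace
    if disc <= 0.0:
        raise DomainError(
            "multipliers at p1 are real (trace^2 >= 4 det): flip regime, no "
            "Neimark-Sacker pair for r={:.6g}".format(pr.r)
        )
    eta = trace / 2.0
    zeta = math.sqrt(disc) / 2.0
    rho = complex(eta, zeta)
    modulus = math.sqrt(det)
    # |rho|(eps) = sqrt(det(eps)) with det linear in r: d|rho|/deps = det'/(2 sqrt(det))
    a, g = p.alpha, p.gamma
    det_slope = p.exp_factor * g * (g * g - g + a * a - 2.0 * a * g) / (a * (a - g))
    dmod = det_slope / (2.0 * modulus)
    resonance = {m: abs(rho**m - 1.0) > RESONANCE_TOL for m in (1, 2, 3, 4)}
    return NSLinearData(
        eta=eta, zeta=zeta, rho=rho, modulus=modulus, dmod_deps=dmod,
        resonance_ok=resonance, epsilon=eps,
    )


def taylor_coeffs_B(p: ModelParams) -> np.ndarray:
    """Taylor coefficients of the p1-shifted map, through third order.

    Returns a (2, 6) array ``B`` with ``B[0]`` = (B11..B16) for the prey
    equation and ``B[1]`` = (B21..B26) for the predator equation, ordered as
    the monomials (u, v, u^2, uv, u^3, u^2 v).  B11, B12, B21, B22 are the
    Jacobian entries; at p1, B22 = 1 exactly.
    """
    fp = interior_fixed_point(p)
    x, y = fp.state
    e1x = math.exp(1.0 - x)
    opx = 1.0 + x
    a = p.alpha
    B = np.empty((2, 6))
    B[0, 0] = 1.0 + p.r * e1x * (1.0 - x) - a * y / opx**2
    B[0, 1] = -a * x / opx
    B[0, 2] = p.r * e1x * (x - 2.0) / 2.0 + a * y / opx**3
    B[0, 3] = -a / opx**2
    B[0, 4] = p.r * e1x * (3.0 - x) / 6.0 - a * y / opx**4
    B[0, 5] = a / opx**3
    B[1, 0] = a * y / opx**2
    B[1, 1] = (1.0 - p.gamma) + a * x / opx
    B[1, 2] = -a * y / opx**3
    B[1, 3] = a / opx**2
    B[1, 4] = a * y / opx**4
    B[1, 5] = -a / opx**3
    return B


def transform_coeffs_A(B: np.ndarray, eta: float, zeta: float) -> np.ndarray:
    """Nonlinearity coefficients after the real eigenbasis transformation.

    With (u, v) = T (X, Y), T = [[B12, 0], [eta - B11, -zeta]], the
    transformed nonlinearities are

      Psi = A11 X^3 + A12 X Y + A13 X^2 + A14 X^2 Y + O(4)
      Phi = A21 X^3 + A22 X Y + A23 X^2 + A24 X^2 Y + O(4)

    Returns a (2, 4) array, rows (Psi, Phi), columns (A_*1..A_*4).
    """
    (B11, B12, B13, B14, B15, B16), (B21, B22, B23, B24, B25, B26) = B
    if B12 == 0.0:
        raise DomainError("eigenbasis transform requires B12 != 0")
    if zeta == 0.0:
        raise DomainError("eigenbasis transform requires a complex pair (zeta != 0)")
    w = eta - B11
    A = np.empty((2, 4))
    A[0, 0] = B12 * (B12 * B15 + B16 * w)
    A[0, 1] = -zeta * B14
    A[0, 2] = B12 * B13 + B14 * w
    A[0, 3] = -zeta * B12 * B16
    A[1, 0] = B12 * (-B25 * B12**2 + B12 * (B15 - B26) * w + B16 * w**2) / zeta
    A[1, 1] = B12 * B24 - B14 * w
    A[1, 2] = (-B23 * B12**2 + B12 * (B13 - B24) * w + B14 * w**2) / zeta
    A[1, 3] = B12 * (B12 * B26 - B16 * w)
    return A


def deltas_from_A(A: np.ndarray) -> tuple[complex, complex, complex, complex]:
    """Complex normal-form combinations (delta11, delta20, delta02, delta21).

    From the second/third partials of (Psi, Phi) at the origin
    (Psi_XX = 2 A13, Psi_XY = A12, Psi_XXY = 2 A14, Psi_XXX = 6 A11 and the
    Phi analogues; all pure-Y partials vanish):

      delta11 = (A13 + i A23)/2
      delta20 = (A13 + A22 + i (A23 - A12))/4
      delta02 = (A13 + A22 + i (A23 + A12))/4
      delta21 = (3 A11 + A24 + i (3 A21 - A14))/8

    The A14 in delta21's imaginary part comes from Psi_XXY; it makes chi
    exactly invariant under the conjugate multiplier choice.
    """
    (A11, A12, A13, A14), (A21, A22, A23, A24) = A
    d11 = (A13 + 1j * A23) / 2.0
    d20 = (A13 + A22 + 1j * (A23 - A12)) / 4.0
    d02 = (A13 + A22 + 1j * (A23 + A12)) / 4.0
    d21 = (3.0 * A11 + A24 + 1j * (3.0 * A21 - A14)) / 8.0
    return d11, d20, d02, d21


def chi_from_deltas(
    rho: complex, d11: complex, d20: complex, d02: complex, d21: complex
) -> float:
    """First Lyapunov coefficient of the discrete Neimark-Sacker normal form."""
    rb = rho.conjugate()
    term = ((1.0 - 2.0 * rb) * rb**2 / (1.0 - rho)) * d11 * d20
    return (
        -term.real
        - 0.5 * abs(d11) ** 2
        - abs(d02) ** 2
        + (rb * d21).real
    )


def first_lyapunov_chi(p: ModelParams, B: np.ndarray | None = None) -> NSCoefficients:
    """Full Neimark-Sacker normal-form computation at p1 for rate p.r.

    ``B`` may be supplied externally (e.g. finite-difference estimates) to
    cross-check the analytic Taylor coefficients; by default the closed-form
    coefficients are used.  Raises :class:`DomainError` in the real-multiplier
    regime or within tolerance of a strong resonance.
    """
    lin = ns_linear_data(p, eps=0.0)
    for m, ok in lin.resonance_ok.items():
        if not ok:
            raise DomainError(
                f"strong resonance: |rho^{m} - 1| <= {RESONANCE_TOL:g} at r={p.r:.6g}"
            )
    if B is None:
        B = taylor_coeffs_B(p)
    A = transform_coeffs_A(B, lin.eta, lin.zeta)
    d11, d20, d02, d21 = deltas_from_A(A)
    chi = chi_from_deltas(lin.rho, d11, d20, d02, d21)
    if abs(chi) <= NUMERIC_TOL:
        verdict = "degenerate (chi ~ 0)"
    elif chi < 0.0:
        verdict = "attracting invariant closed curve (chi < 0)"
    else:
        verdict = "repelling invariant closed curve (chi > 0)"
    return NSCoefficients(
        B=B, A=A, delta11=d11, delta20=d20, delta02=d02, delta21=d21,
        chi=chi, linear=lin, verdict=verdict,
    )
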