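"""Shared fixtures and independent numerical oracles.

The Taylor oracle fits a full bivariate polynomial (total degree 6) to map
values sampled on a small grid around the expansion point and reads the
coefficients off the least-squares fit; with radius 1e-2 the fit recovers
third-order Taylor coefficients of this map to ~1e-6 relative, well inside
the 1e-5 comparison tolerance used by the normal-form tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from rickerholling import (
    ModelParams,
    State,
    interior_fixed_point,
    step,
)

# monomial order used for state-Taylor comparisons: u, v, u^2, uv, u^3, u^2 v
B_MONOMIALS = [(1, 0), (0, 1), (2, 0), (1, 1), (3, 0), (2, 1)]
# monomial order for transformed coefficients: X^3, XY, X^2, X^2 Y
A_MONOMIALS = [(3, 0), (1, 1), (2, 0), (2, 1)]


def poly_fit_taylor(f, radius: float = 1e-2, deg: int = 6) -> dict:
    """Taylor coefficients of f: R^2 -> R^m via a polynomial least-squares fit.

    Returns a dict (i, j) -> coefficient vector for the monomial u^i v^j.
    """
    ts = np.linspace(-1.0, 1.0, deg + 3) * radius
    pts = [(u, v) for u in ts for v in ts]
    monos = [(i, d - i) for d in range(deg + 1) for i in range(d + 1)]
    design = np.array([[u**i * v**j for (i, j) in monos] for (u, v) in pts])
    vals = np.array([np.atleast_1d(f(u, v)) for (u, v) in pts])
    coef, *_ = np.linalg.lstsq(design, vals, rcond=None)
    return {m: coef[k] for k, m in enumerate(monos)}


def shifted_map(p: ModelParams):
    """The map in coordinates centred on the interior fixed point."""
    fp = interior_fixed_point(p).state

    def f(u: float, v: float) -> np.ndarray:
        s = step(State(fp.x + u, fp.y + v), p)
        return np.array([s.x - fp.x, s.y - fp.y])

    return f


def oracle_taylor_B(p: ModelParams) -> np.ndarray:
    """Independent (2, 6) Taylor-coefficient estimate of the shifted map."""
    C = poly_fit_taylor(shifted_map(p))
    return np.array([[C[m][row] for m in B_MONOMIALS] for row in (0, 1)])


def fd_jacobian(s: State, p: ModelParams, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the map at a state."""

    def col(dx: float, dy: float) -> np.ndarray:
        sp = step(State(s.x + dx, s.y + dy), p)
        sm = step(State(s.x - dx, s.y - dy), p)
        return (np.array(sp) - np.array(sm)) / (2.0 * h)

    return np.column_stack([col(h, 0.0), col(0.0, h)])


@pytest.fixture(scope="session")
def case3_params() -> ModelParams:
    """Period-doubling scenario: alpha=0.5, gamma=0.3, LAS regime rate."""
    return ModelParams(r=3.5, alpha=0.5, gamma=0.3)


@pytest.fixture(scope="session")
def case1_cascade_rows():
    """Warm-start sweep of the alpha=1, gamma=0.5 diagram across its
    period-doubling cascade (r in [5.2, 5.675]); shared by the cascade,
    chaos and acceptance tests because it is the most expensive sweep."""
    from rickerholling import SweepSettings, sweep

    settings = SweepSettings(
        transient=40_000, n_samples=64, mle_steps=4000, warm_start=True, seed=0
    )
    return sweep(1.0, 0.5, 5.2, 5.675, 239, x0=State(0.33, 0.64), settings=settings)
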