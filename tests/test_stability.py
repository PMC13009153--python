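"""Jury classification, interior stability conditions, critical rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rickerholling import (
    Classification,
    DomainError,
    ModelParams,
    classify_fixed_point,
    critical_r_flip,
    fixed_points,
    interior_fixed_point,
    interior_trace_det,
    jury_classify,
    ns_condition,
    prop_interior_conditions,
    prop_trivial_condition_as_printed,
)
from rickerholling.model import _quadratic_multipliers
from rickerholling.stability import CORRECTION_TRIVIAL_POINT, flip_condition


class TestJuryClassify:
    @pytest.mark.parametrize(
        "trace,det,expected",
        [
            (0.0, 0.5, Classification.LAS),                 # complex pair, |rho|=sqrt(.5)
            (0.0, 1.0, Classification.NON_HYPERBOLIC),      # unit-modulus complex pair
            (0.0894284, -0.6558287, Classification.LAS),    # roots 0.8558, -0.7664
            (0.0, 2.0, Classification.SOURCE),
            (2.5, 1.0, Classification.SADDLE),              # roots 2, 0.5
            (-2.0, 1.0, Classification.NON_HYPERBOLIC),     # double root -1
        ],
    )
    def test_examples(self, trace, det, expected):
        assert jury_classify(trace, det) is expected

    def test_agrees_with_direct_multiplier_moduli(self):
        rng = np.random.default_rng(11)
        tol = 1e-9
        for _ in range(10_000):
            trace = rng.uniform(-3.0, 3.0)
            det = rng.uniform(-3.0, 3.0)
            m1, m2 = (abs(z) for z in _quadratic_multipliers(trace, det))
            cls = jury_classify(trace, det, tol)
            if abs(m1 - 1.0) <= tol or abs(m2 - 1.0) <= tol:
                assert cls is Classification.NON_HYPERBOLIC
            elif m1 < 1.0 and m2 < 1.0:
                assert cls is Classification.LAS
            elif m1 > 1.0 and m2 > 1.0:
                assert cls is Classification.SOURCE
            else:
                assert cls is Classification.SADDLE

    def test_las_iff_jury_sign_pattern(self):
        # LAS <=> R(1) > 0, R(-1) > 0, det < 1 (away from the boundaries)
        rng = np.random.default_rng(12)
        for _ in range(2000):
            trace = rng.uniform(-3.0, 3.0)
            det = rng.uniform(-3.0, 3.0)
            R1, Rm1 = 1.0 - trace + det, 1.0 + trace + det
            if min(abs(R1), abs(Rm1), abs(det - 1.0)) < 1e-6:
                continue
            pattern = R1 > 0.0 and Rm1 > 0.0 and det < 1.0
            assert (jury_classify(trace, det) is Classification.LAS) == pattern

    def test_bad_tol_rejected(self):
        with pytest.raises(DomainError):
            jury_classify(0.0, 0.5, tol=0.5)


class TestClassifyFixedPoint:
    def test_interior_las_then_saddle_across_flip(self):
        r_c = critical_r_flip(0.5, 0.3)
        for r in list(np.linspace(0.1, r_c - 1e-3, 8)):
            p = ModelParams(r=float(r), alpha=0.5, gamma=0.3)
            rep = classify_fixed_point(interior_fixed_point(p), p)
            assert rep.classification in (Classification.LAS, Classification.NON_HYPERBOLIC)
        for r in list(np.linspace(r_c + 1e-3, r_c + 0.5, 8)):
            p = ModelParams(r=float(r), alpha=0.5, gamma=0.3)
            rep = classify_fixed_point(interior_fixed_point(p), p)
            assert rep.classification is Classification.SADDLE

    def test_interior_saddle_at_r4(self):
        p = ModelParams(r=4.0, alpha=0.5, gamma=0.3)
        rep = classify_fixed_point(interior_fixed_point(p), p)
        assert rep.classification is Classification.SADDLE
        # the flipped multiplier just past criticality
        rho_neg = min((rep.jac.rho1.real, rep.jac.rho2.real))
        assert rho_neg == pytest.approx(-1.0408572, abs=1e-6)

    def test_trivial_point_always_saddle_for_moderate_gamma(self):
        # {1 + r e, 1 - gamma}: one multiplier always outside the unit circle
        rng = np.random.default_rng(13)
        for _ in range(100):
            p = ModelParams(r=rng.uniform(0.01, 8.0), alpha=1.0, gamma=rng.uniform(0.01, 1.99))
            rep = classify_fixed_point(fixed_points(p)[0], p)
            assert rep.classification is Classification.SADDLE
            assert CORRECTION_TRIVIAL_POINT in rep.corrections_applied

    def test_as_printed_trivial_condition_is_exposed(self):
        p = ModelParams(r=1.0, alpha=1.0, gamma=0.5)
        lhs, rhs = prop_trivial_condition_as_printed(p)
        assert lhs == pytest.approx(math.e * 0.5)
        assert rhs == 0.5


class TestInteriorConditions:
    def test_condition_values_case3(self):
        # condition (ii): R(-1) = 4 - 1.0189715 r at alpha=0.5, gamma=0.3
        slope = 0.3 * (0.09 - 0.6 + 0.25 - 0.3) / (0.5 * 0.2) * math.exp(-0.5)
        p = ModelParams(r=3.5, alpha=0.5, gamma=0.3)
        c1, c2, c3 = prop_interior_conditions(p)
        assert c2 == pytest.approx(4.0 + slope * 3.5, rel=1e-12)
        assert c2 == pytest.approx(0.4336, abs=1e-4)
        assert c1 > 0.0 and c3 < 0.0  # LAS sign pattern (+, +, -)

    def test_conditions_equal_jury_values_at_p1(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            alpha = rng.uniform(0.3, 3.0)
            gamma = rng.uniform(0.05, alpha * 0.95)
            p = ModelParams(r=rng.uniform(0.1, 5.0), alpha=alpha, gamma=gamma)
            trace, det = interior_trace_det(p)
            c1, c2, c3 = prop_interior_conditions(p)
            assert c1 == pytest.approx(1.0 - trace + det, rel=1e-10, abs=1e-12)
            assert c2 == pytest.approx(1.0 + trace + det, rel=1e-10, abs=1e-12)
            assert c3 == pytest.approx(det - 1.0, rel=1e-10, abs=1e-12)

    def test_degenerate_surface_condition_iii_vanishes(self):
        for r in (0.5, 2.0, 5.0):
            p = ModelParams(r=r, alpha=2.0, gamma=1.0)
            _, _, c3 = prop_interior_conditions(p)
            assert abs(c3) < 1e-12


class TestCriticalRFlip:
    def test_case3_value(self):
        assert critical_r_flip(0.5, 0.3) == pytest.approx(3.925527, abs=5e-7)

    def test_case1_value_is_16_over_3(self):
        assert critical_r_flip(1.0, 0.5) == pytest.approx(16.0 / 3.0, rel=1e-12)

    def test_degenerate_surface_raises(self):
        # at (2, 1) the R(-1) root r = 8 has det = 1: a 1:2 resonance, not a
        # generic flip
        with pytest.raises(DomainError):
            critical_r_flip(2.0, 1.0)

    def test_no_positive_root_raises(self):
        # gamma^2 - 2 gamma + alpha^2 - 2 alpha gamma > 0 for alpha >> gamma
        with pytest.raises(DomainError):
            critical_r_flip(4.0, 0.1)

    def test_multiplier_reaches_minus_one_at_r_c(self):
        for alpha, gamma in [(0.5, 0.3), (1.0, 0.5), (0.8, 0.45)]:
            r_c = critical_r_flip(alpha, gamma)
            trace, det = interior_trace_det(ModelParams(r=r_c, alpha=alpha, gamma=gamma))
            rhos = _quadratic_multipliers(trace, det)
            assert min(abs(rho + 1.0) for rho in rhos) < 1e-10

    def test_bisection_oracle_agreement(self):
        # bracket a multiplier crossing of -1 and bisect on its real part
        for alpha, gamma in [(0.5, 0.3), (1.0, 0.5)]:
            r_c = critical_r_flip(alpha, gamma)

            def rho_plus_one(r):
                trace, det = interior_trace_det(ModelParams(r=r, alpha=alpha, gamma=gamma))
                rhos = _quadratic_multipliers(trace, det)
                return min((z.real for z in rhos), key=lambda v: abs(v + 1.0)) + 1.0

            lo, hi = 0.8 * r_c, 1.2 * r_c
            assert rho_plus_one(lo) * rho_plus_one(hi) < 0.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if rho_plus_one(lo) * rho_plus_one(mid) <= 0.0:
                    hi = mid
                else:
                    lo = mid
            assert 0.5 * (lo + hi) == pytest.approx(r_c, abs=1e-8)


class TestNSCondition:
    def test_degenerate_surface_residual_zero(self):
        for r in (0.5, 2.0, 3.598768):
            cond = ns_condition(ModelParams(r=r, alpha=2.0, gamma=1.0))
            assert abs(cond.residual) < 1e-12
            assert cond.side_conditions["degenerate_surface"]

    def test_case3_residual_value(self):
        # det - 1 = r e^{-1/2} * 0.3*(-0.26)/0.1 = -0.4730939 r
        cond = ns_condition(ModelParams(r=3.5, alpha=0.5, gamma=0.3))
        assert cond.residual == pytest.approx(-0.4730939 * 3.5, abs=5e-6)

    def test_surface_root_in_alpha(self):
        # alpha^2 - 0.6 alpha - 0.21 = 0  =>  alpha = (0.6 + sqrt(1.2))/2
        alpha = (0.6 + math.sqrt(1.2)) / 2.0
        for r in (0.5, 2.0):
            cond = ns_condition(ModelParams(r=r, alpha=alpha, gamma=0.3))
            assert abs(cond.residual) < 1e-12

    def test_flip_condition_residual_matches_jury(self):
        p = ModelParams(r=3.5, alpha=0.5, gamma=0.3)
        trace, det = interior_trace_det(p)
        assert flip_condition(p).residual == pytest.approx(1.0 + trace + det, rel=1e-12)
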