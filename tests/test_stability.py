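"""Tests for Jacobians, characteristic polynomial and stability verdicts."""

import numpy as np
import pytest

from notchfde import (
    CellTopology,
    CharPoly,
    ModelParameters,
    characteristic_coefficients,
    e0_eigenvalues,
    effective_rates,
    equilibrium_no_delta,
    equilibrium_with_delta,
    fractional_arg_condition,
    full_jacobian,
    jacobian,
    rhs,
    routh_hurwitz,
    stability_report,
    sufficient_condition_ratio,
)


def finite_difference_jacobian(params, topology, state, lam=None, eps=1e-6):
    state = np.asarray(state, float).ravel()
    n = state.size
    J = np.empty((n, n))
    for j in range(n):
        plus, minus = state.copy(), state.copy()
        plus[j] += eps
        minus[j] -= eps
        fp = rhs(plus.reshape(-1, 3), params, topology, lam).ravel()
        fm = rhs(minus.reshape(-1, 3), params, topology, lam).ravel()
        J[:, j] = (fp - fm) / (2 * eps)
    return J


class TestJacobian:
    def test_block_at_no_delta_equilibrium_is_triangular(self, table1_zero):
        e = effective_rates(table1_zero)
        n0 = e.lambda_notch / e.d
        J = jacobian(table1_zero, (0.0, n0, 0.0))
        # lam = 0 kills the inhibition column; D = 0 kills the D columns
        assert J[0, 1] == 0.0 and J[0, 2] == 0.0 and J[1, 2] == 0.0
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvals(J).real),
            np.sort(e0_eigenvalues(table1_zero)),
            rtol=1e-10,
        )

    def test_full_jacobian_matches_finite_differences(self, table1, rng):
        topo = CellTopology.grid(2, 3)
        lam = rng.uniform(0, 1500, size=6)
        for _ in range(20):
            state = rng.uniform(0.05, 8.0, size=(6, 3))
            J = full_jacobian(table1, topo, state, lambda_per_cell=lam)
            J_fd = finite_difference_jacobian(table1, topo, state, lam)
            np.testing.assert_allclose(J, J_fd, rtol=2e-5, atol=1e-6)

    def test_two_cell_full_jacobian_matches_finite_differences(self, table1, pair, rng):
        for _ in range(10):
            state = rng.uniform(0.05, 10.0, size=(2, 3))
            J = full_jacobian(table1, pair, state)
            J_fd = finite_difference_jacobian(table1, pair, state)
            np.testing.assert_allclose(J, J_fd, rtol=2e-5, atol=1e-6)


class TestE0Eigenvalues:
    def test_frozen_values_at_table1(self, table1_zero):
        eigs = e0_eigenvalues(table1_zero)
        assert eigs[0] == pytest.approx(-0.015848931924611134, rel=1e-12)
        assert eigs[1] == eigs[0]
        assert eigs[2] == pytest.approx(-0.1071736280924389, rel=1e-12)

    def test_always_negative_real(self, rng):
        for _ in range(50):
            p = ModelParameters(
                lambda_delta=0.0,
                lambda_notch=rng.uniform(0.001, 10),
                f=rng.uniform(1e-4, 1),
                d=rng.uniform(1e-4, 1),
                a=rng.uniform(1e-4, 1),
                b=rng.uniform(1, 1000),
                theta=rng.uniform(0, 1e8),
                alpha=rng.uniform(0.05, 1.0),
            )
            eigs = e0_eigenvalues(p)
            assert np.all(eigs < 0)
            verdict, _ = fractional_arg_condition(eigs, p.alpha)
            assert verdict == "stable"

    def test_matches_numeric_block_eigenvalues(self, table1_zero):
        e = effective_rates(table1_zero)
        J = jacobian(table1_zero, (0.0, e.lambda_notch / e.d, 0.0))
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvals(J).real),
            np.sort(e0_eigenvalues(table1_zero)),
            atol=1e-10,
        )


class TestCharacteristicPolynomial:
    def test_monic_by_construction(self, table1):
        eq = equilibrium_with_delta(table1)
        assert characteristic_coefficients(table1, eq).a3 == 1.0
        with pytest.raises(ValueError, match="monic"):
            CharPoly(a3=2.0, a2=1.0, a1=1.0, a0=1.0)

    def test_roots_equal_block_jacobian_eigenvalues(self, table1):
        eq = equilibrium_with_delta(table1)
        char = characteristic_coefficients(table1, eq)
        roots = np.sort_complex(char.roots())
        eigs = np.sort_complex(np.linalg.eigvals(jacobian(table1, eq.values[0])))
        np.testing.assert_allclose(roots, eigs, atol=1e-8)

    def test_no_binding_limit_by_symbolic_substitution(self, table1):
        # f -> 0: the off-diagonal binding entries vanish; a2 reduces to
        # 3 d^a and the coupling term survives through a1, a0
        sympy = pytest.importorskip("sympy")
        eq = equilibrium_with_delta(table1)
        D, N, A = eq.values[0]
        p_small = table1.replace(f=1e-12)
        e = effective_rates(p_small)
        char = characteristic_coefficients(p_small, eq)
        d_, a_, b_, th, lam = sympy.symbols("d a b th lam", positive=True)
        Ds, Ns, As = sympy.symbols("D N A", positive=True)
        coupling = a_ * b_ * th * lam / ((1 + th * As) ** 2 * (b_ + Ds * Ns) ** 2)
        subs = {
            d_: e.d,
            a_: e.a,
            b_: e.b,
            th: e.theta,
            lam: e.lambda_delta,
            Ds: D,
            Ns: N,
            As: A,
        }
        assert char.a2 == pytest.approx(float((3 * d_).evalf(subs=subs)), rel=1e-6)
        assert char.a1 == pytest.approx(
            float((3 * d_**2 + coupling * Ns).evalf(subs=subs)), rel=1e-6
        )
        assert char.a0 == pytest.approx(
            float((d_**3 + coupling * d_ * Ns).evalf(subs=subs)), rel=1e-6
        )


class TestRouthHurwitz:
    def test_simple_stable_cubic(self):
        ok, detail = routh_hurwitz(CharPoly(1.0, 2.0, 3.0, 1.0))
        assert ok and detail["a2a1_minus_a3a0"] == pytest.approx(5.0)

    def test_simple_unstable_cubic(self):
        ok, detail = routh_hurwitz(CharPoly(1.0, 1.0, 1.0, 2.0))
        assert not ok and detail["a2a1_minus_a3a0"] == pytest.approx(-1.0)

    def test_agrees_with_eigensolver_over_random_draws(self, rng):
        for _ in range(200):
            a2, a1, a0 = rng.uniform(-3, 3, size=3)
            char = CharPoly(1.0, a2, a1, a0)
            roots = char.roots()
            if np.any(np.abs(roots.real) < 1e-9):
                continue  # boundary cases excluded by construction
            ok, _ = routh_hurwitz(char)
            assert ok == bool(np.all(roots.real < 0))


class TestArgCondition:
    def test_negative_real_axis_is_stable(self):
        verdict, margins = fractional_arg_condition([-1.0], 0.9)
        assert verdict == "stable"
        assert margins[0] == pytest.approx(np.pi - 0.45 * np.pi)

    def test_positive_real_axis_is_unstable_for_any_order(self):
        for alpha in (0.1, 0.5, 1.0):
            verdict, _ = fractional_arg_condition([1.0], alpha)
            assert verdict == "unstable"

    def test_verdict_flips_at_sector_boundary(self):
        # complex pair at |arg| = 0.4*pi crosses the sector at alpha = 0.8
        z = np.exp(1j * 0.4 * np.pi)
        pair = [z, np.conj(z)]
        assert fractional_arg_condition(pair, 0.79)[0] == "stable"
        assert fractional_arg_condition(pair, 0.81)[0] == "unstable"
        assert fractional_arg_condition(pair, 0.8)[0] == "inconclusive"

    def test_origin_is_inconclusive(self):
        verdict, _ = fractional_arg_condition([0.0, -1.0], 0.9)
        assert verdict == "inconclusive"


class TestSufficientCondition:
    def test_table1_value_direct_arithmetic(self, table1):
        e = effective_rates(table1)
        expected = (e.d**3 + e.f**2 * e.d) / (
            4 * e.f**2 * e.lambda_notch + 2 * e.f * e.d**2
        )
        ratio, holds = sufficient_condition_ratio(table1)
        assert ratio == pytest.approx(expected, rel=1e-14)
        assert holds and ratio < 1

    def test_decreasing_in_binding_rate_toward_asymptote(self, table1):
        # ratio falls with f over the physiological range and levels off at
        # d^a / (4 lamN^a) as the f^2 terms dominate
        ratios = [
            sufficient_condition_ratio(table1.replace(f=f))[0]
            for f in np.geomspace(0.005, 0.1, 10)
        ]
        assert np.all(np.diff(ratios) < 0)
        e = effective_rates(table1)
        limit = sufficient_condition_ratio(table1.replace(f=100.0))[0]
        assert limit == pytest.approx(e.d / (4 * e.lambda_notch), rel=1e-3)

    def test_ratio_below_one_implies_rh_stable_equilibrium(self, rng):
        checked = 0
        for _ in range(30):
            p = ModelParameters(
                lambda_delta=rng.uniform(10, 3000),
                lambda_notch=rng.uniform(0.01, 0.5),
                f=rng.uniform(0.002, 0.05),
                d=rng.uniform(0.002, 0.05),
                a=rng.uniform(0.002, 0.05),
                b=rng.uniform(50, 500),
                theta=rng.uniform(1e3, 1e7),
                alpha=rng.uniform(0.5, 1.0),
            )
            ratio, holds = sufficient_condition_ratio(p)
            if not holds:
                continue
            eq = equilibrium_with_delta(p)
            ok, _ = routh_hurwitz(characteristic_coefficients(p, eq))
            assert ok, f"ratio {ratio} < 1 but RH failed at {p}"
            checked += 1
        assert checked >= 10

    def test_rh_implies_sector_condition_for_all_orders(self, table1):
        eq = equilibrium_with_delta(table1)
        char = characteristic_coefficients(table1, eq)
        assert routh_hurwitz(char)[0]
        for alpha in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0):
            verdict, _ = fractional_arg_condition(char.roots(), alpha)
            assert verdict == "stable"


class TestStabilityReport:
    def test_report_for_both_equilibria(self, table1, table1_zero):
        rep0 = stability_report(table1_zero, equilibrium_no_delta(table1_zero))
        assert rep0.verdict == "stable" and rep0.char is None
        rep1 = stability_report(table1, equilibrium_with_delta(table1))
        assert rep1.verdict == "stable"
        assert rep1.rh_stable and rep1.sufficient_holds
        # per-cell reduction vs the unreduced 6x6 system: the reduced
        # spectrum must be a subset of the full spectrum
        eq = equilibrium_with_delta(table1)
        full = np.linalg.eigvals(
            full_jacobian(table1, CellTopology.pair(), eq.values)
        )
        for xi in rep1.eigenvalues:
            assert np.min(np.abs(full - xi)) < 1e-8
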