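import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings

from rumorctl import (
    CharCoeffs,
    CrossingCubic,
    DegenerateCrossingError,
    char_coeffs,
    char_residual,
    critical_delays,
    crossing_cubic,
    crossing_direction,
    equilibria_S1,
    equilibria_S2,
    hopf_frequencies,
    hopf_result,
    stability_intervals,
    tau0_stable,
)

from conftest import rates_strategy


def _positive(eqs):
    out = [e for e in eqs if e.label == "positive"]
    return out[0] if out else None


@pytest.fixture
def c_free(params_sliding):
    return char_coeffs(_positive(equilibria_S1(params_sliding)), params_sliding)


class TestCharCoeffs:
    def test_free_subsystem_values(self, c_free):
        expected = (0.35, 0.277, 0.0252, -0.1, 0.133, 0.0143)
        got = tuple(getattr(c_free, k) for k in ("a1", "a2", "a3", "a4", "a5", "a6"))
        assert got == pytest.approx(expected, rel=1e-10)

    def test_rejects_non_positive_equilibrium(self, params_sliding):
        rumor_free = equilibria_S1(params_sliding)[0]
        with pytest.raises(ValueError):
            char_coeffs(rumor_free, params_sliding)

    def test_controlled_conventions_differ_by_alpha_I(self, params_sliding):
        eq = _positive(equilibria_S2(params_sliding))
        printed = char_coeffs(eq, params_sliding, "printed")
        derived = char_coeffs(eq, params_sliding, "derived")
        assert derived.a6 == pytest.approx(params_sliding.alpha * eq.state.I * printed.a6)
        assert derived.a6 == pytest.approx(0.012863, abs=5e-6)
        assert printed.a6 == pytest.approx(0.18541, abs=5e-5)
        # the remaining coefficients agree
        for k in ("a1", "a2", "a3", "a4", "a5"):
            assert getattr(printed, k) == getattr(derived, k)

    def test_derived_convention_matches_characteristic_determinant(self, params_sliding):
        """Independent oracle: determinant of the linearization's 3x3 matrix."""
        p = params_sliding
        eq = _positive(equilibria_S2(p))
        S, I, R = eq.state
        c = char_coeffs(eq, p, "derived")
        J0 = np.array(
            [
                [-p.beta * I - p.mu, -p.beta * S, 0.0],
                [p.beta * I, p.beta * S - p.alpha * R - p.mu - p.q, 0.0],
                [0.0, p.alpha * R + p.q, -p.mu],
            ]
        )
        Jtau = np.zeros((3, 3))
        Jtau[1, 2] = -p.alpha * I
        Jtau[2, 2] = p.alpha * I
        rng = np.random.default_rng(7)
        for lam in rng.normal(size=4) + 1j * rng.normal(size=4):
            tau = 1.3
            det = np.linalg.det(lam * np.eye(3) - J0 - Jtau * cmath.exp(-lam * tau))
            model = c.P(lam) + c.Q(lam) * cmath.exp(-lam * tau)
            assert det == pytest.approx(model, rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=rates_strategy())
    def test_routh_hurwitz_closed_form_identities(self, p):
        eq = _positive(equilibria_S1(p))
        if eq is None:
            return
        c = char_coeffs(eq, p)
        a, b, m, L = p.alpha, p.beta, p.mu, p.Lambda
        tol = lambda v: max(1.0, abs(v)) * 1e-12  # noqa: E731
        assert abs((c.a1 + c.a4) - m * (a + b) / a) < tol(m * (a + b) / a)
        lhs = c.a3 + c.a6
        rhs = (L * a * b * m - (a + b) * m**3) / a
        assert abs(lhs - rhs) < tol(rhs)
        lhs = (c.a1 + c.a4) * (c.a2 + c.a5) - (c.a3 + c.a6)
        rhs = L * b**2 * m / a
        assert abs(lhs - rhs) < tol(rhs)


class TestTau0Stability:
    def test_free_positive_equilibrium_stable(self, c_free):
        assert tau0_stable(c_free)

    def test_controlled_derived_stable_printed_not(self, params_sliding):
        # the Jacobian-consistent coefficients satisfy Routh-Hurwitz; the
        # printed constant term (missing its alpha*I factor) does not
        eq = _positive(equilibria_S2(params_sliding))
        assert tau0_stable(char_coeffs(eq, params_sliding, "derived"))
        assert not tau0_stable(char_coeffs(eq, params_sliding, "printed"))

    def test_violated_sign_condition(self):
        c = CharCoeffs(1.0, 1.0, 0.0, 0.0, 0.0, -1.0)
        assert not tau0_stable(c)


class TestCrossingCubic:
    def test_coefficients(self, c_free):
        cc = crossing_cubic(c_free)
        assert cc.B1 == pytest.approx(-0.4415, rel=1e-10)
        assert cc.B2 == pytest.approx(0.03854, rel=1e-10)
        assert cc.B3 == pytest.approx(0.00043055, rel=1e-10)
        assert cc.Delta == pytest.approx(4 * cc.B1**2 - 12 * cc.B2)

    def test_constant_term_sign(self):
        c = CharCoeffs(0.0, 0.0, 0.5, 0.0, 0.0, 1.0)
        assert crossing_cubic(c).B3 < 0


class TestFrequencies:
    def test_two_positive_crossings(self, c_free):
        ws = hopf_frequencies(crossing_cubic(c_free))
        assert len(ws) == 2
        assert ws[0] == pytest.approx(0.5610, abs=5e-5)
        assert ws[1] == pytest.approx(0.3699, abs=5e-5)
        assert ws[0] > ws[1]  # descending order

    def test_no_root_when_all_coefficients_positive(self):
        cc = CrossingCubic(1.0, 1.0, 1.0)
        assert cc.Delta <= 0
        assert hopf_frequencies(cc) == []

    def test_returned_frequencies_are_roots(self, c_free):
        cc = crossing_cubic(c_free)
        for w in hopf_frequencies(cc):
            assert abs(cc.h(w**2)) < 1e-8


class TestCriticalDelays:
    @pytest.mark.parametrize("w_idx,tau0", [(0, 1.3845), (1, 5.9800)])
    def test_first_delays(self, c_free, w_idx, tau0):
        w = hopf_frequencies(crossing_cubic(c_free))[w_idx]
        taus = critical_delays(c_free, w, 4)
        assert taus[0] == pytest.approx(tau0, abs=0.01)

    def test_spacing_and_characteristic_residual(self, c_free):
        for w in hopf_frequencies(crossing_cubic(c_free)):
            taus = critical_delays(c_free, w, 4)
            for t1, t2 in zip(taus, taus[1:]):
                assert t2 - t1 == pytest.approx(2 * math.pi / w, rel=1e-12)
            for t in taus:
                assert char_residual(c_free, w, t) < 1e-8

    def test_rejects_non_crossing_frequency(self, c_free):
        with pytest.raises(ValueError):
            critical_delays(c_free, 2.0, 2)


class TestCrossingDirection:
    def test_signs_at_benchmark(self, c_free):
        cc = crossing_cubic(c_free)
        w_hi, w_lo = hopf_frequencies(cc)
        assert crossing_direction(cc, w_hi) == 1
        assert crossing_direction(cc, w_lo) == -1

    def test_single_crossing_enters_rhp(self):
        # h(0) < 0 and h -> +inf: the lone simple positive root crosses upward
        cc = CrossingCubic(0.0, 0.0, -1.0)
        (w,) = hopf_frequencies(cc)
        assert crossing_direction(cc, w) == 1

    def test_degenerate_crossing_rejected(self):
        # double root of h at v=1: h = (v-1)^2 * v
        cc = CrossingCubic(-2.0, 1.0, 0.0)
        assert cc.hprime(1.0) == 0.0
        with pytest.raises(DegenerateCrossingError):
            crossing_direction(cc, 1.0)


class TestStabilityIntervals:
    def test_switching_pattern(self, c_free):
        si = stability_intervals(c_free, tau_max=50.0)
        stable = si.stable_intervals()
        expected = [(0.0, 1.3845), (5.9800, 12.5853), (22.9664, 23.7860)]
        assert len(stable) == 3
        for (lo, hi), (elo, ehi) in zip(stable, expected):
            assert lo == pytest.approx(elo, abs=0.02)
            assert hi == pytest.approx(ehi, abs=0.02)

    def test_permanent_instability_beyond_last_window(self, c_free):
        si = stability_intervals(c_free, tau_max=200.0)
        last_stable = si.stable_intervals()[-1][1]
        assert last_stable == pytest.approx(23.7860, abs=0.02)
        for bp, n in zip([0.0] + si.breakpoints, si.rhp_pairs):
            if bp > 24.0:
                assert n >= 1

    def test_stable_everywhere_without_crossings(self):
        # all-positive crossing cubic has no positive roots
        c = CharCoeffs(3.0, 3.0, 1.0, 0.0, 0.0, 0.1)
        assert hopf_frequencies(crossing_cubic(c)) == []
        si = stability_intervals(c, tau_max=100.0)
        assert si.stable_intervals() == [(0.0, 100.0)]

    def test_hopf_result_reports_first_delay(self, c_free):
        hr = hopf_result(c_free, jmax=2)
        assert hr.tau_star == pytest.approx(1.3845, abs=0.01)
        assert {cr.direction for cr in hr.crossings} == {1, -1}
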