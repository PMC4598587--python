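import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcflipflop.quality import (
    ideal_signal,
    perfect_areas,
    real_areas,
    theta_A,
    theta_S,
)
from mcflipflop.schedule import MINUTE
from mcflipflop.simulate import PhiSeries

BP = np.array([0.0, 180.0, 900.0, 1080.0, 1800.0]) * MINUTE


def series(phi_fn, dt=60.0):
    t = np.arange(0.0, BP[-1] + dt / 2, dt)
    t = np.unique(np.concatenate([t, BP]))
    return PhiSeries(t=t, phi=phi_fn(t), breakpoints=BP)


def step_series(levels, dt=60.0):
    """Piecewise-constant Phi taking levels[i] on window i."""
    def fn(t):
        idx = np.clip(np.searchsorted(BP, t, side="right") - 1, 0, 3)
        return np.asarray(levels, dtype=float)[idx]
    return series(fn, dt)


class TestRealAreas:
    def test_constant_negative_window1(self):
        phi = step_series([-1.0, -1.0, 1.0, 1.0])
        R = real_areas(phi)
        assert R[0] == pytest.approx(-180.0, rel=1e-12)

    def test_theta1_kills_positive(self):
        phi = step_series([1.0, -1.0, 1.0, 1.0])
        R = real_areas(phi)
        # the gate keeps only Phi < 0; the two breakpoint-adjacent samples
        # of the +1 plateau contribute nothing
        assert R[0] == pytest.approx(0.0, abs=1.0)

    def test_half_and_half_memory_window(self):
        # -1 on the first half of [t1, t2], +0.5 on the second half
        mid = 0.5 * (BP[1] + BP[2])

        def fn(t):
            out = np.where(t < mid, -1.0, 0.5)
            out[t < BP[1]] = -1.0
            out[t >= BP[2]] = 0.5
            return out

        phi = series(fn, dt=6.0)
        R = real_areas(phi)
        # oracle: fine-grid Riemann sum
        tt = np.linspace(BP[1], BP[2], 200001)
        riemann = np.trapezoid(np.where(tt < mid, -1.0, 0.5), tt) / 60.0
        assert riemann == pytest.approx(-180.0, rel=1e-3)
        assert R[1] == pytest.approx(riemann, abs=0.2)

    def test_not_covering_breakpoints_raises(self):
        t = np.linspace(0, BP[2], 100)
        phi = PhiSeries(t=t, phi=np.zeros_like(t), breakpoints=BP)
        with pytest.raises(ValueError):
            real_areas(phi)


class TestPerfectAreas:
    def test_unit_rectangles(self):
        phi = ideal_signal(-1.0, 1.0, BP)
        assert perfect_areas(phi) == pytest.approx((-180, -720, 180, 720))

    def test_ideal_real_equals_perfect(self):
        phi = ideal_signal(-1.0, 1.0, BP, dt=6.0)
        R, P = real_areas(phi), perfect_areas(phi)
        for r, p in zip(R, P):
            assert r == pytest.approx(p, rel=1e-3)

    def test_asymmetric_extrema_sides(self):
        phi = ideal_signal(-2.0, 1.0, BP)
        P = perfect_areas(phi)
        assert P[0] == pytest.approx(-360.0)
        assert P[2] == pytest.approx(180.0)


class TestThetaS:
    @pytest.mark.parametrize("lam", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_ideal_signal_perfect_quality(self, lam):
        phi = ideal_signal(-1.0, 1.0, BP, dt=6.0)
        assert theta_S(phi, lam).theta_S == pytest.approx(1.0, abs=1e-3)

    def test_zero_rule_no_negative_first_half(self):
        phi = step_series([0.5, 0.5, 1.0, -1.0])
        s = theta_S(phi, 0.4)
        assert s.zero_ruled and s.theta_S == 0.0

    def test_zero_rule_no_positive_second_half(self):
        phi = step_series([-1.0, -1.0, -0.5, -0.5])
        s = theta_S(phi, 0.4)
        assert s.zero_ruled and s.theta_S == 0.0

    def test_flat_zero_signal_scores_zero(self):
        phi = series(lambda t: np.zeros_like(t))
        assert theta_S(phi, 0.5).theta_S == 0.0

    def test_perfect_writes_dead_memory(self):
        # ideal during activation windows, ~0 during both holds
        eps = 1e-9

        def fn(t):
            out = np.full_like(t, eps)
            out[(t >= BP[0]) & (t <= BP[1])] = -1.0
            out[(t > BP[1]) & (t < BP[2])] = -eps
            out[(t >= BP[2]) & (t <= BP[3])] = 1.0
            return out

        s = theta_S(series(fn, dt=6.0), 0.4)
        assert s.S_r == pytest.approx(1.0, abs=2e-3)
        assert s.S_m == pytest.approx(0.0, abs=2e-3)
        assert s.theta_S == pytest.approx(0.4, abs=2e-3)

    def test_lambda_out_of_range(self):
        phi = ideal_signal(-1.0, 1.0, BP)
        with pytest.raises(ValueError):
            theta_S(phi, 1.5)

    def test_exponential_decay_analytic(self):
        # hold windows relax exponentially; S_m has a closed form
        r = np.log(2) / (6 * 3600.0)
        phi = ideal_signal(-1.0, 1.0, BP, dt=6.0, relax_rate=r)
        s = theta_S(phi, 0.4)
        sm_expected = 0.0
        for lo, hi in ((BP[1], BP[2]), (BP[3], BP[4])):
            d = hi - lo
            sm_expected += 0.5 * (1 - np.exp(-r * d)) / (r * d)
        assert s.S_m == pytest.approx(sm_expected, rel=1e-4)
        assert s.S_r == pytest.approx(1.0, abs=1e-3)

    def test_instant_relaxation_kills_memory(self):
        phi = ideal_signal(-1.0, 1.0, BP, dt=6.0, relax_rate=1.0)
        s = theta_S(phi, 0.4)
        assert s.S_m == pytest.approx(0.0, abs=1e-3)

    def test_flip_delay_reduces_response(self):
        fast = theta_S(ideal_signal(-1.0, 1.0, BP, dt=6.0), 1.0)
        slow = theta_S(
            ideal_signal(-1.0, 1.0, BP, dt=6.0, flip_delay=90 * MINUTE), 1.0
        )
        assert slow.S_r < fast.S_r
        assert slow.S_r == pytest.approx(0.5, abs=0.01)

    def test_wrong_sign_memory_subtracts(self):
        # flipping the sign of Phi in one hold window strictly lowers S_m
        good = step_series([-1.0, -1.0, 1.0, 1.0], dt=6.0)
        flipped = step_series([-1.0, 1.0, 1.0, 1.0], dt=6.0)
        s_good, s_flip = theta_S(good, 0.0), theta_S(flipped, 0.0)
        assert s_flip.S_m < s_good.S_m
        # R2 = +720 against P2 = -720: ratio -1, clamped to 0
        assert s_flip.S_m == pytest.approx(0.5 * (0.0 + 1.0), abs=2e-3)


class TestThetaSProperties:
    @given(
        st.floats(0.1, 5.0),
        st.floats(0.1, 5.0),
        st.floats(1e-9, 0.9),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_in_lambda(self, depth, height, frac):
        phi = ideal_signal(
            -depth, height, BP, relax_rate=frac / (3600 * 4)
        )
        scores = {
            lam: theta_S(phi, lam).theta_S
            for lam in (0.0, 0.25, 0.5, 0.75, 1.0)
        }
        s0, s1 = scores[0.0], scores[1.0]
        for lam in (0.25, 0.5, 0.75):
            assert scores[lam] == pytest.approx(
                lam * s1 + (1 - lam) * s0, abs=1e-12
            )

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        phi = ideal_signal(-1.0, 0.7, BP, relax_rate=1e-5)
        scaled = PhiSeries(t=phi.t, phi=c * phi.phi, breakpoints=BP)
        s1, s2 = theta_S(phi, 0.4), theta_S(scaled, 0.4)
        assert s2.S_r == pytest.approx(s1.S_r, rel=1e-12)
        assert s2.S_m == pytest.approx(s1.S_m, rel=1e-12)
        assert s2.theta_S == pytest.approx(s1.theta_S, rel=1e-12)

    def test_quadrature_matches_analytic_on_fixtures(self):
        # trapezoid on a 1-min grid vs analytic integrals
        r = 1e-4
        phi = ideal_signal(-1.0, 1.0, BP, dt=60.0, relax_rate=r)
        R = real_areas(phi)
        d2 = BP[2] - BP[1]
        analytic_R2 = -(1 - np.exp(-r * d2)) / r / 60.0
        assert R[1] == pytest.approx(analytic_R2, rel=1e-5)


class TestThetaA:
    def _score(self, m=-1.0, M=1.0):
        return theta_S(ideal_signal(m, M, BP), 0.4)

    def test_normalization_fixed_point(self):
        s = self._score()
        assert theta_A(s, s.m, s.M) == pytest.approx(s.theta_S)

    def test_zero_amplitude_zero(self):
        phi = step_series([0.0, 0.0, 1.0, 1.0])
        s = theta_S(phi, 0.4)  # m = 0 -> zero-ruled
        assert theta_A(s, -1.0, 1.0) == 0.0

    def test_half_amplitude_quarter_ratio(self):
        s = self._score(-0.5, 0.5)
        got = theta_A(s, -1.0, 1.0)
        assert got == pytest.approx(0.25 * s.theta_S)

    def test_zero_normalizer_rejected(self):
        with pytest.raises(ValueError):
            theta_A(self._score(), 0.0, 1.0)

    def test_bounded_by_theta_S(self):
        s = self._score(-0.3, 0.8)
        assert 0.0 <= theta_A(s, -1.0, 1.0) <= s.theta_S
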