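"""Exact piecewise-linear moment and b-value algebra."""

import numpy as np
import pytest
from scipy.integrate import quad

import diffenc as de
from diffenc.waveform import GAMMA, MS, MT_PER_M, physical_waveform

from conftest import random_spinecho_scheme


def rect_waveform(G, tau):
    """Single ideal rectangle on [0, tau]."""
    return de.EffectiveWaveform(
        np.array([0.0, 0.0, tau, tau]), np.array([0.0, G, G, 0.0])
    )


class TestMoments:
    def test_single_rectangle_closed_forms(self):
        """γGτ, γGτ²/2, γGτ³/3 for a 10 mT/m, 10 ms rectangle."""
        G, tau = 10 * MT_PER_M, 10 * MS
        m = de.moments(rect_waveform(G, tau))
        assert m.M0 == pytest.approx(26.78, rel=1e-12)
        assert m.M1 == pytest.approx(0.1339, rel=1e-12)
        assert m.M2 == pytest.approx(8.9267e-4, rel=1e-4)
        assert m.M2 == pytest.approx(GAMMA * G * tau**3 / 3, rel=1e-12)

    def test_quadrature_oracle_on_random_schemes(self):
        """Closed-form moments match adaptive quadrature to <= 1e-8 relative."""
        rng = np.random.default_rng(2024)
        for _ in range(10):
            scheme = random_spinecho_scheme(rng)
            w = de.effective_waveform(scheme)
            m = de.moments(w)
            bp = np.unique(w.times)

            def g(t):
                return np.interp(t, w.times, w.values)

            for n, val in enumerate([m.M0, m.M1, m.M2]):
                ref, _ = quad(
                    lambda t: g(t) * t**n, 0, w.times[-1],
                    points=bp, limit=200,
                )
                ref *= GAMMA
                scale = max(abs(ref), GAMMA * 1e-6 * (56e-3) ** (n + 1))
                assert abs(val - ref) <= 1e-8 * scale

    def test_moments_linear_b_quadratic_in_amplitude(self, mono800):
        m1 = de.scheme_moments(mono800)
        doubled = mono800.with_amplitude_factor(2.0)
        m2 = de.scheme_moments(doubled)
        assert m2.M1 == pytest.approx(2 * m1.M1, rel=1e-12)
        assert m2.M2 == pytest.approx(2 * m1.M2, rel=1e-12)
        assert m2.b == pytest.approx(4 * m1.b, rel=1e-12)

    def test_origin_shift_rules(self, mono800, accel_pair):
        """M1 is origin-invariant when M0 = 0; M2 picks up 2·Δt·M1."""
        for scheme in (mono800, accel_pair[0]):
            w = de.effective_waveform(scheme)
            m = de.moments(w)
            dt = 7.3e-3
            ms = de.moments(w.shifted(dt))
            assert abs(m.M0) < 1e-9
            assert ms.M1 == pytest.approx(m.M1, abs=1e-9)
            assert ms.M2 - m.M2 == pytest.approx(2 * dt * m.M1, abs=1e-12)

    def test_odd_symmetric_waveform_m2_is_duration_times_m1(self, accel_pair):
        """For the odd-symmetric shifted family, M2 = 2τ·M1 exactly."""
        _, timings = accel_pair
        for t_s in (0.3, 0.8, 1.4):
            scheme = de.apply_timing_shift(timings, t_s, target_b=800.0)
            m = de.scheme_moments(scheme)
            total = 2 * timings.side * MS + timings.c * MS
            assert m.M2 == pytest.approx(total * m.M1, rel=1e-9)


class TestEffectiveWaveform:
    def test_no_pre_pulses_is_identity(self):
        p = de.TrapezoidPulse(10e-3, 5e-3, 1e-3, 20 * MT_PER_M)
        scheme = de.EncodingScheme((p,), refocus_time=5e-3, total_duration=20e-3)
        w = de.effective_waveform(scheme)
        assert w.values.max() == pytest.approx(20 * MT_PER_M)
        assert w.values.min() == 0.0

    def test_monopolar_flip_balances_m0(self, mono800):
        w = de.effective_waveform(mono800)
        plateau_pre = np.interp(11.5 * MS, w.times, w.values)
        plateau_post = np.interp(44.5 * MS, w.times, w.values)
        assert plateau_pre < 0 < plateau_post
        assert abs(de.moments(w).M0) < 1e-9

    def test_velocity_scheme_effective_sign_pattern(self, vel800):
        """Effective pattern (+, − | pause | −, +) after the pre-180 flip."""
        w = de.effective_waveform(vel800)
        probes_ms = [5.75, 17.25, 38.75, 50.25]
        signs = [np.sign(np.interp(t * MS, w.times, w.values)) for t in probes_ms]
        assert signs == [1, -1, -1, 1]

    def test_straddling_pulse_rejected(self):
        p = de.TrapezoidPulse(25e-3, 6e-3, 1e-3, 20 * MT_PER_M)
        with pytest.raises(de.InvalidSchemeError, match="straddles"):
            de.EncodingScheme((p,), refocus_time=28e-3, total_duration=56e-3)

    def test_overlapping_pulses_rejected(self):
        p1 = de.TrapezoidPulse(0.0, 10e-3, 1e-3, 20 * MT_PER_M)
        p2 = de.TrapezoidPulse(5e-3, 10e-3, 1e-3, 20 * MT_PER_M)
        with pytest.raises(de.InvalidSchemeError, match="overlap"):
            de.EncodingScheme((p1, p2), refocus_time=28e-3, total_duration=56e-3)

    def test_short_trapezoid_rejected(self):
        with pytest.raises(de.InvalidSchemeError):
            de.TrapezoidPulse(0.0, 1e-3, 0.8e-3, 20 * MT_PER_M)


class TestBValue:
    def test_stejskal_tanner_rectangular_pair(self):
        """b = q²(Δ − δ/3) for an ideal rectangle pair."""
        delta, Delta, G = 23 * MS, 33 * MS, 30 * MT_PER_M
        pulses = (
            de.TrapezoidPulse(0.0, delta, 0.0, G),
            de.TrapezoidPulse(Delta, delta, 0.0, G),
        )
        scheme = de.EncodingScheme(pulses, refocus_time=28e-3, total_duration=56e-3)
        b = de.bvalue(de.effective_waveform(scheme))
        q = GAMMA * G * delta
        assert b == pytest.approx(q**2 * (Delta - delta / 3), rel=1e-12)

    def test_zero_waveform_has_zero_b(self):
        w = de.EffectiveWaveform(np.array([0.0, 56e-3]), np.zeros(2))
        assert de.bvalue(w) == 0.0

    def test_unbalanced_waveform_warns(self):
        w = rect_waveform(10 * MT_PER_M, 10 * MS)
        with pytest.warns(UserWarning, match="nonzero zeroth moment"):
            b = de.bvalue(w)
        assert b > 0


class TestScaleToB:
    def test_already_at_target_is_unchanged(self, mono800):
        rescaled = de.scale_to_b(mono800, 800.0)
        for p, q in zip(mono800.pulses, rescaled.pulses):
            assert q.amplitude == pytest.approx(p.amplitude, rel=1e-12)

    def test_reaches_target_exactly(self, mono800):
        for target in (50.0, 800.0, 1234.5):
            b = de.scheme_moments(de.scale_to_b(mono800, target)).b
            assert b == pytest.approx(target, rel=1e-10)

    def test_moment_quarter_rule_between_bvalues(self, mono800, mono50):
        """Scaling b = 800 → 50 divides the moments by √16 = 4."""
        m800, m50 = de.scheme_moments(mono800), de.scheme_moments(mono50)
        assert m800.M1 / m50.M1 == pytest.approx(4.0, rel=1e-10)
        assert m800.M2 / m50.M2 == pytest.approx(4.0, rel=1e-10)

    def test_zero_b_scheme_rejected(self):
        scheme = de.EncodingScheme((), refocus_time=28e-3, total_duration=56e-3)
        with pytest.raises(de.InvalidSchemeError, match="zero b-value"):
            de.scale_to_b(scheme, 800.0)


class TestConcomitantBalance:
    def test_one_sided_lobe_imbalance_is_its_g2_integral(self):
        dur, ramp, G = 10e-3, 1.3e-3, 25 * MT_PER_M
        p = de.TrapezoidPulse(0.0, dur, ramp, G)
        scheme = de.EncodingScheme((p,), refocus_time=28e-3, total_duration=56e-3)
        expected = G**2 * (dur - 4 * ramp / 3)
        assert de.concomitant_balance(scheme) == pytest.approx(expected, rel=1e-12)

    def test_polarity_blind(self, mono800):
        """Flipping one side's polarity cannot unbalance ∫G² dt."""
        pulses = list(mono800.pulses)
        pulses[0] = de.TrapezoidPulse(
            pulses[0].start, pulses[0].duration, pulses[0].ramp, -pulses[0].amplitude
        )
        mirrored = de.EncodingScheme(
            tuple(pulses), mono800.refocus_time, mono800.total_duration
        )
        assert abs(de.concomitant_balance(mirrored)) < 1e-18

    def test_all_five_schemes_balanced(self, five_schemes):
        for name, scheme in five_schemes.items():
            scale = sum(
                p.amplitude**2 * p.duration for p in scheme.pulses
            )
            assert abs(de.concomitant_balance(scheme)) <= 1e-12 * scale, name


class TestPhysicalWaveform:
    def test_monopolar_physical_same_polarity(self, mono800):
        w = physical_waveform(mono800)
        assert np.interp(11.5 * MS, w.times, w.values) > 0
        assert np.interp(44.5 * MS, w.times, w.values) > 0
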