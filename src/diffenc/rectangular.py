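"""Closed-form rectangular-pulse expressions for the shifted-timing family.

For ideal rectangular pulses (zero ramp time) the moments of the
acceleration-compensated pattern — effective polarity (+a, −b | pause c |
+b, −a) with per-side durations a (short) and b (long) — reduce to simple
polynomials in the timings.  With γG the gamma-scaled amplitude:

    M1 = γG · [(a+b+c)(b−a) − 2ab]
    M2 = γG · [−2a³ + 2b³ − 6a²b − 3a²c + 3b²c − 2ab² − ac² + bc² − 2abc]
       = (2a + 2b + c) · M1                     (odd-symmetry identity)
    b_diff = (γG)² · D/3,
    D = 2a³ + 3a²(2b+c) − 6ab(b+c) + b²(2b+3c)

Applying the timing shift a → a + t_S, b → b − t_S gives first-order
coefficients dM1/dt_S = −2γG(2b+c) and dM2/dt_S = (2a+2b+c)·dM1/dt_S at
the M1 = 0 solution.  These expressions serve as independent oracles for
the numeric piecewise-linear engine: they must agree with it exactly in
the zero-ramp limit and approximately (ramp corrections of a few percent)
at the realistic 1.3 ms ramps.

Timings are in ms throughout this module (matching the interface units);
moment outputs are SI (s/mm, s²/mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveform import MS, MomentSet, scheme_moments
from .schemes import AccelTimings, apply_timing_shift, compensation_spec


@dataclass(frozen=True)
class RectTimings:
    """Rectangular-pulse timings (ms) and target diffusion weighting.

    ``a``/``b`` are the short/long per-side pulse durations, ``c`` the
    pause; ``b_diff`` is the b-value (s/mm²) fixing the amplitude.
    """

    a: float
    b: float
    c: float
    b_diff: float = 800.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("timings must be positive")
        if self.b_diff <= 0:
            raise ValueError("b_diff must be positive")


def m1_rect_expr(a: float, b: float, c: float) -> float:
    """Rectangular M1 up to the γG prefactor: (a+b+c)(b−a) − 2ab."""
    return (a + b + c) * (b - a) - 2 * a * b


def m2_rect_poly(a, b, c):
    """Rectangular M2 polynomial up to the γG prefactor.

    Factors exactly as (2a+2b+c)·m1_rect_expr(a,b,c): the second moment of
    an odd-symmetric refocused waveform is its total duration times the
    first moment (time origin at the waveform start).
    """
    return (
        -2 * a**3
        + 2 * b**3
        - 6 * a**2 * b
        - 3 * a**2 * c
        + 3 * b**2 * c
        - 2 * a * b**2
        - a * c**2
        + b * c**2
        - 2 * a * b * c
    )


def bvalue_denominator(a: float, b: float, c: float) -> float:
    """D = 2a³ + 3a²(2b+c) − 6ab(b+c) + b²(2b+3c), with b_diff = (γG)²·D/3."""
    return (
        2 * a**3
        + 3 * a**2 * (2 * b + c)
        - 6 * a * b * (b + c)
        + b**2 * (2 * b + 3 * c)
    )


def solve_rect_short_duration(side: float = 23.0, pause: float = 10.0) -> tuple[float, float]:
    """Exact rectangular acceleration-compensated solution (a, b), ms.

    M1 = 0 requires (a+b+c)(b−a) = 2ab with a + b = side, a quadratic in
    d = b − a:  d² + 2(side+pause)·d − side² = 0.
    """
    d = -(side + pause) + np.sqrt((side + pause) ** 2 + side**2)
    return (side - d) / 2, (side + d) / 2


def _gamma_g(t: RectTimings, t_s: float = 0.0) -> float:
    """γG (rad/s per mm) fixed by the b-value, SI, at shift ``t_s``."""
    D = bvalue_denominator(*((t.a + t_s) * MS, (t.b - t_s) * MS, t.c * MS))
    return np.sqrt(3 * t.b_diff / D)


def rect_moments(t: RectTimings, t_s: float = 0.0) -> MomentSet:
    """Closed-form moments of the (shifted) rectangular scheme, SI units.

    The amplitude is re-solved at each shift so the scheme stays at
    ``t.b_diff``, matching the numeric builders' convention.
    """
    a, b, c = (t.a + t_s) * MS, (t.b - t_s) * MS, t.c * MS
    gg = _gamma_g(t, t_s)
    m1 = gg * m1_rect_expr(a, b, c)
    m2 = gg * m2_rect_poly(a, b, c)
    return MomentSet(M0=0.0, M1=m1, M2=m2, b=t.b_diff)


def linear_coefficients(t: RectTimings) -> tuple[float, float]:
    """First-order coefficients (dM1/dt_S, dM2/dt_S) at t_S = 0, per ms.

    Valid at the acceleration-compensated solution (M1 = 0), where the
    amplitude re-solving contributes nothing at first order:
    |dM1/dt_S| = 2γG(2b+c) and dM2/dt_S = (2a+2b+c)·dM1/dt_S — the ratio
    of the two coefficients is the total encoding duration.
    Returned in (s/mm)/ms and (s²/mm)/ms.
    """
    a, b, c = t.a * MS, t.b * MS, t.c * MS
    gg = _gamma_g(t)
    dm1 = -2 * gg * (2 * b + c) * MS
    dm2 = (2 * a + 2 * b + c) * dm1
    return dm1, dm2


def rect_monopolar_m1_max(t: RectTimings) -> float:
    """|M1| of the rectangular monopolar reference (same δ = a+b, pause c).

    Stejskal–Tanner rectangles: q = √(b_diff/(Δ − δ/3)), |M1| = q·Δ with
    Δ = δ + c.  SI units (s/mm).
    """
    delta = (t.a + t.b) * MS
    Delta = delta + t.c * MS
    q = np.sqrt(t.b_diff / (Delta - delta / 3))
    return q * Delta


def relative_coefficient_rect(t: RectTimings) -> float:
    """Closed-form d(|M1|/M1max)/dt_S at t_S = 0 for rectangles, 1/ms."""
    dm1, _ = linear_coefficients(t)
    return abs(dm1) / rect_monopolar_m1_max(t)


def relative_coefficient_trapezoid(
    timings: AccelTimings,
    target_b: float = 800.0,
    step_ms: float = 0.01,
) -> float:
    """Measured d(|M1|/M1max)/dt_S at t_S = 0 on the trapezoid scheme, 1/ms.

    Central finite difference of the *signed* M1 fraction (|M1| itself has
    a kink at the compensated point).  Independent of the b-value, since
    both M1 and M1max scale with the amplitude.
    """

    def signed_fraction(t_s: float) -> float:
        scheme = apply_timing_shift(timings, t_s, target_b=target_b)
        shifted = AccelTimings(
            a=timings.a, b=timings.b, c=timings.c, ramp=timings.ramp, t_s=t_s
        )
        spec = compensation_spec(scheme, shifted)
        sign = np.sign(scheme_moments(scheme).M1)
        return sign * spec.residual_fraction_m1

    return abs(
        (signed_fraction(step_ms) - signed_fraction(-step_ms)) / (2 * step_ms)
    )
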