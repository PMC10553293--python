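"""Builders for the five spin-echo diffusion encodings and the t_S tuner.

All five schemes share the same envelope — 23 ms of gradient before the
180° pulse, a 10 ms pause, 23 ms after — so they can be played at one echo
time.  They differ only in how the windows are partitioned into lobes:

* monopolar: one lobe per side, same polarity (maximal M1, M2);
* velocity-compensated: four equal lobes with effective sign pattern
  (+, − | pause | −, +), which nulls M1 for any pause length;
* acceleration-compensated: per side a short lobe of duration ``a`` and a
  long one of duration ``b`` with opposite polarity, effective pattern
  (+a, −b | pause | +b, −a); ``a`` is root-found so M1 = 0, and the odd
  symmetry of the pattern then forces M2 = 0 as well;
* partially compensated: the acceleration-compensated timings with the
  short lobes lengthened by a shift t_S and the long ones shortened by the
  same amount.  Both residual moments grow by the same relative amount,
  ≈ 0.348·t_S/ms of their monopolar maxima at these timings, so one scalar
  tunes the compensation level continuously.

Builder arguments are in the conventional ms / s/mm² units; returned
schemes are SI (s, T/mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .waveform import (
    MS,
    MT_PER_M,
    EncodingScheme,
    InvalidSchemeError,
    TrapezoidPulse,
    scale_to_b,
    scheme_moments,
)

#: Default amplitude (T/mm) used before rescaling to the target b-value.
_SEED_AMPLITUDE = 10.0 * MT_PER_M

#: Advertised per-ms tuning coefficient of the residual moment fractions,
#: |M1|/M1max ≈ |M2|/M2max ≈ NOMINAL_TUNING_PER_MS · t_S, at the default
#: 23/10/23 ms trapezoid timings.  Used only for human-facing labels; all
#: computed fractions come from the exact waveform moments.
NOMINAL_TUNING_PER_MS = 0.348

#: Timing windows of the fixed 56 ms encoding envelope, ms.
DEFAULT_PRE_MS = 23.0
DEFAULT_PAUSE_MS = 10.0
DEFAULT_POST_MS = 23.0
DEFAULT_RAMP_MS = 1.3
DEFAULT_B = 800.0


@dataclass(frozen=True)
class AccelTimings:
    """Per-side lobe durations of the acceleration-compensated family (ms).

    ``a`` is the short (outermost) lobe, ``b`` the long (innermost) lobe,
    ``c`` the pause between the two sides; ``t_s`` is the applied shift.
    """

    a: float
    b: float
    c: float
    ramp: float = DEFAULT_RAMP_MS
    t_s: float = 0.0

    def __post_init__(self) -> None:
        if self.a + self.t_s < 2 * self.ramp - 1e-12:
            raise InvalidSchemeError("short pulse too short for its ramps")
        if self.b - self.t_s < 2 * self.ramp - 1e-12:
            raise InvalidSchemeError("long pulse too short for its ramps")
        if self.c <= 0:
            raise InvalidSchemeError("pause length must be positive")

    @property
    def side(self) -> float:
        """Per-side encoding duration a + b, ms (invariant under t_s)."""
        return self.a + self.b

    @property
    def total(self) -> float:
        """Total encoding duration 2a + 2b + c, ms."""
        return 2 * self.side + self.c


@dataclass(frozen=True)
class CompensationSpec:
    """Residual moment fractions of a scheme against its monopolar reference.

    The reference is the monopolar scheme with the same per-side pulse
    length, pause length and b-value; M1max/M2max are its moment magnitudes.
    """

    t_s: float
    residual_fraction_m1: float
    residual_fraction_m2: float
    m1_max: float
    m2_max: float

    @property
    def compensation_level(self) -> float:
        """1 − residual fraction: the percent label of the family (0.84, …)."""
        return 1.0 - self.residual_fraction_m1


def _scheme(pulses, refocus_ms: float, total_ms: float, label: str) -> EncodingScheme:
    return EncodingScheme(
        pulses=tuple(pulses),
        refocus_time=refocus_ms * MS,
        total_duration=total_ms * MS,
        label=label,
    )


def build_monopolar(
    pre: float = DEFAULT_PRE_MS,
    pause: float = DEFAULT_PAUSE_MS,
    post: float = DEFAULT_POST_MS,
    ramp: float = DEFAULT_RAMP_MS,
    target_b: float = DEFAULT_B,
) -> EncodingScheme:
    """Monopolar encoding: one same-polarity trapezoid filling each window."""
    if pre != post:
        raise InvalidSchemeError("monopolar scheme requires pre == post")
    if pre < 2 * ramp:
        raise InvalidSchemeError("window shorter than two ramp times")
    pulses = [
        TrapezoidPulse(0.0, pre * MS, ramp * MS, _SEED_AMPLITUDE),
        TrapezoidPulse((pre + pause) * MS, post * MS, ramp * MS, _SEED_AMPLITUDE),
    ]
    scheme = _scheme(pulses, pre + pause / 2, pre + pause + post, "monopolar")
    return scale_to_b(scheme, target_b)


def build_velocity_compensated(
    pulse: float = 11.5,
    ramp: float = DEFAULT_RAMP_MS,
    pause: float = DEFAULT_PAUSE_MS,
    target_b: float = DEFAULT_B,
) -> EncodingScheme:
    """Velocity-compensated encoding from the sign-pattern concatenation rule.

    Concatenating G_pulse, −G_pulse, (pause), −G_pulse, G_pulse as the
    *effective* waveform yields M1 = 0 for any pause length; the physical
    waveform has the pre-180° half flipped, i.e. (−, + | pause | −, +).
    """
    if pulse < 2 * ramp:
        raise InvalidSchemeError("pulse shorter than two ramp times")
    A = _SEED_AMPLITUDE
    p, r = pulse * MS, ramp * MS
    pulses = [
        TrapezoidPulse(0.0, p, r, -A),
        TrapezoidPulse(p, p, r, +A),
        TrapezoidPulse(2 * p + pause * MS, p, r, -A),
        TrapezoidPulse(3 * p + pause * MS, p, r, +A),
    ]
    scheme = _scheme(
        pulses, 2 * pulse + pause / 2, 4 * pulse + pause, "velocity-compensated"
    )
    return scale_to_b(scheme, target_b)


def _accel_scheme_from_timings(
    t: AccelTimings, amplitude: float = _SEED_AMPLITUDE
) -> EncodingScheme:
    """Physical four-lobe scheme for timings ``t`` (shift already applied).

    Effective polarity pattern (+a, −b | pause | +b, −a); the physical
    pre-180° half is flipped, so the played pattern is (−a, +b | +b, −a).
    """
    a = (t.a + t.t_s) * MS
    b = (t.b - t.t_s) * MS
    c = t.c * MS
    r = t.ramp * MS
    side = a + b
    A = amplitude
    pulses = [
        TrapezoidPulse(0.0, a, r, -A),
        TrapezoidPulse(a, b, r, +A),
        TrapezoidPulse(side + c, b, r, +A),
        TrapezoidPulse(side + c + b, a, r, -A),
    ]
    label = (
        "acceleration-compensated"
        if t.t_s == 0
        else f"shifted (t_S = {t.t_s:g} ms)"
    )
    return _scheme(pulses, t.side + t.c / 2, 2 * t.side + t.c, label)


def build_acceleration_compensated(
    side: float = DEFAULT_PRE_MS,
    pause: float = DEFAULT_PAUSE_MS,
    ramp: float = DEFAULT_RAMP_MS,
    target_b: float = DEFAULT_B,
) -> tuple[EncodingScheme, AccelTimings]:
    """Acceleration-compensated encoding: root-found short-lobe duration.

    Solves for the short-lobe duration ``a`` (with a + b = side) such that
    the effective waveform's first moment vanishes; M2 = 0 then follows
    from the odd symmetry of the (+a, −b | +b, −a) pattern.  Returns the
    scaled scheme together with the solved timings.
    """
    if side <= 4 * ramp:
        raise InvalidSchemeError("side must exceed four ramp times")

    def m1_of(a: float) -> float:
        t = AccelTimings(a=a, b=side - a, c=pause, ramp=ramp)
        return scheme_moments(_accel_scheme_from_timings(t)).M1

    lo, hi = 2 * ramp + 1e-9, side / 2 - 1e-9
    f_lo, f_hi = m1_of(lo), m1_of(hi)
    if f_lo * f_hi > 0:
        raise InvalidSchemeError(
            "no M1 root for the short-pulse duration in "
            f"({2 * ramp:g}, {side / 2:g}) ms"
        )
    a = brentq(m1_of, lo, hi, xtol=1e-12)
    timings = AccelTimings(a=a, b=side - a, c=pause, ramp=ramp)
    scheme = scale_to_b(_accel_scheme_from_timings(timings), target_b)
    return scheme, timings


def apply_timing_shift(
    timings: AccelTimings, t_s: float, target_b: float = DEFAULT_B
) -> EncodingScheme:
    """Shift lobe durations (a → a + t_S, b → b − t_S) at fixed envelope.

    The pause and the total encoding duration are untouched; the amplitude
    is re-solved so the shifted scheme keeps the target b-value.
    """
    shifted = AccelTimings(
        a=timings.a, b=timings.b, c=timings.c, ramp=timings.ramp, t_s=t_s
    )
    return scale_to_b(_accel_scheme_from_timings(shifted), target_b)


def compensation_spec(
    scheme: EncodingScheme, timings: AccelTimings
) -> CompensationSpec:
    """Residual |M1|/M1max and |M2|/M2max against the monopolar reference.

    The reference monopolar scheme uses the same per-side pulse length and
    pause length and is scaled to the same b-value.
    """
    m = scheme_moments(scheme)
    ref = build_monopolar(
        pre=timings.side,
        pause=timings.c,
        post=timings.side,
        ramp=timings.ramp,
        target_b=m.b,
    )
    mref = scheme_moments(ref)
    return CompensationSpec(
        t_s=timings.t_s,
        residual_fraction_m1=abs(m.M1) / abs(mref.M1),
        residual_fraction_m2=abs(m.M2) / abs(mref.M2),
        m1_max=abs(mref.M1),
        m2_max=abs(mref.M2),
    )


def residual_fraction(
    timings: AccelTimings, t_s: float, target_b: float = DEFAULT_B
) -> CompensationSpec:
    """Compensation spec of the shifted scheme at ``t_s`` (ms)."""
    scheme = apply_timing_shift(timings, t_s, target_b=target_b)
    shifted = AccelTimings(
        a=timings.a, b=timings.b, c=timings.c, ramp=timings.ramp, t_s=t_s
    )
    return compensation_spec(scheme, shifted)


def solve_shift_for_fraction(
    timings: AccelTimings,
    target_fraction: float,
    target_b: float = DEFAULT_B,
) -> tuple[float, float]:
    """Invert the fraction–shift map: find t_S with |M1|/M1max = target.

    Returns ``(t_s, fraction_mismatch)`` where the mismatch is the (small)
    difference between the M1- and M2-based residual fractions at the
    solution — the two coincide only approximately for trapezoidal lobes.
    """
    if target_fraction < 0:
        raise ValueError("target fraction must be non-negative")
    if target_fraction == 0:
        return 0.0, 0.0
    hi = timings.b - 2 * timings.ramp - 1e-9
    f_hi = residual_fraction(timings, hi, target_b).residual_fraction_m1
    if target_fraction > f_hi:
        raise InvalidSchemeError(
            f"fraction {target_fraction:g} unreachable; maximum feasible "
            f"is {f_hi:g} at t_S = {hi:g} ms"
        )

    def objective(t_s: float) -> float:
        return (
            residual_fraction(timings, t_s, target_b).residual_fraction_m1
            - target_fraction
        )

    t_s = brentq(objective, 0.0, hi, xtol=1e-9)
    spec = residual_fraction(timings, t_s, target_b)
    return t_s, spec.residual_fraction_m1 - spec.residual_fraction_m2


def build_all(
    target_b: float = DEFAULT_B,
    shifts_ms: tuple[float, ...] = (0.45, 0.95),
) -> dict[str, EncodingScheme]:
    """The standard scheme family at one b-value.

    Returns monopolar, velocity- and acceleration-compensated schemes plus
    one partially compensated scheme per requested timing shift (labelled
    by its compensation level, e.g. '84%-compensated' for t_S = 0.45 ms).
    """
    schemes: dict[str, EncodingScheme] = {}
    schemes["monopolar"] = build_monopolar(target_b=target_b)
    schemes["velocity-compensated"] = build_velocity_compensated(target_b=target_b)
    accel, timings = build_acceleration_compensated(target_b=target_b)
    schemes["acceleration-compensated"] = accel
    for t_s in shifts_ms:
        scheme = apply_timing_shift(timings, t_s, target_b=target_b)
        # Family labels follow the nominal linear tuning model (84% for
        # t_S = 0.45 ms, 67% for 0.95 ms); exact fractions are reported
        # separately by compensation_spec.
        level = round(100 * (1 - NOMINAL_TUNING_PER_MS * t_s))
        schemes[f"{level:.0f}%-compensated"] = scheme
    return schemes
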