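"""Piecewise-linear gradient waveforms and their exact moment/b-value algebra.

A spin-echo diffusion encoding is a set of trapezoidal gradient lobes placed
around a refocusing (180°) pulse.  For phase calculations the *effective*
waveform is used: every lobe played before the refocusing pulse has its
polarity negated, after which position/velocity/acceleration phase and the
diffusion weighting follow from straight integration.

All integrals here are evaluated in closed form: the effective gradient is
piecewise linear, so G(t)·tⁿ is a piecewise polynomial and q(t) = γ∫G dt is
piecewise quadratic.  Each segment is integrated via exact polynomial
antiderivatives — no numerical quadrature anywhere on the main path.

Internal units are SI-consistent: time in s, gradient in T/mm, so that with
γ in rad/s/T the moments come out as M0 [1/mm], M1 [s/mm], M2 [s²/mm] and
the b-value in s/mm².  Constructors and I/O accept the conventional ms and
mT/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from numpy.polynomial import Polynomial

#: Gyromagnetic ratio of the proton, rad/s/T.
GAMMA = 2.678e8

#: 1 ms in s.
MS = 1e-3
#: 1 mT/m expressed in T/mm.
MT_PER_M = 1e-6


class InvalidSchemeError(ValueError):
    """Raised when pulse timings cannot form a valid spin-echo encoding."""


@dataclass(frozen=True)
class TrapezoidPulse:
    """One trapezoidal gradient lobe.

    Parameters
    ----------
    start : float
        Start time of the ramp-up, s.
    duration : float
        Total lobe duration including both ramps, s.
    ramp : float
        Ramp (rise/fall) time, s.  ``ramp = 0`` gives an ideal rectangle,
        ``duration = 2*ramp`` a triangle.
    amplitude : float
        Signed plateau amplitude, T/mm.
    """

    start: float
    duration: float
    ramp: float
    amplitude: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude):
            raise InvalidSchemeError("pulse amplitude must be finite")
        if self.ramp < 0:
            raise InvalidSchemeError("ramp time must be non-negative")
        if self.duration < 2 * self.ramp:
            raise InvalidSchemeError(
                f"duration {self.duration} shorter than two ramps {2 * self.ramp}"
            )

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def center(self) -> float:
        return self.start + self.duration / 2

    @property
    def area(self) -> float:
        """Signed time integral of the lobe, T·s/mm."""
        return self.amplitude * (self.duration - self.ramp)

    def profile(self) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoint representation (times, values) of the lobe.

        Rectangles are encoded with repeated breakpoints (a jump); the
        segment iterator skips the resulting zero-length pieces.
        """
        if self.ramp == 0:
            t = np.array([self.start, self.start, self.end, self.end])
        else:
            t = np.array(
                [self.start, self.start + self.ramp, self.end - self.ramp, self.end]
            )
        v = np.array([0.0, self.amplitude, self.amplitude, 0.0])
        return t, v


@dataclass(frozen=True)
class EncodingScheme:
    """Ordered gradient lobes on one axis around a refocusing pulse."""

    pulses: tuple[TrapezoidPulse, ...]
    refocus_time: float
    total_duration: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pulses", tuple(self.pulses))
        prev_end = -np.inf
        for p in self.pulses:
            if p.start < prev_end - 1e-12:
                raise InvalidSchemeError("pulses overlap or are out of order")
            prev_end = p.end
            if p.start < self.refocus_time < p.end:
                raise InvalidSchemeError(
                    f"pulse [{p.start}, {p.end}] straddles the refocusing "
                    f"pulse at {self.refocus_time}"
                )
        if self.pulses and self.total_duration < self.pulses[-1].end - 1e-12:
            raise InvalidSchemeError("total_duration ends before the last pulse")

    @property
    def start(self) -> float:
        return self.pulses[0].start if self.pulses else 0.0

    @property
    def pre_pulses(self) -> tuple[TrapezoidPulse, ...]:
        return tuple(p for p in self.pulses if p.end <= self.refocus_time)

    @property
    def post_pulses(self) -> tuple[TrapezoidPulse, ...]:
        return tuple(p for p in self.pulses if p.start >= self.refocus_time)

    def with_amplitude_factor(self, factor: float) -> "EncodingScheme":
        """Scale every lobe amplitude by ``factor`` (polarities preserved)."""
        return replace(
            self,
            pulses=tuple(
                replace(p, amplitude=p.amplitude * factor) for p in self.pulses
            ),
        )


@dataclass(frozen=True)
class EffectiveWaveform:
    """Piecewise-linear effective gradient with a declared time origin.

    ``times`` may contain repeated entries encoding jump discontinuities
    (ideal rectangles).  The first and last value are zero.
    """

    times: np.ndarray
    values: np.ndarray
    origin: str = "encoding_start"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("times/values must be matching 1-D arrays, length >= 2")
        if np.any(np.diff(t) < -1e-15):
            raise ValueError("breakpoint times must be non-decreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def segments(self) -> Iterator[tuple[float, float, float, float]]:
        """Yield (t0, t1, v0, v1) for every finite-length linear segment."""
        for i in range(len(self.times) - 1):
            t0, t1 = self.times[i], self.times[i + 1]
            if t1 > t0:
                yield float(t0), float(t1), float(self.values[i]), float(self.values[i + 1])

    def shifted(self, dt: float) -> "EffectiveWaveform":
        """Translate the time axis by ``dt`` (origin marker becomes custom)."""
        return EffectiveWaveform(self.times + dt, self.values.copy(), origin="custom")

    def sample(self, dwell: float) -> tuple[np.ndarray, np.ndarray]:
        """Sample on a regular grid with spacing ``dwell`` (s)."""
        n = int(round(self.duration / dwell)) + 1
        t = self.times[0] + dwell * np.arange(n)
        # np.interp resolves repeated breakpoints to the right-hand value,
        # which is the convention we want for ideal rectangles.
        return t, np.interp(t, self.times, self.values)


@dataclass(frozen=True)
class MomentSet:
    """Gradient moments and diffusion weighting of one effective waveform."""

    M0: float  # 1/mm
    M1: float  # s/mm
    M2: float  # s^2/mm
    b: float  # s/mm^2
    gamma: float = GAMMA

    def as_dict(self) -> dict[str, float]:
        return {"M0": self.M0, "M1": self.M1, "M2": self.M2, "b": self.b}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def effective_waveform(scheme: EncodingScheme) -> EffectiveWaveform:
    """Effective gradient of a spin-echo scheme: pre-180° lobes sign-flipped.

    The time origin is placed at the start of the first gradient lobe (the
    encoding start), which is the convention under which the scheme's second
    moments are reported.
    """
    if not scheme.pulses:
        return EffectiveWaveform(np.array([0.0, scheme.total_duration]), np.zeros(2))
    t0 = scheme.start
    times = [0.0]
    values = [0.0]
    for p in scheme.pulses:
        sign = -1.0 if p.end <= scheme.refocus_time else 1.0
        pt, pv = p.profile()
        times.extend(pt - t0)
        values.extend(sign * pv)
    end = max(scheme.total_duration - t0, times[-1])
    times.append(end)
    values.append(0.0)
    return EffectiveWaveform(np.array(times), np.array(values))


def physical_waveform(scheme: EncodingScheme) -> EffectiveWaveform:
    """Played (unflipped) gradient of a scheme, origin at the encoding start."""
    if not scheme.pulses:
        return EffectiveWaveform(np.array([0.0, scheme.total_duration]), np.zeros(2))
    t0 = scheme.start
    times = [0.0]
    values = [0.0]
    for p in scheme.pulses:
        pt, pv = p.profile()
        times.extend(pt - t0)
        values.extend(pv)
    end = max(scheme.total_duration - t0, times[-1])
    times.append(end)
    values.append(0.0)
    return EffectiveWaveform(np.array(times), np.array(values))


def moments(w: EffectiveWaveform, gamma: float = GAMMA) -> MomentSet:
    """Closed-form M0, M1, M2 and b-value of a piecewise-linear waveform.

    Mn = γ ∫ G(t)·tⁿ dt and b = ∫ q(t)² dt with q(t) = γ ∫₀ᵗ G dt', each
    segment integrated through exact polynomial antiderivatives.  Segments
    are integrated in local coordinates u = t − t0, which stays accurate
    even for very short ramps where the global-t slope is enormous.
    """
    m = np.zeros(3)
    b = 0.0
    q0 = 0.0
    for t0, t1, v0, v1 in w.segments():
        dt = t1 - t0
        g = Polynomial([v0, (v1 - v0) / dt])  # G(t0 + u)
        t_of_u = Polynomial([t0, 1.0])
        p = g
        for n in range(3):
            anti = p.integ()
            m[n] += anti(dt)
            p = p * t_of_u
        q = g.integ() + q0  # q(t0 + u) in local units
        q2 = (q * q).integ()
        b += q2(dt)
        q0 = q(dt)
    return MomentSet(
        M0=gamma * m[0], M1=gamma * m[1], M2=gamma * m[2], b=gamma**2 * b, gamma=gamma
    )


def bvalue(w: EffectiveWaveform, gamma: float = GAMMA) -> float:
    """Diffusion weighting b = ∫ q² dt of the effective waveform, s/mm².

    Warns (but still returns b) if the zeroth moment does not vanish, since
    a non-refocused waveform forms no echo.
    """
    ms = moments(w, gamma=gamma)
    scale = gamma * np.max(np.abs(w.values)) * w.duration
    if scale > 0 and abs(ms.M0) > 1e-9 * scale:
        warnings.warn(
            f"waveform has nonzero zeroth moment M0 = {ms.M0:.3e} /mm; "
            "no echo forms and the b-value is origin-dependent",
            stacklevel=2,
        )
    return ms.b


def scheme_moments(scheme: EncodingScheme, gamma: float = GAMMA) -> MomentSet:
    """Moments of the scheme's effective waveform (origin: encoding start)."""
    return moments(effective_waveform(scheme), gamma=gamma)


def scale_to_b(scheme: EncodingScheme, target_b: float) -> EncodingScheme:
    """Rescale all lobe amplitudes so the scheme reaches ``target_b`` (s/mm²).

    b is quadratic in a global amplitude factor, so the factor is
    √(target/current) and the moments scale by the same factor.
    """
    if target_b <= 0:
        raise ValueError("target_b must be positive")
    current = scheme_moments(scheme).b
    if current <= 0:
        raise InvalidSchemeError("scheme has zero b-value; cannot scale")
    return scheme.with_amplitude_factor(np.sqrt(target_b / current))


def concomitant_balance(scheme: EncodingScheme) -> float:
    """First-order concomitant (Maxwell) phase imbalance, T²·s/mm².

    Concomitant fields scale with G(t)², whose phase is refocused when
    ∫G² dt matches on both sides of the 180° pulse.  Returns the pre-180°
    integral minus the post-180° integral evaluated on the *physical*
    (unflipped) waveform; zero means balanced.
    """
    pre = 0.0
    post = 0.0
    for p in scheme.pulses:
        pt, pv = p.profile()
        total = 0.0
        for i in range(len(pt) - 1):
            dt = pt[i + 1] - pt[i]
            if dt > 0:
                g = Polynomial([pv[i], (pv[i + 1] - pv[i]) / dt])
                total += (g * g).integ()(dt)
        if p.end <= scheme.refocus_time:
            pre += total
        else:
            post += total
    return pre - post
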