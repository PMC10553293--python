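"""Motion and IVIM signal model: what the encodings do to moving spins.

The mechanisms behind the in-vivo observations are small and analytic:

* a spin with position x0, velocity v and constant acceleration acc
  accrues the phase φ = M0·x0 + M1·v + ½·M2·acc, so nulled moments mean
  nulled motion phase;
* blood flowing ballistically (no direction change during the encoding)
  through randomly oriented vessels dephases as the orientation average of
  cos(M1·v·cosθ), i.e. a sinc in M1·v — attenuation depends on M1, not b;
* liver tissue is modelled as a two-compartment mix of parenchyma and
  perfusing blood; with monopolar encodings the blood compartment is
  dephased away and the two-point ADC is biased low, while
  velocity-compensated encodings retain it and report the perfusion-
  inflated ADC f·D_blood + (1−f)·D_liver.

Diffusivities are in µm²/ms, b-values in s/mm², M1 in s/mm, speeds in
mm/s (so M1·v is in radians with the γ-inclusive moment definitions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gmean

from .waveform import MomentSet

#: 1 µm²/ms expressed in mm²/s units times s/mm² b-values: b·D is
#: dimensionless once D is multiplied by this factor.
_UM2_PER_MS = 1e-3


@dataclass(frozen=True)
class MotionState:
    """Rigid motion of a spin packet: position (mm), velocity (mm/s),
    constant acceleration (mm/s²)."""

    x0: float = 0.0
    v: float = 0.0
    acc: float = 0.0

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.x0, self.v, self.acc])):
            raise ValueError("motion state must be finite")


@dataclass(frozen=True)
class LiverModel:
    """Two-compartment liver: parenchyma plus ballistically flowing blood.

    Parameters
    ----------
    f : float
        Perfusion (blood) signal fraction at the echo time, in [0, 1].
    d_blood, d_liver : float
        Compartment diffusivities, µm²/ms.
    v_blood : float
        Characteristic microvascular blood speed, mm/s.
    """

    f: float = 0.3
    d_blood: float = 1.6
    d_liver: float = 0.95
    v_blood: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.f <= 1:
            raise ValueError("perfusion fraction must lie in [0, 1]")
        if self.d_blood <= 0 or self.d_liver <= 0:
            raise ValueError("diffusivities must be positive")
        if self.v_blood < 0:
            raise ValueError("blood speed must be non-negative")


def phase(m: MomentSet, s: MotionState) -> float:
    """Phase (rad) accrued by a spin in motion state ``s``.

    φ = M0·x0 + M1·v + ½·M2·acc — the Taylor expansion of the spin's
    trajectory against the gradient moments.  M0 vanishes for every valid
    spin-echo scheme but is kept for diagnostic waveforms.
    """
    return m.M0 * s.x0 + m.M1 * s.v + 0.5 * m.M2 * s.acc


def ballistic_attenuation(m1, speed):
    """Attenuation of plug flow at ``speed`` through isotropic vessels.

    The orientation average of cos(M1·v·cosθ) over the sphere is
    sin(M1·v)/(M1·v); returned as its magnitude, in [0, 1], equal to 1 at
    M1·v = 0.  Accepts scalars or arrays.
    """
    m1 = np.asarray(m1, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise ValueError("speed must be non-negative")
    out = np.abs(np.sinc(m1 * speed / np.pi))
    return float(out) if out.ndim == 0 else out


def liver_signal(b, m1, model: LiverModel = LiverModel()):
    """Normalized two-compartment liver signal at weighting ``b`` (s/mm²).

    (1−f)·exp(−b·D_liver) + f·exp(−b·D_blood)·A(M1, v_blood), with A the
    ballistic attenuation factor.  Equals 1 at b = 0, M1 = 0.
    """
    b = np.asarray(b, dtype=float)
    tissue = (1 - model.f) * np.exp(-b * model.d_liver * _UM2_PER_MS)
    blood = (
        model.f
        * np.exp(-b * model.d_blood * _UM2_PER_MS)
        * ballistic_attenuation(m1, model.v_blood)
    )
    out = tissue + blood
    return float(out) if out.ndim == 0 else out


def adc(s_low, s_high, b_low: float = 50.0, b_high: float = 800.0):
    """Two-point apparent diffusion coefficient, µm²/ms.

    ADC = ln(S_low/S_high)/(b_high − b_low); exactly inverts a
    monoexponential decay.  Signals must be positive.
    """
    s_low = np.asarray(s_low, dtype=float)
    s_high = np.asarray(s_high, dtype=float)
    if np.any(s_low <= 0) or np.any(s_high <= 0):
        raise ValueError("ADC undefined for non-positive signals")
    if b_high == b_low:
        raise ValueError("b-values must differ")
    out = np.log(s_low / s_high) / (b_high - b_low) / _UM2_PER_MS
    return float(out) if out.ndim == 0 else out


def mixed_adc_estimate(model: LiverModel = LiverModel()) -> float:
    """Perfusion-inflated ADC estimate f·D_blood + (1−f)·D_liver, µm²/ms.

    First-order prediction of the two-point ADC when the blood compartment
    is *not* attenuated (velocity-compensated case)."""
    return model.f * model.d_blood + (1 - model.f) * model.d_liver


def trace_weighted(signals, repetition_axis: int = -1, direction_axis: int = 0):
    """Trace-weighted combination of per-direction, per-repetition signals.

    Repetitions are averaged arithmetically within each diffusion
    direction, then the direction means are averaged geometrically, which
    removes the directional dependence of anisotropic diffusion.  A
    direction mean of zero yields a zero result (not an error).
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim < 2:
        raise ValueError("need at least (directions, repetitions) axes")
    if np.any(signals < 0):
        raise ValueError("signals must be non-negative")
    rep = repetition_axis % signals.ndim
    direction = direction_axis % signals.ndim
    if rep == direction:
        raise ValueError("repetition and direction axes must differ")
    means = signals.mean(axis=rep)
    if rep < direction:
        direction -= 1
    with np.errstate(divide="ignore"):  # a zero direction-mean maps to 0
        out = gmean(means, axis=direction)
    return float(out) if np.ndim(out) == 0 else out


def roi_normalize(mean_signals, reference: float):
    """Normalize ROI means on a reference (right-lobe monopolar b=50) value."""
    if reference <= 0:
        raise ValueError("reference signal must be positive")
    out = np.asarray(mean_signals, dtype=float) / reference
    return float(out) if out.ndim == 0 else out
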