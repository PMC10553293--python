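"""File formats and run configuration.

Two waveform formats are supported:

* a sampled CSV with header ``# time_ms,gradient_mT_per_m`` holding the
  *effective* gradient at a fixed dwell (default 10 µs) — convenient for
  plotting and for feeding external moment checkers;
* an exact breakpoint JSON
  ``{"breakpoints_ms": [...], "values_mT_per_m": [...], "refocus_ms": x}``
  holding the *physical* waveform together with the refocusing-pulse time,
  from which the effective waveform is reconstructed losslessly.

Scheme descriptors are small JSON/YAML mappings handed to the builders,
e.g. ``{"type": "shifted", "t_shift_ms": 0.45, "b_s_per_mm2": 800}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import schemes as sb
from .waveform import (
    MS,
    MT_PER_M,
    EffectiveWaveform,
    EncodingScheme,
    effective_waveform,
    physical_waveform,
)

CSV_HEADER = "# time_ms,gradient_mT_per_m"

#: Descriptors of the five standard encodings at the published timings.
DEFAULT_SCHEMES = [
    {"type": "monopolar"},
    {"type": "velocity"},
    {"type": "acceleration"},
    {"type": "shifted", "t_shift_ms": 0.45},
    {"type": "shifted", "t_shift_ms": 0.95},
]


class WaveformParseError(ValueError):
    """Malformed waveform file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(message + where)


@dataclass
class RunConfig:
    """Configuration of a CLI run (times in ms, b in s/mm², dwell in µs)."""

    schemes: list[dict] = field(default_factory=lambda: [dict(d) for d in DEFAULT_SCHEMES])
    bvalues: list[float] = field(default_factory=lambda: [50.0, 800.0])
    out_dir: str = "waveforms"
    dwell_us: float = 10.0
    log_level: str = "info"

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.bvalues):
            raise ValueError("b-values must be positive")
        if self.dwell_us <= 0:
            raise ValueError("dwell must be positive")
        for d in self.schemes:
            if d.get("type") not in {"monopolar", "velocity", "acceleration", "shifted"}:
                raise ValueError(f"unknown scheme type in descriptor: {d!r}")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from JSON or YAML (by file extension)."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig(**data)


def build_from_descriptor(
    desc: dict, target_b: float | None = None
) -> tuple[EncodingScheme, sb.AccelTimings | None]:
    """Instantiate a scheme from a descriptor mapping.

    ``target_b`` overrides the descriptor's ``b_s_per_mm2``.  Returns the
    scheme and, for the acceleration-compensated family, its solved
    timings (None otherwise).
    """
    kind = desc["type"]
    b = target_b if target_b is not None else desc.get("b_s_per_mm2", sb.DEFAULT_B)
    pre = desc.get("pre_ms", sb.DEFAULT_PRE_MS)
    pause = desc.get("pause_ms", sb.DEFAULT_PAUSE_MS)
    post = desc.get("post_ms", pre)
    ramp = desc.get("ramp_ms", sb.DEFAULT_RAMP_MS)
    if kind == "monopolar":
        return sb.build_monopolar(pre, pause, post, ramp, target_b=b), None
    if kind == "velocity":
        return sb.build_velocity_compensated(pre / 2, ramp, pause, target_b=b), None
    if kind == "acceleration":
        return sb.build_acceleration_compensated(pre, pause, ramp, target_b=b)
    if kind == "shifted":
        t_s = desc.get("t_shift_ms", 0.0)
        _, timings = sb.build_acceleration_compensated(pre, pause, ramp, target_b=b)
        shifted = sb.AccelTimings(timings.a, timings.b, timings.c, timings.ramp, t_s)
        return sb.apply_timing_shift(timings, t_s, target_b=b), shifted
    raise ValueError(f"unknown scheme type {kind!r}")


def scheme_slug(desc: dict) -> str:
    """Filesystem-friendly name for a descriptor."""
    kind = desc["type"]
    if kind == "shifted":
        return f"shifted_tS{desc.get('t_shift_ms', 0.0):g}ms".replace(".", "p")
    return kind


# ---------------------------------------------------------------------------
# Waveform files
# ---------------------------------------------------------------------------


def write_waveform_csv(
    path: str | Path, w: EffectiveWaveform, dwell_us: float = 10.0
) -> None:
    """Write the waveform sampled at a fixed dwell, in ms / mT/m."""
    t, v = w.sample(dwell_us * 1e-6)
    with open(path, "w") as fh:
        fh.write(CSV_HEADER + "\n")
        for ti, vi in zip(t / MS, v / MT_PER_M):
            fh.write(f"{ti:.6f},{vi:.9f}\n")


def read_waveform_csv(path: str | Path) -> EffectiveWaveform:
    """Read a sampled waveform CSV back as a piecewise-linear waveform."""
    times, values = [], []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise WaveformParseError(
                    f"expected 'time_ms,gradient' pair, got {line!r}", line=i
                )
            try:
                times.append(float(parts[0]) * MS)
                values.append(float(parts[1]) * MT_PER_M)
            except ValueError as exc:
                raise WaveformParseError(str(exc), line=i) from exc
    if len(times) < 2:
        raise WaveformParseError("waveform file holds fewer than two samples")
    return EffectiveWaveform(np.array(times), np.array(values), origin="file_start")


def write_waveform_json(path: str | Path, scheme: EncodingScheme) -> None:
    """Write the exact physical breakpoints plus the refocusing time."""
    w = physical_waveform(scheme)
    payload = {
        "breakpoints_ms": [round(t / MS, 9) for t in w.times],
        "values_mT_per_m": [round(v / MT_PER_M, 9) for v in w.values],
        "refocus_ms": round((scheme.refocus_time - scheme.start) / MS, 9),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_waveform_json(path: str | Path) -> tuple[EffectiveWaveform, float]:
    """Read exact breakpoints; returns (effective waveform, refocus time s).

    The stored physical waveform is converted to the effective one by
    negating all values strictly before the refocusing time.
    """
    with open(path) as fh:
        data = json.load(fh)
    try:
        t = np.asarray(data["breakpoints_ms"], dtype=float) * MS
        v = np.asarray(data["values_mT_per_m"], dtype=float) * MT_PER_M
        refocus = float(data["refocus_ms"]) * MS
    except (KeyError, TypeError) as exc:
        raise WaveformParseError(f"missing or malformed field: {exc}") from exc
    flipped = np.where(t < refocus, -v, v)
    # breakpoints exactly at the refocusing time belong to both halves and
    # carry G = 0 for any valid scheme; leave them unflipped.
    return EffectiveWaveform(t, flipped, origin="file_start"), refocus
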