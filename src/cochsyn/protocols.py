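"""Acoustic stimulus protocols as drive-level envelopes.

Sound pressure is abstracted to a drive level s(t) in [0, 1]: 0 is silence
and 1 the plateau level (30 dB above fiber threshold in the experiments the
protocols mimic).  Tone segments rise over a 4 ms quarter-sin^2 onset ramp;
a symmetric offset ramp is applied by default to avoid discontinuities in
the delayed differential equation (set ``offset_ramp=False`` for an
instantaneous offset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .release_model import Envelope

RAMP_DEFAULT = 4e-3  # s

#: masker-probe gaps used in the forward-masking paradigm (s)
FM_GAPS = (4e-3, 16e-3, 64e-3, 256e-3)
FM_MASKER = 100e-3
FM_PROBE = 15e-3
FM_PERIOD = 0.5  # presented at 2 Hz


def sin2_ramp(duration: float = RAMP_DEFAULT, dt: float = 5e-5) -> np.ndarray:
    """Quarter-period sin^2 onset ramp: s(t) = sin^2(pi t / (2 T)), 0 -> 1."""
    if duration <= 0:
        raise ValueError("ramp duration must be positive")
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    return np.sin(np.pi * t / (2.0 * duration)) ** 2


@dataclass
class Protocol:
    """A periodic stimulus: a list of (kind, duration) segments per cycle.

    ``kind`` is ``"silence"`` or ``"tone"``; durations are in seconds and
    must sum to ``period`` = 1 / presentation rate.
    """

    name: str
    segments: List[Tuple[str, float]]
    period: float
    rate_hz: float
    ramp: float = RAMP_DEFAULT
    offset_ramp: bool = True

    def __post_init__(self) -> None:
        total = sum(d for _, d in self.segments)
        if abs(total - self.period) > 1e-9:
            raise ValueError(
                f"segment durations ({total} s) must sum to the period "
                f"({self.period} s)")
        if abs(self.period * self.rate_hz - 1.0) > 1e-9:
            raise ValueError("period must equal 1 / presentation rate")
        tones = [d for k, d in self.segments if k == "tone"]
        if tones and self.ramp > min(tones) / (2 if self.offset_ramp else 1):
            raise ValueError("ramp does not fit into the shortest tone")

    @property
    def tone_onsets(self) -> List[float]:
        """Start times of the tone segments within the cycle."""
        out, t = [], 0.0
        for kind, dur in self.segments:
            if kind == "tone":
                out.append(t)
            t += dur
        return out

    def envelope(self, dt: float = 5e-5) -> Envelope:
        """Sample the drive level on a uniform grid of step ``dt``."""
        n = int(round(self.period / dt))
        t = np.arange(n + 1) * dt
        s = np.zeros(n + 1)
        t0 = 0.0
        for kind, dur in self.segments:
            if kind == "tone":
                tau = t - t0
                inside = (tau >= 0) & (tau <= dur)
                seg = np.ones(n + 1)
                up = tau < self.ramp
                seg[up] = np.sin(np.pi * tau[up] / (2 * self.ramp)) ** 2
                if self.offset_ramp:
                    down = tau > dur - self.ramp
                    seg[down] = np.sin(
                        np.pi * (dur - tau[down]) / (2 * self.ramp)) ** 2
                s[inside] = seg[inside]
            t0 += dur
        return Envelope(t, np.clip(s, 0.0, 1.0), self.period)


def forward_masking_protocol(gap: float, ramp: float = RAMP_DEFAULT,
                             offset_ramp: bool = True) -> Protocol:
    """100 ms masker + silent gap + 15 ms probe, presented at 2 Hz.

    ``gap`` in seconds; the paradigm uses 4, 16, 64 and 256 ms (other values
    are allowed with a warning).  The trailing silence pads the cycle to
    500 ms.
    """
    if not any(abs(gap - g) < 1e-9 for g in FM_GAPS):
        warnings.warn(f"gap {gap * 1e3:.1f} ms is outside the canonical "
                      "{4, 16, 64, 256} ms set", stacklevel=2)
    trailing = FM_PERIOD - FM_MASKER - gap - FM_PROBE
    if trailing < 0:
        raise ValueError("masker + gap + probe exceed the 500 ms cycle")
    segments = [("tone", FM_MASKER), ("silence", gap), ("tone", FM_PROBE)]
    if trailing > 0:
        segments.append(("silence", trailing))
    return Protocol(name=f"fm_{gap * 1e3:g}ms", segments=segments,
                    period=FM_PERIOD, rate_hz=2.0, ramp=ramp,
                    offset_ramp=offset_ramp)


def tone_burst_protocol(burst_ms: float, rate_hz: float,
                        ramp: float = RAMP_DEFAULT,
                        offset_ramp: bool = True) -> Protocol:
    """Single tone burst per cycle: e.g. 50 ms at 10/5 Hz or 500 ms at 0.5 Hz.

    The inter-stimulus interval is onset-to-onset, so the period is
    1 / ``rate_hz``.
    """
    burst = burst_ms * 1e-3
    period = 1.0 / rate_hz
    if burst >= period:
        raise ValueError("burst must be shorter than the period")
    return Protocol(name=f"tb_{burst_ms:g}ms_{rate_hz:g}Hz",
                    segments=[("tone", burst), ("silence", period - burst)],
                    period=period, rate_hz=rate_hz, ramp=ramp,
                    offset_ramp=offset_ramp)
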