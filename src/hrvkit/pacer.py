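"""Paced-breathing pacer: cycle timing and the rising/falling ball waveform.

Slow paced breathing at 5 or 6 breaths/min drives respiratory sinus
arrhythmia at 0.083-0.1 Hz. The pacer animates a ball that rises during
inhalation and falls during exhalation, with an inspiration-to-expiration
ratio of 0.435 and a 1.5-s pause at end-inspiration and end-expiration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BreathCycle", "breath_cycle", "pacer_waveform"]


@dataclass(frozen=True)
class BreathCycle:
    rate_bpm: float
    ie_ratio: float
    pause_s: float
    cycle_s: float
    inhale_s: float
    exhale_s: float
    pacing_hz: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def breath_cycle(rate_bpm: float = 6.0, ie_ratio: float = 0.435, pause_s: float = 1.5) -> BreathCycle:
    """Breathing-cycle timing for a pacing rate.

    The active (non-pause) part of the cycle is split so that
    ``inhale/exhale == ie_ratio``:

    * inhale = ie/(1+ie) * (cycle - 2*pause)
    * exhale =  1/(1+ie) * (cycle - 2*pause)
    """
    if rate_bpm <= 0 or ie_ratio <= 0 or pause_s < 0:
        raise ValueError("rate_bpm and ie_ratio must be positive, pause_s non-negative")
    cycle_s = 60.0 / rate_bpm
    if 2 * pause_s >= cycle_s:
        raise ValueError(f"pauses ({2 * pause_s} s) exceed the breathing cycle ({cycle_s} s)")
    active = cycle_s - 2 * pause_s
    inhale_s = ie_ratio / (1 + ie_ratio) * active
    exhale_s = active / (1 + ie_ratio)
    return BreathCycle(
        rate_bpm=rate_bpm,
        ie_ratio=ie_ratio,
        pause_s=pause_s,
        cycle_s=cycle_s,
        inhale_s=inhale_s,
        exhale_s=exhale_s,
        pacing_hz=rate_bpm / 60.0,
    )


def pacer_waveform(
    cycle: BreathCycle,
    duration_s: float,
    dt_s: float = 0.02,
    shape: str = "linear",
) -> pd.DataFrame:
    """Ball-height waveform in [0, 1] over ``duration_s``.

    Per cycle: rise 0->1 during inhale, hold 1 for the end-inspiration
    pause, fall 1->0 during exhale, hold 0 for the end-expiration pause.
    ``shape`` is ``linear`` (default) or ``cosine`` (eased ramps). The
    companion audio tone maps the same waveform onto pitch, so no separate
    synthesis is needed.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if duration_s < cycle.cycle_s:
        raise ValueError("duration must cover at least one breathing cycle")
    if shape not in ("linear", "cosine"):
        raise ValueError(f"unknown ramp shape {shape!r}")
    t = np.arange(0.0, duration_s, dt_s)
    phase = np.mod(t, cycle.cycle_s)
    h = np.zeros_like(t)
    t1 = cycle.inhale_s
    t2 = t1 + cycle.pause_s
    t3 = t2 + cycle.exhale_s
    rising = phase < t1
    frac_up = phase[rising] / t1
    high = (phase >= t1) & (phase < t2)
    falling = (phase >= t2) & (phase < t3)
    frac_dn = (phase[falling] - t2) / cycle.exhale_s
    if shape == "cosine":
        h[rising] = 0.5 * (1 - np.cos(np.pi * frac_up))
        h[falling] = 0.5 * (1 + np.cos(np.pi * frac_dn))
    else:
        h[rising] = frac_up
        h[falling] = 1.0 - frac_dn
    h[high] = 1.0
    return pd.DataFrame({"t_s": t, "height": h})
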