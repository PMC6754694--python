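"""Training-session orchestration: timed segments, tagging, biofeedback meter.

Two session kinds exist:

* ``basic`` — 3-min rest then 5-min paced-breathing training (480 s);
* ``training_game`` — rest 180 s, flanker stressor 240 s, poststress
  recovery 180 s, training 300 s (900 s total).

Each participant is in one of four arms: pacing at 5 or 6 breaths/min,
with or without the biofeedback display. HRV is computed continuously in
the background regardless of the display flag. The biofeedback meter maps
the current wideband HRV value, relative to the rest-segment baseline,
onto a calm(green)-to-stressed(red) scale updated every 2 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flanker import FlankerTrial, schedule_trials
from .hrv import BAND_NAMES, HRVConfig, HRVRecord, compute_hrv_stream, filter_hrv_range
from .ibi import IBISeries

__all__ = [
    "SessionPlan",
    "MeterCalibration",
    "BiofeedbackState",
    "SessionResult",
    "build_session_plan",
    "run_session",
    "calibrate_meter",
    "meter_state",
    "session_events",
]

SEGMENT_LAYOUTS = {
    "basic": [("rest", 180.0), ("training", 300.0)],
    "training_game": [("rest", 180.0), ("stressor", 240.0), ("recovery", 180.0), ("training", 300.0)],
}


@dataclass(frozen=True)
class SessionPlan:
    kind: str
    rate_bpm: float  # 5 or 6 in-study
    biofeedback: bool
    segments: list[tuple[str, float]]  # ordered (label, duration_s)

    @property
    def total_s(self) -> float:
        return float(sum(d for _, d in self.segments))

    @property
    def pacing_hz(self) -> float:
        return self.rate_bpm / 60.0

    def intervals(self) -> list[tuple[str, float, float]]:
        """Half-open [start, end) intervals per segment, in session time."""
        out, t = [], 0.0
        for label, dur in self.segments:
            out.append((label, t, t + dur))
            t += dur
        return out

    def segment_at(self, t: float) -> str | None:
        for label, start, end in self.intervals():
            if start <= t < end:
                return label
        return None


@dataclass(frozen=True)
class MeterCalibration:
    baseline_mu: float
    baseline_sd: float
    band: str = "wb"

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be non-negative")
        if self.band not in BAND_NAMES:
            raise ValueError(f"unknown band {self.band!r}")


@dataclass(frozen=True)
class BiofeedbackState:
    meter: float  # in [0, 1]
    zone: str  # green | yellow | red


@dataclass
class SessionResult:
    plan: SessionPlan
    records: list[HRVRecord]
    trials: list[FlankerTrial] = field(default_factory=list)
    calibration: MeterCalibration | None = None
    meter: list[tuple[float, float, str]] = field(default_factory=list)  # (t, meter, zone)


def build_session_plan(kind: str, rate_bpm: float = 6.0, biofeedback: bool = True) -> SessionPlan:
    if kind not in SEGMENT_LAYOUTS:
        raise ValueError(f"unknown session kind {kind!r}; expected {sorted(SEGMENT_LAYOUTS)}")
    if rate_bpm not in (5.0, 6.0, 5, 6):
        raise ValueError("in-study pacing rates are 5 or 6 breaths/min")
    return SessionPlan(
        kind=kind,
        rate_bpm=float(rate_bpm),
        biofeedback=bool(biofeedback),
        segments=list(SEGMENT_LAYOUTS[kind]),
    )


def calibrate_meter(
    rest_records: list[HRVRecord],
    band: str = "wb",
    valid_range: tuple[float, float] = (0.0, 10.0),
) -> MeterCalibration:
    """Baseline mean/sd of the configured band over rest-segment records.

    Out-of-range values are excluded first (they are artifact-driven).
    """
    kept, _ = filter_hrv_range(rest_records, valid_range)
    vals = np.array([r.value(band) for r in kept])
    vals = vals[np.isfinite(vals)]
    if vals.size < 3:
        raise ValueError(f"need at least 3 valid rest records to calibrate, got {vals.size}")
    return MeterCalibration(
        baseline_mu=float(np.mean(vals)),
        baseline_sd=float(np.std(vals, ddof=1)),
        band=band,
    )


def meter_state(value: float, cal: MeterCalibration) -> BiofeedbackState:
    """Map an HRV value onto the calm/stress meter.

    meter = clamp((value - (mu - 2 sd)) / (4 sd), 0, 1); zones split at
    thirds: red below 1/3, yellow in [1/3, 2/3), green at or above 2/3.
    With a degenerate (sd = 0) baseline the meter steps at the mean.
    """
    mu, sd = cal.baseline_mu, cal.baseline_sd
    if sd == 0:
        if value < mu:
            meter = 0.0
        elif value == mu:
            meter = 0.5
        else:
            meter = 1.0
    else:
        meter = float(np.clip((value - (mu - 2 * sd)) / (4 * sd), 0.0, 1.0))
    if meter < 1 / 3:
        zone = "red"
    elif meter < 2 / 3:
        zone = "yellow"
    else:
        zone = "green"
    return BiofeedbackState(meter=meter, zone=zone)


def run_session(
    plan: SessionPlan,
    series: IBISeries,
    config: HRVConfig | None = None,
    seed: int | None = None,
) -> SessionResult:
    """Run the full session pipeline over an IBI stream.

    Produces segment-tagged streaming HRV records (window-end rule, half-
    open segments), a flanker schedule during the stressor of a
    training-game session (onsets in session time), and — when enough rest
    records exist — the meter calibration and 2-s meter track. HRV is
    computed even for biofeedback-off arms; only the display flag differs.
    """
    config = config or HRVConfig()
    if series.duration_s < plan.total_s:
        raise ValueError(
            f"series of {series.duration_s:.1f} s shorter than plan ({plan.total_s:.0f} s)"
        )
    records = compute_hrv_stream(series, config, segments=plan.intervals())
    # the stream may run past the plan when the final beat overshoots it;
    # the session owns only windows ending inside [0, total)
    records = [r for r in records if r.t < plan.total_s]
    trials: list[FlankerTrial] = []
    if plan.kind == "training_game":
        stressor = next(iv for iv in plan.intervals() if iv[0] == "stressor")
        rel = schedule_trials(duration_s=stressor[2] - stressor[1], seed=seed)
        trials = [
            FlankerTrial(
                onset_s=t.onset_s + stressor[1],
                center=t.center,
                flankers=t.flankers,
                congruent=t.congruent,
            )
            for t in rel
        ]
    result = SessionResult(plan=plan, records=records, trials=trials)
    rest = [r for r in records if r.segment == "rest"]
    try:
        cal = calibrate_meter(rest, valid_range=config.valid_range)
    except ValueError:
        cal = None
    if cal is not None:
        result.calibration = cal
        for r in records:
            v = r.value(cal.band)
            if np.isfinite(v):
                st = meter_state(v, cal)
                result.meter.append((r.t, st.meter, st.zone))
    return result


def session_events(plan: SessionPlan) -> list[dict]:
    """Timing metadata: segment boundaries plus rest-segment landscape
    fades every 30 s and per-minute narrator announcements."""
    events = []
    for label, start, end in plan.intervals():
        events.append({"t_s": start, "event": "segment_start", "segment": label})
        if label == "rest":
            t = start + 30.0
            while t < end:
                events.append({"t_s": t, "event": "landscape_fade", "segment": label})
                t += 30.0
            t = start + 60.0
            while t <= end:
                events.append({"t_s": t, "event": "minute_announcement", "segment": label})
                t += 60.0
        events.append({"t_s": end, "event": "segment_end", "segment": label})
    return sorted(events, key=lambda e: (e["t_s"], e["event"]))


def meter_to_dataframe(result: SessionResult) -> pd.DataFrame:
    return pd.DataFrame(result.meter, columns=["t_s", "meter", "zone"])


def events_to_json(plan: SessionPlan) -> str:
    return json.dumps(session_events(plan), indent=2)
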