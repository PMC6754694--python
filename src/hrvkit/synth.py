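"""Synthetic IBI streams, sessions, and cohort adherence histories.

The IBI generator is an additive-sinusoid model: each interbeat interval is
the mean plus a respiratory modulation (a sinusoid at the breathing
frequency), a low-frequency modulation, and white beat noise, with optional
split/merge beat artifacts. The model is deliberately transparent: an
in-band sinusoid of amplitude ``A`` ms has variance ``A^2/2``, so the HRV
pipeline's output can be checked against ``ln(A^2/2)`` in closed form.
(An integral-pulse-frequency-modulation generator would be more
physiological but has no such closed form.)

Segment effects encode the expected psychophysiology: cognitive stress
lowers vagal amplitude and shortens the mean IBI; paced breathing at
5-6 breaths/min moves the respiratory peak to the pacing frequency and
raises its amplitude. The default multipliers place the four segment
means at approximately 7.37 (rest), 6.92 (stressor), 7.15 (recovery) and
8.21 (training) ln(ms^2) — the spacing a wideband biofeedback measure
shows across a stressor session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .ibi import IBISeries
from .protocol import StudyCalendar, build_calendar
from .session import SessionPlan

__all__ = [
    "SynthParams",
    "SegmentEffect",
    "default_segment_effects",
    "amp_for_ln_variance",
    "synth_ibi",
    "synth_session",
    "CohortModel",
    "synth_cohort",
]


def amp_for_ln_variance(ln_var: float) -> float:
    """Sinusoid amplitude (ms) whose variance A^2/2 has the given ln."""
    return math.sqrt(2.0 * math.exp(ln_var))


#: Rest-segment respiratory amplitude: places the wideband ln-variance at
#: 7.37 ln(ms^2), a typical resting value on this measure's scale.
REST_RESP_AMP_MS = 56.34


@dataclass(frozen=True)
class SynthParams:
    """Generative settings for one IBI stream."""

    mean_ibi_ms: float = 1000.0
    resp_hz: float = 0.25  # spontaneous breathing ~15 breaths/min
    resp_amp_ms: float = REST_RESP_AMP_MS
    lf_hz: float = 0.08
    lf_amp_ms: float = 15.0
    lf_phase: float = 0.0
    noise_sd_ms: float = 5.0
    artifact_rate: float = 0.0  # per-beat probability of a split/merge
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (250.0 <= self.mean_ibi_ms <= 3000.0):
            raise ValueError("mean_ibi_ms must lie in [250, 3000]")
        if self.resp_amp_ms < 0 or self.lf_amp_ms < 0 or self.noise_sd_ms < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0 <= self.artifact_rate < 0.5:
            raise ValueError("artifact_rate must be in [0, 0.5)")
        nyq = 0.5 * 1000.0 / self.mean_ibi_ms
        for f in (self.resp_hz, self.lf_hz):
            if not 0 < f < nyq:
                raise ValueError(f"modulation frequency {f} Hz exceeds beat-rate Nyquist {nyq:.3f} Hz")
        worst = self.mean_ibi_ms - self.resp_amp_ms - self.lf_amp_ms - 5 * self.noise_sd_ms
        if worst <= 0:
            raise ValueError("parameters imply non-positive interbeat intervals")


@dataclass(frozen=True)
class SegmentEffect:
    """Per-segment multipliers on the base generator."""

    resp_amp_mult: float = 1.0
    mean_ibi_mult: float = 1.0
    resp_hz: float | None = None  # override (training: pacing frequency)

    def __post_init__(self) -> None:
        if self.resp_amp_mult <= 0 or self.mean_ibi_mult <= 0:
            raise ValueError("multipliers must be positive")


def default_segment_effects(pacing_hz: float = 0.1) -> dict[str, SegmentEffect]:
    """Stress lowers vagal amplitude (x0.80) and mean IBI (x0.93, HR up);
    recovery rebounds towards rest (x0.895); paced training moves
    respiration to the pacing frequency with amplitude up (x1.518).

    The amplitude multipliers follow the ln-variance map
    ``mult = exp(delta_ln/2)`` for segment deltas of -0.45, -0.22 and
    +0.835 relative to rest.
    """
    return {
        "rest": SegmentEffect(),
        "stressor": SegmentEffect(resp_amp_mult=0.80, mean_ibi_mult=0.93),
        "recovery": SegmentEffect(resp_amp_mult=0.895),
        "training": SegmentEffect(resp_amp_mult=1.518, resp_hz=pacing_hz),
    }


def _generate_beats(
    params: SynthParams,
    duration_s: float,
    rng: np.random.Generator,
    t_start: float = 0.0,
) -> tuple[list[float], list[bool]]:
    """Sequential beat generation from ``t_start`` for ``duration_s``.

    Returns the recorded intervals and a parallel flag list marking the
    intervals corrupted by an injected split/merge artifact.
    """
    ibis: list[float] = []
    injected: list[bool] = []
    t = t_start
    end = t_start + duration_s
    while t < end:
        ibi = (
            params.mean_ibi_ms
            + params.resp_amp_ms * math.sin(2 * math.pi * params.resp_hz * t)
            + params.lf_amp_ms * math.sin(2 * math.pi * params.lf_hz * t + params.lf_phase)
        )
        if params.noise_sd_ms > 0:
            ibi += rng.normal(0.0, params.noise_sd_ms)
        ibi = max(ibi, 1.0)
        u = rng.uniform() if params.artifact_rate > 0 else 1.0
        if u < params.artifact_rate:
            if u < params.artifact_rate / 2:
                # split beat: the monitor reports two half intervals
                ibis.extend([ibi / 2.0, ibi / 2.0])
                injected.extend([True, True])
            else:
                # merged beat: one doubled interval swallowing the next beat
                ibis.append(ibi * 2.0)
                injected.append(True)
                t += ibi / 1000.0
        else:
            ibis.append(ibi)
            injected.append(False)
        t += ibi / 1000.0
    return ibis, injected


def synth_ibi(params: SynthParams, duration_s: float,
              participant_id: str = "synth",
              annotate_artifacts: bool = False) -> IBISeries:
    """Generate one synthetic IBI stream; reproducible from ``params.seed``.

    With ``annotate_artifacts`` the injected split/merge beats are marked
    in the artifact mask (ground truth for detector evaluation); by
    default the mask reflects only the hard physiological range, as a real
    monitor's stream would.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(params.seed)
    ibis, injected = _generate_beats(params, duration_s, rng)
    mask = np.array(injected) if annotate_artifacts else None
    return IBISeries(np.array(ibis), participant_id=participant_id,
                     source=f"synth(seed={params.seed})", artifact_mask=mask)


def synth_session(
    plan: SessionPlan,
    params: SynthParams | None = None,
    effects: dict[str, SegmentEffect] | None = None,
    seed: int | None = None,
) -> IBISeries:
    """Generate an IBI stream spanning a session plan, segment by segment.

    Time is continuous across segment boundaries; the training segment's
    respiration runs at the arm's pacing frequency (0.0833 or 0.1 Hz).
    Segment intervals are attached to the returned series.
    """
    params = params or SynthParams()
    effects = effects or default_segment_effects(pacing_hz=plan.pacing_hz)
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    all_ibis: list[float] = []
    t = 0.0
    for label, start, end in plan.intervals():
        eff = effects.get(label, SegmentEffect())
        seg_params = replace(
            params,
            resp_amp_ms=params.resp_amp_ms * eff.resp_amp_mult,
            mean_ibi_ms=params.mean_ibi_ms * eff.mean_ibi_mult,
            resp_hz=eff.resp_hz if eff.resp_hz is not None else params.resp_hz,
        )
        # generate until this segment's wall-clock end
        seg_ibis, _ = _generate_beats(seg_params, end - t, rng, t_start=t)
        all_ibis.extend(seg_ibis)
        t += sum(seg_ibis) / 1000.0
    series = IBISeries(np.array(all_ibis), participant_id="synth",
                       source=f"synth_session(seed={seed})")
    series.segments = plan.intervals()
    return series


# ---------------------------------------------------------------- cohort


@dataclass(frozen=True)
class CohortModel:
    """Adherence model: weekly completion probability with geometric decay.

    In week ``k`` every scheduled activity is completed with probability
    ``p0 * decay**(k-1)``; baseline activities use ``p_baseline``. When
    ``completer_fraction`` is set, that fraction of participants is forced
    through the full 3-sessions/week, 6-week regimen regardless of decay
    (the rest follow the decaying model), mimicking the split between
    regimen completers and partial adherers.
    """

    p0: float = 0.9
    decay: float = 0.85
    p_baseline: float = 0.89
    completer_fraction: float | None = None
    start_spread_days: int = 60

    def __post_init__(self) -> None:
        for p in (self.p0, self.decay, self.p_baseline):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.completer_fraction is not None and not 0 <= self.completer_fraction <= 1:
            raise ValueError("completer_fraction must lie in [0, 1]")

    def week_p(self, k: int) -> float:
        return self.p0 * self.decay ** (k - 1)


def synth_cohort(
    n_participants: int,
    model: CohortModel | None = None,
    start_date: date = date(2017, 6, 1),
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[StudyCalendar]]:
    """Generate per-participant activity histories and calendars.

    Returns a history frame (participant_id, activity, date, status)
    consumable by the protocol module, plus the matching calendars.
    """
    model = model or CohortModel()
    rng = np.random.default_rng(seed)
    rows = []
    calendars = []
    for i in range(n_participants):
        pid = f"P{i:04d}"
        entry = start_date + timedelta(days=int(rng.integers(0, model.start_spread_days + 1)))
        cal = build_calendar(pid, entry)
        calendars.append(cal)
        forced = (
            model.completer_fraction is not None
            and rng.uniform() < model.completer_fraction
        )
        for act in cal.scheduled:
            lo, hi = act.window(cal.start_date)
            span = (hi - lo).days
            if act.window_key.startswith("week"):
                k = int(act.window_key[4:])
                p = model.week_p(k)
            elif act.window_key in ("day0", "baseline23"):
                p = model.p_baseline
            else:
                # quarterly/final windows: continue the geometric decay by
                # the window's midpoint week
                mid_week = (act.start_day + act.end_day) / 2 / 7.0
                p = model.week_p(max(int(mid_week), 1))
            force_this = (
                forced
                and act.activity in ("training_basic", "training_game")
                and act.window_key.startswith("week")
            )
            for _ in range(act.required):
                if force_this or rng.uniform() < p:
                    offset = int(rng.integers(0, span + 1)) if span > 0 else 0
                    rows.append(
                        {
                            "participant_id": pid,
                            "activity": act.activity,
                            "date": lo + timedelta(days=offset),
                            "status": "completed",
                        }
                    )
    history = pd.DataFrame(rows, columns=["participant_id", "activity", "date", "status"])
    return history, calendars
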