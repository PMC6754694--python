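"""Eriksen flanker stressor: stimulus scheduling and response scoring.

The flanker task presents a central arrow flanked by four bounding arrows
that all point one way, giving 4 stimulus combinations (center x flankers,
each left/right). Each stimulus is visible for 400 ms; the participant has
a 2.7-s response window to tap the direction of the *central* arrow. A new
stimulus follows at a random 1-3-s interval. The task runs for 4 minutes
and serves as a standardized cognitive stressor.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "FlankerTrial",
    "schedule_trials",
    "adjudicate_response",
    "summarize_flanker",
    "trials_to_dataframe",
]

DIRECTIONS = ("left", "right")
STIMULUS_MS = 400.0
RESPONSE_WINDOW_S = 2.7


@dataclass(frozen=True)
class FlankerTrial:
    onset_s: float
    center: str
    flankers: str
    congruent: bool
    presented_ms: float = STIMULUS_MS
    response: str = "none"  # left | right | none
    rt_s: float | None = None
    outcome: str = "pending"  # correct | incorrect | missed | pending

    def __post_init__(self) -> None:
        if self.center not in DIRECTIONS or self.flankers not in DIRECTIONS:
            raise ValueError("center/flankers must be 'left' or 'right'")
        if self.congruent != (self.center == self.flankers):
            raise ValueError("congruent flag inconsistent with arrows")
        if self.rt_s is not None and self.rt_s < 0:
            raise ValueError("rt_s must be non-negative")


def schedule_trials(
    duration_s: float = 240.0,
    isi_low: float = 1.0,
    isi_high: float = 3.0,
    response_window_s: float = RESPONSE_WINDOW_S,
    seed: int | None = None,
    isi_origin: str = "window_end",
) -> list[FlankerTrial]:
    """Generate a reproducible stimulus schedule.

    Onsets advance sequentially: from the end of the previous response
    window (default) or from stimulus offset (``isi_origin="offset"``) plus
    a uniform 1-3-s inter-stimulus interval. Each stimulus is drawn
    uniformly from the 4 combinations. Generation stops when the next
    trial could not complete its response window within ``duration_s``.
    """
    if not (0 <= isi_low <= isi_high):
        raise ValueError("need 0 <= isi_low <= isi_high")
    if isi_origin not in ("window_end", "offset"):
        raise ValueError(f"unknown isi_origin {isi_origin!r}")
    if duration_s <= response_window_s + isi_high:
        raise ValueError("duration too short for a single trial")
    rng = np.random.default_rng(seed)
    hold = response_window_s if isi_origin == "window_end" else STIMULUS_MS / 1000.0
    trials: list[FlankerTrial] = []
    t = float(rng.uniform(isi_low, isi_high))
    while t + response_window_s <= duration_s:
        center = DIRECTIONS[int(rng.integers(2))]
        flankers = DIRECTIONS[int(rng.integers(2))]
        trials.append(
            FlankerTrial(
                onset_s=round(t, 6),
                center=center,
                flankers=flankers,
                congruent=center == flankers,
            )
        )
        t += hold + float(rng.uniform(isi_low, isi_high))
    return trials


def adjudicate_response(
    trial: FlankerTrial,
    tapped: str,
    t_tap_s: float | None = None,
    response_window_s: float = RESPONSE_WINDOW_S,
) -> FlankerTrial:
    """Score one trial.

    The stimulus is visible for only 400 ms but responses count through the
    full window. Correct iff the tap matches the central arrow within the
    window; late or absent taps are missed.
    """
    if tapped == "none":
        return replace(trial, response="none", rt_s=None, outcome="missed")
    if tapped not in DIRECTIONS:
        raise ValueError(f"invalid response {tapped!r}")
    if t_tap_s is None:
        raise ValueError("t_tap_s required when a tap occurred")
    if t_tap_s < trial.onset_s:
        raise ValueError(f"tap at {t_tap_s} s precedes stimulus onset {trial.onset_s} s")
    rt = t_tap_s - trial.onset_s
    if rt > response_window_s:
        outcome = "missed"
    elif tapped == trial.center:
        outcome = "correct"
    else:
        outcome = "incorrect"
    return replace(trial, response=tapped, rt_s=rt, outcome=outcome)


def _rt_stats(trials: list[FlankerTrial]) -> dict:
    rts = [t.rt_s for t in trials if t.outcome == "correct" and t.rt_s is not None]
    n_correct = sum(t.outcome == "correct" for t in trials)
    return {
        "n": len(trials),
        "n_correct": n_correct,
        "accuracy": n_correct / len(trials),
        "mean_rt_s": float(np.mean(rts)) if rts else None,
        "median_rt_s": float(np.median(rts)) if rts else None,
    }


def summarize_flanker(trials: list[FlankerTrial]) -> dict:
    """Accuracy and reaction-time summary, overall and by congruency."""
    if not trials:
        raise ValueError("no trials to summarize")
    congruent = [t for t in trials if t.congruent]
    incongruent = [t for t in trials if not t.congruent]
    n_missed = sum(t.outcome == "missed" for t in trials)
    n_correct = sum(t.outcome == "correct" for t in trials)
    return {
        "n_trials": len(trials),
        "accuracy": n_correct / len(trials),
        "n_missed": n_missed,
        "congruent": _rt_stats(congruent) if congruent else {"empty": True},
        "incongruent": _rt_stats(incongruent) if incongruent else {"empty": True},
    }


def trials_to_dataframe(trials: list[FlankerTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "onset_s": t.onset_s,
                "center": t.center,
                "flankers": t.flankers,
                "congruent": t.congruent,
                "response": t.response,
                "rt_s": t.rt_s,
                "outcome": t.outcome,
            }
            for t in trials
        ]
    )


def trials_to_json(trials: list[FlankerTrial]) -> str:
    return json.dumps([asdict(t) for t in trials], sort_keys=True)
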