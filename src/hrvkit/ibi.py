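"""Interbeat-interval (IBI) ingest, artifact editing, and signal-quality checks.

An IBI stream is the beat-by-beat output of a chest-strap heart-rate monitor:
one positive interval in milliseconds per heartbeat. Everything downstream
(HRV analysis, biofeedback, session tagging) consumes the :class:`IBISeries`
container defined here.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "IBISeries",
    "ArtifactPolicy",
    "QualityReport",
    "parse_ibi",
    "clean_ibi",
    "quality_check",
    "read_ibi_csv",
    "write_ibi_csv",
]

#: Hard physiological plausibility range for a single interbeat interval
#: (20-240 bpm). Intervals outside it are always artifact-flagged: they are
#: sensor dropouts or packet glitches, not heartbeats.
HARD_RANGE_MS = (250.0, 3000.0)


@dataclass
class IBISeries:
    """A beat-by-beat interbeat-interval stream.

    Parameters
    ----------
    intervals : array of float
        Interbeat intervals in milliseconds, one per beat, all positive.
    participant_id : str
        Opaque participant identifier.
    source : str
        Free-text provenance (device, file, or generator description).
    artifact_mask : bool array, optional
        Per-beat artifact flag. Beats outside the hard physiological range
        are flagged unconditionally on construction.
    segments : list of (label, start_s, end_s), optional
        Half-open session-segment intervals attached by the session layer.
    """

    intervals: np.ndarray
    participant_id: str = ""
    source: str = ""
    artifact_mask: np.ndarray | None = None
    segments: list[tuple[str, float, float]] | None = None
    hard_range_ms: tuple[float, float] = HARD_RANGE_MS

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1 or self.intervals.size == 0:
            raise ValueError("no intervals")
        if np.any(~np.isfinite(self.intervals)) or np.any(self.intervals <= 0):
            bad = int(np.flatnonzero(~(self.intervals > 0))[0]) + 1
            raise ValueError(f"non-positive or non-finite interval at row {bad}")
        lo, hi = self.hard_range_ms
        out_of_range = (self.intervals < lo) | (self.intervals > hi)
        if self.artifact_mask is None:
            self.artifact_mask = out_of_range
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool) | out_of_range
        if self.artifact_mask.shape != self.intervals.shape:
            raise ValueError("artifact_mask length must match intervals")

    @property
    def onsets(self) -> np.ndarray:
        """Beat onset times in seconds from stream start (cumulative)."""
        return np.cumsum(self.intervals) / 1000.0

    @property
    def duration_s(self) -> float:
        return float(self.onsets[-1])

    @property
    def n_beats(self) -> int:
        return int(self.intervals.size)

    @property
    def artifact_fraction(self) -> float:
        return float(np.mean(self.artifact_mask))

    def segment_at(self, t: float) -> str | None:
        """Label of the half-open segment [start, end) containing time ``t``."""
        if not self.segments:
            return None
        for label, start, end in self.segments:
            if start <= t < end:
                return label
        return None


@dataclass(frozen=True)
class ArtifactPolicy:
    """How to detect and repair beat artifacts.

    A beat is flagged when it deviates from the running median of
    ``window`` beats by more than ``rel_threshold`` (relative). Flagged
    beats are either interpolated across from neighbouring good beats
    (``method="interpolate"``, default) or removed (``method="drop"``).
    """

    rel_threshold: float = 0.25
    window: int = 5
    method: str = "interpolate"

    def __post_init__(self) -> None:
        if self.method not in ("interpolate", "drop"):
            raise ValueError(f"unknown artifact method {self.method!r}")
        if not 0 < self.rel_threshold:
            raise ValueError("rel_threshold must be positive")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")


@dataclass(frozen=True)
class QualityReport:
    n_beats: int
    duration_s: float
    mean_hr_bpm: float
    artifact_fraction: float
    verdict: str  # "pass" | "fail"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def parse_ibi(text: str, participant_id: str = "") -> IBISeries:
    """Parse a delimited interval stream into an :class:`IBISeries`.

    One interval (ms) per row; an optional second column of device
    timestamps is ignored for timing (onsets are always cumulative).
    A header row naming ``ibi_ms`` is accepted.
    """
    rows = [ln.strip() for ln in text.splitlines()]
    rows = [r for r in rows if r]
    if rows and rows[0].lower().replace("\t", ",").split(",")[0].strip() in ("ibi_ms", "ibi"):
        rows = rows[1:]
    if not rows:
        raise ValueError("no intervals")
    intervals = []
    for i, row in enumerate(rows, start=1):
        first = row.replace("\t", ",").split(",")[0].strip()
        try:
            val = float(first)
        except ValueError:
            raise ValueError(f"non-numeric interval at row {i}: {first!r}") from None
        if not np.isfinite(val) or val <= 0:
            raise ValueError(f"non-positive interval at row {i}: {first!r}")
        intervals.append(val)
    return IBISeries(np.array(intervals), participant_id=participant_id, source="parse")


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    return median_filter(x, size=window, mode="nearest")


def clean_ibi(series: IBISeries, policy: ArtifactPolicy | None = None) -> IBISeries:
    """Flag and repair beat artifacts.

    Beats deviating more than ``policy.rel_threshold`` from the running
    median of ``policy.window`` beats — plus any beat outside the hard
    physiological range or already flagged — are repaired per the policy.
    Idempotent: cleaning a cleaned series changes nothing.
    """
    policy = policy or ArtifactPolicy()
    x = series.intervals
    if x.size < policy.window:
        raise ValueError(f"need at least {policy.window} beats to clean, got {x.size}")
    med = _running_median(x, policy.window)
    flagged = np.abs(x - med) > policy.rel_threshold * med
    flagged |= series.artifact_mask

    if not flagged.any():
        return replace(series, intervals=x.copy(), artifact_mask=flagged)
    if flagged.all():
        raise ValueError("every beat flagged as artifact; cannot repair")

    if policy.method == "drop":
        kept = ~flagged
        return replace(
            series,
            intervals=x[kept],
            artifact_mask=np.zeros(int(kept.sum()), dtype=bool),
        )

    # interpolate across flagged runs using beat index as the abscissa
    idx = np.arange(x.size)
    good = ~flagged
    repaired = x.copy()
    repaired[flagged] = np.interp(idx[flagged], idx[good], x[good])
    return replace(series, intervals=repaired, artifact_mask=flagged)


def quality_check(
    series: IBISeries,
    min_duration_s: float = 60.0,
    max_artifact_fraction: float = 0.10,
) -> QualityReport:
    """Signal-quality gate: decides whether a session may proceed.

    Degenerate input never raises; it yields a ``fail`` verdict.
    """
    good = series.intervals[~series.artifact_mask]
    mean_hr = float(60000.0 / np.mean(good)) if good.size else float("nan")
    af = series.artifact_fraction
    dur = series.duration_s
    verdict = "pass" if (af <= max_artifact_fraction and dur >= min_duration_s and good.size) else "fail"
    return QualityReport(
        n_beats=series.n_beats,
        duration_s=dur,
        mean_hr_bpm=mean_hr,
        artifact_fraction=af,
        verdict=verdict,
    )


def read_ibi_csv(path_or_buf, participant_id: str = "") -> IBISeries:
    """Read an IBI CSV with required column ``ibi_ms`` and optional
    ``t_s`` / ``artifact`` columns."""
    df = pd.read_csv(path_or_buf)
    if "ibi_ms" not in df.columns:
        raise ValueError("IBI CSV requires an 'ibi_ms' column")
    mask = df["artifact"].to_numpy(dtype=bool) if "artifact" in df.columns else None
    return IBISeries(
        df["ibi_ms"].to_numpy(dtype=float),
        participant_id=participant_id,
        source=str(getattr(path_or_buf, "name", path_or_buf)),
        artifact_mask=mask,
    )


def write_ibi_csv(series: IBISeries, path_or_buf) -> None:
    df = pd.DataFrame(
        {
            "ibi_ms": series.intervals,
            "t_s": series.onsets,
            "artifact": series.artifact_mask.astype(int),
        }
    )
    df.to_csv(path_or_buf, index=False)


def serialize_ibi(series: IBISeries) -> str:
    buf = io.StringIO()
    write_ibi_csv(series, buf)
    return buf.getvalue()
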