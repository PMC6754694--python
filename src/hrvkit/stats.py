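"""Descriptive and inferential statistics over segment-tagged HRV records.

Measures are pooled across sessions and participants within a segment
(rest, stressor, recovery, training), summarized as mean (SE) with a
mean +/- 2 SE plotting interval, and compared between sequential segments
with unpaired t tests (Welch by default). Pooling ignores within-
participant clustering; that is a deliberate replication of common
practice in interim app-data reviews and a documented limitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hrv import HRVRecord

__all__ = ["SegmentSummary", "TTestResult", "segment_stats", "sequential_t_test", "anova_segments"]

#: Natural presentation order of session segments.
SEGMENT_ORDER = ("rest", "stressor", "recovery", "training")


@dataclass(frozen=True)
class SegmentSummary:
    segment: str
    n: int
    mean: float
    se: float

    @property
    def ci2se(self) -> tuple[float, float]:
        return (self.mean - 2 * self.se, self.mean + 2 * self.se)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    direction: int  # sign of mean(b) - mean(a)


def _band_values(records, band: str) -> dict[str, np.ndarray]:
    groups: dict[str, list[float]] = {}
    for r in records:
        if r.segment is None:
            continue
        v = r.value(band) if isinstance(r, HRVRecord) else r[band]
        if np.isfinite(v):
            groups.setdefault(r.segment, []).append(float(v))
    return {k: np.array(v) for k, v in groups.items()}


def segment_stats(records, band: str = "wb") -> list[SegmentSummary]:
    """One mean (SE) summary per segment present in the records.

    ``records`` may be :class:`HRVRecord` objects or a tidy DataFrame with
    ``segment`` and band columns. Measures are counted individually
    (multiple per participant allowed). The outlier range filter is the
    caller's responsibility (see :func:`hrvkit.hrv.filter_hrv_range`).
    """
    if isinstance(records, pd.DataFrame):
        records = [
            HRVRecord(t=float(row.get("t_s", i)), rsa=row.get("rsa", np.nan),
                      lf=row.get("lf", np.nan), wb=row.get("wb", np.nan),
                      segment=row["segment"])
            for i, (_, row) in enumerate(records.iterrows())
            if isinstance(row["segment"], str)
        ]
    groups = _band_values(records, band)
    if not groups:
        raise ValueError("no segment-tagged finite values to summarize")
    out = []
    for seg in sorted(groups, key=lambda s: (SEGMENT_ORDER.index(s) if s in SEGMENT_ORDER else 99, s)):
        vals = groups[seg]
        n = vals.size
        se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        out.append(SegmentSummary(segment=seg, n=int(n), mean=float(np.mean(vals)), se=se))
    return out


def sequential_t_test(a, b, equal_var: bool = False) -> TTestResult:
    """Unpaired t test between two segments' values (Welch by default).

    ``a`` and ``b`` are arrays of values or lists of records from the
    earlier and later segment. Degenerate input (no variance in either
    group and equal means) returns t=0, p=1.
    """
    a = np.asarray([x.value("wb") if isinstance(x, HRVRecord) else x for x in a], dtype=float)
    b = np.asarray([x.value("wb") if isinstance(x, HRVRecord) else x for x in b], dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    direction = int(np.sign(np.mean(b) - np.mean(a)))
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(t=0.0, df=float(a.size + b.size - 2), p=1.0, direction=0)
        return TTestResult(t=math.inf * direction, df=float(a.size + b.size - 2),
                           p=0.0, direction=direction)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
                       direction=direction)


def anova_segments(records, band: str = "wb") -> tuple[float, float]:
    """One-way fixed-effects ANOVA on segment label: (F, p)."""
    groups = _band_values(records, band)
    if len(groups) < 2:
        raise ValueError("need at least two segments for ANOVA")
    res = sps.f_oneway(*groups.values())
    return float(res.statistic), float(res.pvalue)
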