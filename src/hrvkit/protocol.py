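"""Study-protocol engine: calendars, daily activity menu, incentives, compliance.

The yearlong protocol schedules, per participant and relative to their own
entry date (day 0): baseline assessments on days 0-3, a twice-weekly basic
training plus once-weekly training-game regimen with a weekly survey for
weeks 1-6, quarterly surveys and practice at months 3/6/9, and a final
survey at month 12. Incentives (US $) follow the protocol table: 15 and
5+5 for the baseline parts, 10 per compliant week, 20 per quarterly
survey, 20 for the final survey. A nightly scan pays earned, unpaid
incentives. Compliance is the ratio of completed to scheduled activities,
adjusted for each participant's start date.

Week ``k`` covers study days ``7(k-1)+1 .. 7k``; months are 30-day blocks
(month ``m`` covers days ``30(m-1)+1 .. 30m``). Neither boundary is dictated
by the protocol table; both are package conventions and configurable here.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "ScheduledActivity",
    "StudyCalendar",
    "IncentiveRule",
    "LedgerEntry",
    "IncentiveLedger",
    "build_calendar",
    "daily_menu",
    "evaluate_incentives",
    "fulfillment_scan",
    "compliance_report",
    "compliance_ratio",
    "normalize_history",
]

TRAINING_ACTIVITIES = ("training_basic", "training_game")

#: Protocol incentive amounts (US $) by rule key prefix.
AMOUNT_BASELINE_1 = 15.0
AMOUNT_BASELINE_23 = 5.0
AMOUNT_WEEKLY = 10.0
AMOUNT_QUARTERLY = 20.0
AMOUNT_FINAL = 20.0

#: Days a weekly survey stays on the menu once scheduled.
SURVEY_MENU_DAYS = 4


@dataclass(frozen=True)
class ScheduledActivity:
    activity: str
    start_day: int  # inclusive, study days from start_date
    end_day: int  # inclusive
    required: int
    window_key: str

    def window(self, start_date: date) -> tuple[date, date]:
        return (start_date + timedelta(days=self.start_day),
                start_date + timedelta(days=self.end_day))


@dataclass(frozen=True)
class StudyCalendar:
    participant_id: str
    start_date: date
    scheduled: tuple[ScheduledActivity, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "participant_id": self.participant_id,
                "start_date": self.start_date.isoformat(),
                "scheduled": [asdict(a) for a in self.scheduled],
            },
            indent=2,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "StudyCalendar":
        return cls(
            participant_id=d["participant_id"],
            start_date=date.fromisoformat(d["start_date"]),
            scheduled=tuple(ScheduledActivity(**a) for a in d["scheduled"]),
        )


def week_days(k: int) -> tuple[int, int]:
    """Study-day window of week ``k`` (1-based): days 7(k-1)+1 .. 7k."""
    return 7 * (k - 1) + 1, 7 * k


def month_days(m: int) -> tuple[int, int]:
    """Study-day window of month ``m`` (1-based, 30-day blocks)."""
    return 30 * (m - 1) + 1, 30 * m


def build_calendar(participant_id: str, start_date: date) -> StudyCalendar:
    """Deterministic per-participant calendar anchored at the entry date."""
    sched: list[ScheduledActivity] = [
        ScheduledActivity("baseline_part1", 0, 0, 1, "day0"),
        ScheduledActivity("training_game", 0, 0, 1, "day0"),
        ScheduledActivity("baseline_part2", 0, 3, 1, "baseline23"),
        ScheduledActivity("baseline_part3", 0, 3, 1, "baseline23"),
    ]
    for k in range(1, 7):
        lo, hi = week_days(k)
        key = f"week{k}"
        sched += [
            ScheduledActivity("training_basic", lo, hi, 2, key),
            ScheduledActivity("training_game", lo, hi, 1, key),
            ScheduledActivity("weekly_survey", lo, hi, 1, key),
        ]
    for m in (3, 6, 9):
        lo, hi = month_days(m)
        key = f"month{m}"
        sched += [
            ScheduledActivity("training_basic", lo, hi, 8, key),
            ScheduledActivity("training_game", lo, hi, 1, key),
            ScheduledActivity("quarterly_survey", lo, hi, 1, key),
        ]
    lo, hi = month_days(12)
    sched += [
        ScheduledActivity("training_basic", lo, hi, 2, "month12"),
        ScheduledActivity("training_game", lo, hi, 1, "month12"),
        ScheduledActivity("final_survey", lo, hi, 1, "month12"),
    ]
    return StudyCalendar(participant_id=participant_id, start_date=start_date,
                         scheduled=tuple(sched))


# ---------------------------------------------------------------- history


def normalize_history(history) -> pd.DataFrame:
    """Coerce an activity history to a frame with columns
    participant_id, activity, date (datetime.date), status."""
    if isinstance(history, pd.DataFrame):
        df = history.copy()
    else:
        df = pd.DataFrame(list(history),
                          columns=["participant_id", "activity", "date", "status"])
    if df.empty:
        return pd.DataFrame(columns=["participant_id", "activity", "date", "status"])
    for col in ("participant_id", "activity", "date", "status"):
        if col not in df.columns:
            raise ValueError(f"history missing column {col!r}")
    if not isinstance(df["date"].iloc[0], date) or hasattr(df["date"].iloc[0], "hour"):
        df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def _completed_in_window(hist: pd.DataFrame, activity: str, lo: date, hi: date,
                         statuses=("completed",)) -> pd.DataFrame:
    m = (
        (hist["activity"] == activity)
        & (hist["status"].isin(statuses))
        & (hist["date"] >= lo)
        & (hist["date"] <= hi)
    )
    return hist[m]


# ---------------------------------------------------------------- daily menu


def daily_menu(calendar: StudyCalendar, on_date: date, history) -> list[dict]:
    """Pending activities for one participant on one day.

    Completed activities are removed; pending trainings carry a
    "sessions remaining this week" note; a weekly survey drops off the
    menu ``SURVEY_MENU_DAYS`` days after it was scheduled.
    """
    if on_date < calendar.start_date:
        raise ValueError("date precedes study entry")
    hist = normalize_history(history)
    hist = hist[hist["participant_id"] == calendar.participant_id]
    menu: list[dict] = []
    for act in calendar.scheduled:
        lo, hi = act.window(calendar.start_date)
        if not (lo <= on_date <= hi):
            continue
        done = len(_completed_in_window(hist, act.activity, lo, hi))
        if done >= act.required:
            continue
        if act.activity == "weekly_survey" and (on_date - lo).days >= SURVEY_MENU_DAYS:
            continue
        entry = {
            "activity": act.activity,
            "window_key": act.window_key,
            "required": act.required,
            "completed": done,
            "note": "",
        }
        if act.activity in TRAINING_ACTIVITIES and act.window_key.startswith("week"):
            total_req = sum(a.required for a in calendar.scheduled
                            if a.window_key == act.window_key and a.activity in TRAINING_ACTIVITIES)
            total_done = sum(
                len(_completed_in_window(hist, a, lo, hi)) for a in TRAINING_ACTIVITIES
            )
            entry["note"] = f"{max(total_req - total_done, 0)} remaining"
        menu.append(entry)
    return menu


# ---------------------------------------------------------------- incentives


@dataclass(frozen=True)
class IncentiveRule:
    key: str
    amount: float
    kind: str  # "activity" | "weekly"
    activity: str | None = None
    window_key: str | None = None


def default_rules() -> list[IncentiveRule]:
    rules = [
        IncentiveRule("baseline_part1", AMOUNT_BASELINE_1, "activity", "baseline_part1", "day0"),
        IncentiveRule("baseline_part2", AMOUNT_BASELINE_23, "activity", "baseline_part2", "baseline23"),
        IncentiveRule("baseline_part3", AMOUNT_BASELINE_23, "activity", "baseline_part3", "baseline23"),
    ]
    rules += [IncentiveRule(f"week{k}", AMOUNT_WEEKLY, "weekly", None, f"week{k}")
              for k in range(1, 7)]
    rules += [IncentiveRule(f"month{m}_quarterly", AMOUNT_QUARTERLY, "activity",
                            "quarterly_survey", f"month{m}") for m in (3, 6, 9)]
    rules.append(IncentiveRule("final_survey", AMOUNT_FINAL, "activity",
                               "final_survey", "month12"))
    return rules


@dataclass
class LedgerEntry:
    participant_id: str
    rule_key: str
    amount: float
    earned_date: date
    fulfilled: bool = False
    fulfilled_date: date | None = None


class IncentiveLedger:
    """Earned/fulfilled incentive entries; duplicates (participant, rule)
    are silently ignored so re-evaluation is idempotent."""

    def __init__(self) -> None:
        self.entries: list[LedgerEntry] = []
        self._keys: set[tuple[str, str]] = set()

    def add(self, entries) -> list[LedgerEntry]:
        added = []
        for e in entries:
            key = (e.participant_id, e.rule_key)
            if key in self._keys:
                continue
            self._keys.add(key)
            self.entries.append(e)
            added.append(e)
        return added

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._keys

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def total_earned(self) -> float:
        return float(sum(e.amount for e in self.entries))

    @property
    def total_paid(self) -> float:
        return float(sum(e.amount for e in self.entries if e.fulfilled))

    def to_json(self) -> str:
        return json.dumps(
            [
                {**asdict(e),
                 "earned_date": e.earned_date.isoformat(),
                 "fulfilled_date": e.fulfilled_date.isoformat() if e.fulfilled_date else None}
                for e in self.entries
            ],
            indent=2,
        )


def evaluate_incentives(
    calendar: StudyCalendar,
    history,
    as_of_date: date,
    mode: str = "strict",
    rules: list[IncentiveRule] | None = None,
    ledger: IncentiveLedger | None = None,
) -> list[LedgerEntry]:
    """Find newly earned incentives for one participant.

    ``strict`` weekly criterion: both basic trainings, the training game,
    and the weekly survey completed within the week. ``relaxed``: an
    initiated (or completed) weekly survey suffices — the criterion the
    study fell back to mid-course. Each satisfied rule yields exactly one
    entry; entries already present in ``ledger`` are not re-issued.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown incentive mode {mode!r}")
    rules = rules if rules is not None else default_rules()
    hist = normalize_history(history)
    hist = hist[(hist["participant_id"] == calendar.participant_id)
                & (hist["date"] <= as_of_date)]
    by_window = {a.window_key: a for a in calendar.scheduled}
    new: list[LedgerEntry] = []
    for rule in rules:
        if ledger is not None and (calendar.participant_id, rule.key) in ledger:
            continue
        sched = [a for a in calendar.scheduled if a.window_key == rule.window_key]
        if not sched:
            continue
        lo, hi = sched[0].window(calendar.start_date)
        earned_date: date | None = None
        if rule.kind == "activity":
            done = _completed_in_window(hist, rule.activity, lo, hi)
            if len(done) >= 1:
                earned_date = max(done["date"])
        elif rule.kind == "weekly":
            dates = []
            ok = True
            survey_statuses = ("completed",) if mode == "strict" else ("completed", "initiated")
            survey = _completed_in_window(hist, "weekly_survey", lo, hi, survey_statuses)
            if survey.empty:
                ok = False
            else:
                dates.append(max(survey["date"]))
            if mode == "strict" and ok:
                for a in sched:
                    if a.activity in TRAINING_ACTIVITIES:
                        done = _completed_in_window(hist, a.activity, lo, hi)
                        if len(done) < a.required:
                            ok = False
                            break
                        dates.append(sorted(done["date"])[a.required - 1])
            if ok:
                earned_date = max(dates)
        if earned_date is not None and earned_date <= as_of_date:
            new.append(LedgerEntry(calendar.participant_id, rule.key, rule.amount, earned_date))
    if ledger is not None:
        new = ledger.add(new)
    return new


def fulfillment_scan(ledger: IncentiveLedger, as_of_date: date) -> list[tuple[str, float]]:
    """The nightly scan: mark every earned, unfulfilled entry as paid.

    Returns (participant_id, amount) payouts; an immediate second run
    returns nothing.
    """
    payouts = []
    for e in ledger.entries:
        if not e.fulfilled and e.earned_date <= as_of_date:
            e.fulfilled = True
            e.fulfilled_date = as_of_date
            payouts.append((e.participant_id, e.amount))
    return payouts


# ---------------------------------------------------------------- compliance


def compliance_ratio(completed: int, scheduled: int) -> float:
    """Completed/scheduled as a percentage rounded to one decimal."""
    if scheduled <= 0:
        return 0.0
    return round(100.0 * completed / scheduled, 1)


@dataclass
class ComplianceReport:
    as_of_date: date
    activity_table: pd.DataFrame  # activity, window_key, scheduled, completed, pct
    sessions_per_day: pd.Series  # training sessions by study day
    completion_curve: pd.DataFrame  # survey windows in order, completed counts
    n_enrolled: int
    n_regimen_completers: int

    @property
    def regimen_pct(self) -> float:
        return compliance_ratio(self.n_regimen_completers, self.n_enrolled)

    def to_json(self) -> str:
        return json.dumps(
            {
                "as_of_date": self.as_of_date.isoformat(),
                "n_enrolled": self.n_enrolled,
                "n_regimen_completers": self.n_regimen_completers,
                "regimen_pct": self.regimen_pct,
                "activities": self.activity_table.to_dict(orient="records"),
            },
            indent=2,
        )


def _completed_regimen(hist: pd.DataFrame, cal: StudyCalendar) -> bool:
    """At least 3 training sessions in each of weeks 1-6."""
    for k in range(1, 7):
        lo_d, hi_d = week_days(k)
        lo = cal.start_date + timedelta(days=lo_d)
        hi = cal.start_date + timedelta(days=hi_d)
        n = sum(len(_completed_in_window(hist, a, lo, hi)) for a in TRAINING_ACTIVITIES)
        if n < 3:
            return False
    return True


def compliance_report(histories, calendars: list[StudyCalendar], as_of_date: date) -> ComplianceReport:
    """Cohort compliance: per-activity completed/scheduled ratios, the
    sessions-per-study-day histogram, and the survey completion curve.

    An activity counts as scheduled for a participant once its window has
    opened by ``as_of_date`` (start-date adjusted); it counts as completed
    when the required number of completions fell inside the window.
    """
    if not calendars:
        raise ValueError("need at least one participant calendar")
    hist_all = normalize_history(histories)
    hist_all = hist_all[hist_all["date"] <= as_of_date] if not hist_all.empty else hist_all
    rows: dict[tuple[str, str], dict] = {}
    day_counts: dict[int, int] = {}
    n_completers = 0
    for cal in calendars:
        hist = hist_all[hist_all["participant_id"] == cal.participant_id] if not hist_all.empty else hist_all
        if not hist.empty and _completed_regimen(hist, cal):
            n_completers += 1
        for act in cal.scheduled:
            lo, hi = act.window(cal.start_date)
            if lo > as_of_date:
                continue
            key = (act.activity, act.window_key)
            row = rows.setdefault(
                key,
                {"activity": act.activity, "window_key": act.window_key,
                 "scheduled": 0, "completed": 0},
            )
            row["scheduled"] += 1
            if not hist.empty and len(_completed_in_window(hist, act.activity, lo, hi)) >= act.required:
                row["completed"] += 1
        if not hist.empty:
            training = hist[hist["activity"].isin(TRAINING_ACTIVITIES)
                            & (hist["status"] == "completed")]
            for d in training["date"]:
                sd = (d - cal.start_date).days
                day_counts[sd] = day_counts.get(sd, 0) + 1
    table = pd.DataFrame(list(rows.values()))
    if not table.empty:
        table["pct"] = [compliance_ratio(c, s) for c, s in zip(table["completed"], table["scheduled"])]
    per_day = pd.Series(day_counts, dtype=int).sort_index() if day_counts else pd.Series(dtype=int)
    surveys = table[table["activity"].str.contains("survey")] if not table.empty else table
    return ComplianceReport(
        as_of_date=as_of_date,
        activity_table=table,
        sessions_per_day=per_day,
        completion_curve=surveys.reset_index(drop=True) if not table.empty else table,
        n_enrolled=len(calendars),
        n_regimen_completers=n_completers,
    )
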