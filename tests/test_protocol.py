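"""Study calendar, daily menu, incentives, and compliance reporting."""

from datetime import date, timedelta

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hrvkit import (
    IncentiveLedger,
    build_calendar,
    compliance_ratio,
    compliance_report,
    daily_menu,
    evaluate_incentives,
    fulfillment_scan,
)
from hrvkit.protocol import week_days

START = date(2017, 6, 5)


def hist(*rows):
    return pd.DataFrame(rows, columns=["participant_id", "activity", "date", "status"])


def day(n):
    return START + timedelta(days=n)


class TestCalendar:
    cal = build_calendar("p1", START)

    def test_weeks_one_to_six_have_18_training_sessions(self):
        n = sum(a.required for a in self.cal.scheduled
                if a.window_key.startswith("week") and a.activity.startswith("training"))
        assert n == 18

    def test_day0_baseline_part1_worth_15(self):
        from hrvkit.protocol import default_rules
        rules = {r.key: r for r in default_rules()}
        assert rules["baseline_part1"].amount == 15.0
        entries = [a for a in self.cal.scheduled if a.activity == "baseline_part1"]
        assert entries[0].start_day == 0 and entries[0].end_day == 0

    def test_quarter_windows_anchored_at_months_3_6_9(self):
        quarters = [a for a in self.cal.scheduled if a.activity == "quarterly_survey"]
        assert [a.start_day for a in quarters] == [61, 151, 241]

    def test_weekly_window_definition(self):
        assert week_days(1) == (1, 7)
        assert week_days(2) == (8, 14)

    def test_determinism(self):
        assert build_calendar("p1", START) == build_calendar("p1", START)


class TestMenu:
    cal = build_calendar("p1", START)

    def test_training_remaining_annotation(self):
        h = hist(("p1", "training_basic", day(9), "completed"))
        menu = daily_menu(self.cal, day(10), h)
        training = [m for m in menu if m["activity"] == "training_basic"]
        assert training and training[0]["note"] == "2 remaining"

    def test_completed_survey_removed(self):
        h = hist(("p1", "weekly_survey", day(8), "completed"))
        menu = daily_menu(self.cal, day(9), h)
        assert not any(m["activity"] == "weekly_survey" for m in menu)

    def test_stale_survey_expires_after_four_days(self):
        menu = daily_menu(self.cal, day(8 + 5), hist())
        assert not any(m["activity"] == "weekly_survey" for m in menu)
        fresh = daily_menu(self.cal, day(8 + 2), hist())
        assert any(m["activity"] == "weekly_survey" for m in fresh)

    def test_date_before_entry_raises(self):
        with pytest.raises(ValueError):
            daily_menu(self.cal, START - timedelta(days=1), hist())


def full_week(pid="p1", week=1, survey_status="completed"):
    lo, _ = week_days(week)
    rows = [
        (pid, "training_basic", day(lo), "completed"),
        (pid, "training_basic", day(lo + 2), "completed"),
        (pid, "training_game", day(lo + 4), "completed"),
        (pid, "weekly_survey", day(lo + 1), survey_status),
    ]
    return rows


class TestIncentives:
    cal = build_calendar("p1", START)

    def test_strict_week_earns_ten(self):
        entries = evaluate_incentives(self.cal, hist(*full_week()), day(30))
        weekly = [e for e in entries if e.rule_key == "week1"]
        assert len(weekly) == 1 and weekly[0].amount == 10.0

    def test_strict_requires_trainings(self):
        rows = [r for r in full_week() if r[1] != "training_game"]
        entries = evaluate_incentives(self.cal, hist(*rows), day(30))
        assert not any(e.rule_key == "week1" for e in entries)

    def test_relaxed_survey_initiation_suffices(self):
        h = hist(("p1", "weekly_survey", day(3), "initiated"))
        strict = evaluate_incentives(self.cal, h, day(30), mode="strict")
        relaxed = evaluate_incentives(self.cal, h, day(30), mode="relaxed")
        assert not any(e.rule_key == "week1" for e in strict)
        assert any(e.rule_key == "week1" for e in relaxed)

    def test_baseline_completion_earns_15(self):
        h = hist(("p1", "baseline_part1", day(0), "completed"))
        entries = evaluate_incentives(self.cal, h, day(5))
        assert [e.amount for e in entries if e.rule_key == "baseline_part1"] == [15.0]

    def test_reevaluation_no_duplicates(self):
        ledger = IncentiveLedger()
        h = hist(*full_week())
        first = evaluate_incentives(self.cal, h, day(30), ledger=ledger)
        second = evaluate_incentives(self.cal, h, day(30), ledger=ledger)
        assert len(first) >= 1 and second == []
        assert len(ledger) == len(first)


class TestFulfillment:
    def ledger_with(self, n):
        cal = build_calendar("p1", START)
        rows = []
        for k in range(1, n + 1):
            rows += full_week(week=k)
        ledger = IncentiveLedger()
        evaluate_incentives(cal, hist(*rows), day(60), ledger=ledger)
        return ledger

    def test_scan_pays_all_pending(self):
        ledger = self.ledger_with(2)
        payouts = fulfillment_scan(ledger, day(60))
        assert len(payouts) == len(ledger.entries)
        assert all(e.fulfilled for e in ledger.entries)

    def test_second_scan_empty(self):
        ledger = self.ledger_with(2)
        fulfillment_scan(ledger, day(60))
        assert fulfillment_scan(ledger, day(61)) == []

    def test_empty_ledger(self):
        assert fulfillment_scan(IncentiveLedger(), day(1)) == []

    def test_conservation(self):
        """Total paid equals the sum of fulfilled amounts and never
        exceeds total earned."""
        ledger = self.ledger_with(3)
        fulfillment_scan(ledger, day(60))
        assert ledger.total_paid == sum(e.amount for e in ledger.entries if e.fulfilled)
        assert ledger.total_paid <= ledger.total_earned


class TestCompliance:
    def test_printed_worked_examples(self):
        """The ratio arithmetic on the study's printed counts."""
        assert compliance_ratio(207, 328) == 63.1
        assert compliance_ratio(164, 328) == 50.0
        assert compliance_ratio(75, 328) == 22.9
        assert compliance_ratio(36, 328) == 11.0
        assert compliance_ratio(0, 328) == 0.0

    def test_report_counts_and_adjusts_for_start_date(self):
        cal_a = build_calendar("a", START)
        cal_b = build_calendar("b", START + timedelta(days=100))
        h = hist(("a", "weekly_survey", day(9), "completed"))
        rep = compliance_report(h, [cal_a, cal_b], day(20))
        row = rep.activity_table.query("activity == 'weekly_survey' and window_key == 'week2'")
        # b's week-2 window has not opened yet, so only a is scheduled
        assert int(row["scheduled"].iloc[0]) == 1

    def test_regimen_completer_detection(self):
        rows = []
        for k in range(1, 7):
            rows += full_week("a", week=k)
        rep = compliance_report(hist(*rows),
                                [build_calendar("a", START), build_calendar("b", START)],
                                day(60))
        assert rep.n_regimen_completers == 1
        assert rep.regimen_pct == 50.0

    def test_sessions_per_day_histogram(self):
        rows = full_week("a", week=1)
        rep = compliance_report(hist(*rows), [build_calendar("a", START)], day(60))
        assert int(rep.sessions_per_day.sum()) == 3

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            compliance_report(hist(), [], day(10))

    @given(st.integers(0, 400), st.integers(1, 400), st.integers(0, 50))
    @settings(max_examples=100, derandomize=True)
    def test_ratio_bounds_and_monotonicity(self, completed, scheduled, extra):
        completed = min(completed, scheduled)
        r1 = compliance_ratio(completed, scheduled)
        r2 = compliance_ratio(completed, scheduled + extra)
        assert 0.0 <= r1 <= 100.0
        assert r2 <= r1
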