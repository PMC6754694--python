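"""Synthetic IBI/session/cohort generator properties."""

from datetime import timedelta

import numpy as np
import pytest

from hrvkit import (
    CohortModel,
    HRVConfig,
    SynthParams,
    amp_for_ln_variance,
    band_ln_variance,
    build_session_plan,
    clean_ibi,
    compliance_report,
    synth_cohort,
    synth_ibi,
    synth_session,
)

from conftest import closed_form_ln_variance


def wb_mean(series, config=HRVConfig()):
    return float(np.mean([v for _, v in band_ln_variance(series, "wb", config)]))


class TestSynthIBI:
    def test_closed_form_recovery(self):
        p = SynthParams(resp_amp_ms=56.34, resp_hz=0.25, lf_amp_ms=0.0,
                        noise_sd_ms=0.0, seed=1)
        series = synth_ibi(p, 300)
        assert wb_mean(series) == pytest.approx(np.log(56.34**2 / 2), abs=0.2)

    def test_same_seed_identical(self):
        p = SynthParams(seed=5, artifact_rate=0.05)
        a, b = synth_ibi(p, 120), synth_ibi(p, 120)
        np.testing.assert_array_equal(a.intervals, b.intervals)

    def test_beat_count_matches_rate(self):
        p = SynthParams(mean_ibi_ms=1000.0, resp_amp_ms=0.0, lf_amp_ms=0.0,
                        noise_sd_ms=0.0, seed=0)
        series = synth_ibi(p, 180)
        assert abs(series.n_beats - 180) <= 2

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            SynthParams(mean_ibi_ms=300.0, resp_amp_ms=290.0)
        with pytest.raises(ValueError, match="Nyquist"):
            SynthParams(resp_hz=0.45, mean_ibi_ms=2000.0)

    def test_parameter_recovery_over_replicates(self):
        """Over 20 seeds the pipeline-estimated wideband mean stays within
        0.2 ln-units of the generator's closed-form set point."""
        target = closed_form_ln_variance(56.34)
        vals = [
            wb_mean(synth_ibi(SynthParams(lf_amp_ms=0.0, noise_sd_ms=2.0, seed=s), 180))
            for s in range(20)
        ]
        assert float(np.mean(vals)) == pytest.approx(target, abs=0.2)

    def test_artifact_fraction_recovered_by_cleaner(self):
        """At a 5% injection rate the cleaning rule recovers the injected
        artifact fraction within 20% relative error."""
        injected, detected = 0, 0
        total = 0
        for seed in range(10):
            p = SynthParams(artifact_rate=0.05, seed=seed)
            truth = synth_ibi(p, 300, annotate_artifacts=True)
            blind = synth_ibi(p, 300, annotate_artifacts=False)
            cleaned = clean_ibi(blind)
            injected += int(truth.artifact_mask.sum())
            detected += int(cleaned.artifact_mask.sum())
            total += truth.n_beats
        inj_frac, det_frac = injected / total, detected / total
        assert det_frac == pytest.approx(inj_frac, rel=0.2)


class TestSynthSession:
    def test_stress_amplitude_maps_to_ln_variance_drop(self):
        """An amplitude multiplier m shifts the band value by 2 ln m:
        stress at x0.8 sits ~0.446 below rest."""
        base = SynthParams(lf_amp_ms=0.0, noise_sd_ms=0.0, seed=2)
        rest = synth_ibi(base, 240)
        from dataclasses import replace

        stress = synth_ibi(replace(base, resp_amp_ms=base.resp_amp_ms * 0.8), 240)
        assert wb_mean(stress) - wb_mean(rest) == pytest.approx(2 * np.log(0.8), abs=0.1)

    def test_training_wideband_up_rsa_down(self):
        """Paced breathing at 0.1 Hz with amplitude up raises wideband
        while the RSA-band value falls relative to rest."""
        plan = build_session_plan("training_game", 6, True)
        series = synth_session(plan, SynthParams(noise_sd_ms=0.0, lf_amp_ms=0.0), seed=9)
        cfg = HRVConfig()

        def seg_series(label):
            lo, hi = next((l, h) for s, l, h in plan.intervals() if s == label)
            m = (series.onsets > lo) & (series.onsets <= hi)
            from hrvkit.ibi import IBISeries

            return IBISeries(series.intervals[m])

        rest, training = seg_series("rest"), seg_series("training")
        assert wb_mean(training) > wb_mean(rest)
        rsa = lambda s: float(np.mean([v for _, v in band_ln_variance(s, "rsa", cfg)]))
        assert rsa(training) < rsa(rest)

    def test_recovery_matches_rest_with_unit_multiplier(self):
        from hrvkit.synth import SegmentEffect, default_segment_effects

        effects = default_segment_effects()
        effects["recovery"] = SegmentEffect()  # multiplier 1.0
        plan = build_session_plan("training_game", 6, True)
        series = synth_session(plan, SynthParams(lf_amp_ms=0.0, noise_sd_ms=0.0),
                               effects=effects, seed=13)
        from hrvkit import run_session

        res = run_session(plan, series, seed=13)
        rest = np.mean([r.wb for r in res.records if r.segment == "rest"])
        rec = np.mean([r.wb for r in res.records if r.segment == "recovery"])
        assert rec == pytest.approx(rest, abs=0.15)

    def test_spans_plan_and_carries_segments(self):
        plan = build_session_plan("basic", 5, True)
        series = synth_session(plan, seed=1)
        assert series.duration_s >= plan.total_s
        assert series.segments == plan.intervals()


class TestSynthCohort:
    def test_no_dropout_full_compliance(self):
        model = CohortModel(p0=1.0, decay=1.0, p_baseline=1.0)
        hist, cals = synth_cohort(20, model, seed=0)
        last = max(c.start_date for c in cals) + timedelta(days=50)
        rep = compliance_report(hist, cals, last)
        weekly = rep.activity_table[rep.activity_table["window_key"].str.startswith("week")]
        assert (weekly["pct"] == 100.0).all()

    def test_immediate_dropout_zero_after_week_one(self):
        model = CohortModel(p0=1.0, decay=0.0, p_baseline=1.0)
        hist, cals = synth_cohort(20, model, seed=0)
        last = max(c.start_date for c in cals) + timedelta(days=50)
        rep = compliance_report(hist, cals, last)
        w2 = rep.activity_table[rep.activity_table["window_key"] == "week2"]
        assert (w2["pct"] == 0.0).all()

    def test_completer_fraction_recovered(self):
        """With the completer fraction set, the reported regimen-completion
        share falls inside a 3-sigma binomial interval at n=328."""
        p = 0.631
        n = 328
        hist, cals = synth_cohort(n, CohortModel(completer_fraction=p, p0=0.3, decay=0.7),
                                  seed=42)
        last = max(c.start_date for c in cals) + timedelta(days=60)
        rep = compliance_report(hist, cals, last)
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(rep.n_regimen_completers / n - p) < 3 * sigma

    def test_expected_weekly_decay_monotone(self):
        model = CohortModel(p0=0.95, decay=0.8)
        hist, cals = synth_cohort(200, model, seed=7)
        last = max(c.start_date for c in cals) + timedelta(days=60)
        rep = compliance_report(hist, cals, last)
        surveys = rep.activity_table[rep.activity_table["activity"] == "weekly_survey"]
        pct = surveys.sort_values("window_key")["pct"].to_numpy()
        # allow sampling jitter but require an overall downward trend
        assert pct[0] > pct[-1]
        assert np.polyfit(np.arange(len(pct)), pct, 1)[0] < 0
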