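# Methods

## Signal model and the ln-variance HRV measures

The analysis treats the beat-by-beat interbeat-interval (IBI) sequence as
an irregularly sampled signal: beat *k* occurs at onset
*t_k* = Σ IBI_i /1000 (seconds), carrying the value IBI_k (ms). HRV in a
frequency band [f₁, f₂] is quantified as ln of the variance of the
band-limited signal, in ln(ms²). Three bands are computed throughout:
RSA 0.12–0.40 Hz, LF 0.06–0.10 Hz, and a wideband 0.03–0.40 Hz that
also covers paced breathing at 5–6 breaths/min (0.083–0.1 Hz), which
spontaneous-breathing RSA bands miss. All three band edges are
configuration, not constants.

The pipeline is, in order:

1. **Artifact editing.** A beat deviating more than 25 % (relative) from
   the running median of 5 beats, or falling outside the hard
   physiological range 250–3000 ms, is flagged and repaired — linearly
   interpolated across by default, optionally dropped. The rule is the
   standard relative-running-median IBI editor; the 25 %/5-beat defaults
   are package choices and both are parameters. Editing is idempotent.
2. **Resampling** to an even grid at 5 Hz by cubic-spline interpolation
   against the onsets. Cubic interpolation is used deliberately instead
   of zero-order hold: a held step signal attenuates a tone at frequency
   f by sinc(f·T̄) (T̄ = mean IBI), which at 0.25 Hz and 1000 ms beats
   costs −0.21 ln-units — sufficient to violate the ±0.1 closed-form
   tolerance this package holds itself to. Measured cubic-spline error at
   0.25 Hz is −0.05 ln-units. `previous` and `linear` remain available in
   the configuration for comparison.
3. **Detrending** by subtracting a moving cubic-polynomial
   (Savitzky–Golay) fit. The window is 101 s by default and is capped at
   the available signal, so a 30-s streaming window degrades to removing
   a single cubic fit. The window must be long: subtracting a short-window
   moving-polynomial trend acts as a high-pass whose cutoff would fall
   inside the LF and paced-breathing bands (a 10-s window at 5 Hz cuts
   near 0.13 Hz and would erase the very tones the wideband measure
   exists to capture). With the 101-s default the measured error at the
   LF band center (0.08 Hz) is +0.02 ln-units.
4. **Band-passing** with a zero-phase FFT mask with raised-cosine
   transition edges (width min(0.01 Hz, bandwidth/4)). A forward–backward
   FIR was considered and rejected: the 0.04-Hz-wide LF band at 5 Hz
   needs ≈800 taps for a usable transition, and filtfilt then requires
   several hundred seconds of signal — impossible on a 30-s streaming
   window of 150 samples. The FFT mask is deterministic, exactly
   zero-phase, and its measured out-of-band leakage is below −26 dB
   (> 6 ln-units) for the test tones.
5. **Variance.** Offline: ln(variance) per non-overlapping 30-s epoch.
   Streaming: ln(variance) of the trailing 30-s window, emitted every
   2 s (the biofeedback update interval; the 2-s step is the one timing
   constant fixed by the protocol, the 30-s window and epoch are package
   choices). Variance below 10⁻⁶ ms² is reported at the floor
   ln(10⁻⁶) ≈ −13.8 rather than −∞.

Values outside [0, 10] ln(ms²) are treated as artifact-driven outliers
and masked per value before any statistics; a record survives if any band
value remains valid.

**Oracle.** A sinusoidal IBI modulation of amplitude *A* ms has variance
*A*²/2, so an in-band tone must yield ln(*A*²/2). The test-suite asserts
this within ±0.1 ln-units at band centers, ±0.05 on the ln 4 shift under
amplitude doubling, and ≥2 ln-units of RSA-band attenuation for a 0.1-Hz
pacing tone whose wideband value stays within ±0.2 of the closed form.

## Sessions, meter, pacer, stressor

A session is an ordered list of half-open segments: `basic` = rest 180 s +
training 300 s; `training_game` = rest 180 s + stressor 240 s + recovery
180 s + training 300 s. Streaming records are tagged by the segment
containing their window-end time. Four arms: pacing 5 or 6 breaths/min ×
biofeedback on/off; HRV is computed identically in biofeedback-off arms
(only the display flag differs).

The meter calibrates on the current session's rest segment (mean μ, SD σ
of the wideband values after range filtering; calibrating on history was
the open alternative — current-session rest is the choice here because it
is what the rest segment exists to establish). The displayed meter is
clamp((v − (μ−2σ))/4σ, 0, 1), zoned red < 1/3 ≤ yellow < 2/3 ≤ green;
σ = 0 degenerates to a step at μ. The μ ± 2σ linear map and thirds zones
are package choices (only the calm-green/stress-red semantics are given);
all thresholds are parameters.

The pacer splits the non-pause part of each cycle so inhale/exhale equals
the 0.435 inspiration-to-expiration ratio, with 1.5-s end-inspiration and
end-expiration pauses: at 6 breaths/min, cycle 10 s = inhale 2.122 s +
pause 1.5 s + exhale 4.878 s + pause 1.5 s. Ramps are linear by default
(a raised-cosine easing is available; the timing invariants are shape-
independent). The synchronized audio tone is the same waveform mapped to
pitch, so no audio is synthesized.

The flanker stressor draws uniformly from the 4 stimulus combinations
(center × flanker direction), presents each for 400 ms, allows 2.7 s to
respond, and schedules the next onset a uniform 1–3 s after the response
window closes. Whether the inter-stimulus interval runs from stimulus
offset or window end is not fixed by the protocol; window-end is the
default (inter-onset 3.7–5.7 s, hence 42–64 trials in 240 s), switchable
via `isi_origin`. Responses before stimulus offset count; the schedule is
bit-reproducible from its seed.

## Protocol, incentives, compliance

Calendars are built deterministically from each participant's entry date
(day 0): baseline part 1 + one training-game practice on day 0, baseline
parts 2–3 on days 0–3, then weeks 1–6 (days 7(k−1)+1 … 7k) each with two
basic trainings, one training game and a weekly survey, quarterly surveys
plus practice in 30-day months 3/6/9, and a final survey in month 12.
Week and month boundaries are package conventions (the protocol table
does not define them). Incentives: $15, $5, $5 for the baseline parts,
$10 per compliant week, $20 per quarterly survey, $20 final. The weekly
criterion has a `strict` mode (both trainings + game + survey) and a
`relaxed` mode (an initiated survey suffices) because real deployments
relax mid-study. Incentive evaluation is idempotent (one entry per
participant × rule); the nightly fulfillment scan pays every earned,
unpaid entry exactly once. A weekly survey leaves the daily menu 4 days
after it is scheduled (visible on the scheduling day and the three
following days).

Compliance is completed/scheduled per activity window, as a percentage
rounded to one decimal, with scheduling adjusted to each participant's
start date (a window counts as scheduled once it has opened by the
analysis date). "Completing the regimen" is operationalized as ≥3
training sessions in each of weeks 1–6.

## Cohort statistics

Segment summaries are mean (SE) over pooled measures (multiple per
participant allowed — pooling ignores within-participant clustering,
which is a faithful replication of interim app-data practice and a known
limitation, not an endorsement). Sequential segment contrasts use the
unpaired Welch t test (the pooled-variance form is available by flag);
"unpaired t test" alone does not determine the variance assumption, and
Welch is the safer default under unequal segment variances. A one-way
fixed-effects ANOVA on segment label stands in for the general linear
model across segments. The test-suite verifies the Welch implementation
against a hand-computed statistic and calibrates its type-I error to
0.05 ± 0.01 over 10,000 null replicates.

## The synthetic generator

`synth_ibi` draws beats sequentially:

IBI_k = m + A_r sin(2π f_r s_k) + A_l sin(2π f_l s_k + φ) + ε_k,

with s_k the cumulative time, ε_k ~ N(0, σ²), and optional split (two
half-intervals) or merged (one doubled interval) beat artifacts at a
per-beat rate. The additive-sinusoid form was chosen over integral-pulse-
frequency modulation precisely because it has a closed-form band
variance (A²/2) for oracle testing; IPFM realism is a possible extension.
Defaults: mean IBI 1000 ms, respiration 0.25 Hz at 56.34 ms (placing the
resting wideband value at 7.37 ln ms²), LF 0.08 Hz at 15 ms, noise SD
5 ms, artifact rate 0 (0.02–0.05 in tests that exercise the cleaner).

Sessions apply per-segment multipliers to the base parameters, derived
from the amplitude↔ln-variance map (multiplier = exp(Δln/2)) so the four
segment set-points sit near 7.37 / 6.92 / 7.148 / 8.205 ln(ms²):
stressor ×0.80 on respiratory amplitude and ×0.93 on mean IBI (heart
rate up), recovery ×0.895, training ×1.518 with respiration moved to the
arm's pacing frequency. The cohort simulator gives every scheduled
activity in week k a completion probability p₀·decay^(k−1) (baseline
activities use their own probability), an optional forced completer
fraction, and a 60-day entry-date spread.

What the generator does **not** emulate: non-sinusoidal and drifting
respiration, IPFM point-process structure, circadian/posture effects,
motion-artifact bursts, or correlated adherence across activities.
Passing tests therefore demonstrate that the pipeline and protocol logic
are correct on data with known structure, not that real chest-strap
streams meet the same tolerances.

## Problem sizes and numerics

Tests and the acceptance script use 180–300-s series, 20-seed replicate
sets, cohorts of 20–328, and 10,000-replicate null calibrations — sizes
chosen so the whole suite completes in well under a minute of CPU while
leaving the statistical tolerances meaningful. Degenerate inputs are
defined rather than fatal wherever the protocol needs it: constant
series report the variance floor, σ = 0 calibrations step at the mean,
quality checks never raise, and an all-flagged series is the one
unrecoverable cleaning error.
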