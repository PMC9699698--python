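# Methods

## Task model and trial taxonomy

A session is a sequence of self-initiated trials. The *waiting time* of a
trial is the interval from the previous trial's port exit to the current
port entry; the first trial's reference exit is undefined, so its waiting
time is measured from session start and the trial is flagged and excluded
from all waiting-time analyses. Timing labels are assigned with closed
boundaries on the timely side: a wait exactly at the criterion (2.5 or 5 s)
is timely, and exactly at the cutoff (5 s, cutoff variant) is still timely.
A trial is `seq8` when it contains at least 8 licks — the 8th lick is the
event that can trigger reward, and licking continues afterwards on rewarded
trials, so a count threshold is the faithful reading of the task logic.
Rewarded implies timely and seq8; timely seq8 trials without reward are
`unrewarded`; everything else is outcome `none`.

Training stages: a session is *late* from the second of the first two
consecutive sessions reaching ≥ 80% timely-seq8 trials; the same number of
sessions from the start are *early* (truncated if fewer precede the late
block); the rest are *intermediate*.

## PETHs and normalization

Spike counts are binned at 80 ms in half-open bins `[a, b)`, with the
anchor at the left edge of the bin containing time 0. The bin-edge
convention is unstated in most descriptions of this procedure; half-open
right-assignment is the deterministic, testable default. Each unit's
normalization statistics — the per-bin mean μ and SD σ of spike counts —
are pooled over all ±20 s windows centered on port entries (windows
truncated by the session bounds are dropped from the statistics but their
trials are kept in PETHs, preserving trial counts for classification). All
z-scored traces of a unit, whatever their anchor, share these statistics,
so entry-, exit-, lick- and outcome-aligned values are on one scale per
unit. Lick PETHs use 10-ms bins z-scored against the whole session's
per-bin lick statistics. A 5-point centered moving average exists for
display only; no analysis path calls it.

## Unit classification

Every rule thresholds a windowed mean z:

| rule | anchor | window (ms) | threshold |
|---|---|---|---|
| entry | port entry | −640 … −80 | > 1 SD |
| exit | port exit | −240 … +320 | > 1 SD |
| lick | licks 1–8 | −200 … +200 | > 1 SD |
| cue | port entry | +160 … +400 | > 2 SD |
| inside port | port entry | +400 … +1520 | > 1 SD |
| tonic waiting | inter-trial intervals | whole waiting period | > 1 SD |
| outcome (i) | 8th lick | +160 … +560 vs −640 … −160 | > 0.5 SD |
| outcome (ii) | 8th lick | +160 … +560 | > 2 SD |

Entry/exit/cue/inside/lick rules are evaluated on timely trials (the cue
exists only there); the tonic rule uses all waiting periods; outcome rules
compare timely rewarded, timely unrewarded and premature seq8 conditions,
each requiring at least `min_trials = 10` trials (threshold rules on mean z
are unstable below that; units with fewer are reported undetermined with a
note). Outcome subtypes use 1.5 SD contrasts of the post-8th-lick window
between conditions, with premature-dominance checked first: a unit whose
premature response exceeds the rewarded one by > 1.5 SD *and* exceeds the
unrewarded response is *expected-no-reward*-responsive; otherwise a no-reward
condition exceeding rewarded by > 1.5 SD with unrewarded ≥ premature is
*no-reward*-responsive; a rewarded response exceeding both others by
> 1.5 SD is *reward*-responsive. The precedence is an operationalization —
the three phenotypes are described but no tie-break is stated — and only
matters when several contrasts hold at once. The discrimination index is
DI = |z(timely unrewarded) − z(premature)| on the outcome window.

**Tonic-waiting saturation.** The tonic rule compares waiting-period rate
against statistics that include the unit's own elevated waiting activity.
For a unit elevated by amplitude A during a fraction *p* of session time,
the achievable z is

    z = (1 − p)·A·Δ / sqrt((b + pA)·Δ + p(1 − p)·A²·Δ²) → sqrt((1 − p)/p)

as A → ∞ (Δ = bin width, b = baseline). With waiting occupying ~60% of the
cycle under default task timing the asymptote is ≈ 0.82 — *below* the 1 SD
threshold for any amplitude. Tonic units are therefore only detectable in
sessions where waiting is a small fraction of the cycle (p ≲ 0.3); the
recovery benchmark houses them in a premature-heavy, long-trial session
(p ≈ 0.2). This is a genuine property of the normalization, documented here
rather than worked around.

## Waiting-time modulation and logistic fits

Trials with waits ≤ 450 ms are excluded. Two fixed right-closed interval
schemes are provided (10 and 11 intervals; the 11-interval scheme refines
short waits), plus an equal-count quantile mode. The modulation curve takes,
per interval, the mean over entry-responsive units of the anticipatory-window
z computed from that interval's trials; the representative x is the median
waiting time of the interval's trials (geometric mean was the logged
alternative; the median is robust to the open-ended last interval).
Intervals contributing fewer than 3 trials in a session are skipped for
that session.

The logistic `y = p1/(1 + exp(−p2(x − p3)))` is fitted by least squares
with multistart (p2 ∈ {0.3, 1, 3}; p1 initialized at max(y); p3 at the
half-range crossing) because the SSE surface is multimodal in p2; p2 is
constrained positive by default (both the neural and behavioral curves are
increasing by construction). The 95% profile-likelihood CI on p2 is
`{p2*: SSE(p2*) ≤ SSE_min·(1 + F(0.95; 1, n−3)/(n−3))}` with p1, p3
re-optimized at each fixed p2*, bounds located by geometric expansion and
bisection; a side that never crosses the threshold within the search range
is flagged open. Groups are compared with the extra-sum-of-squares F test:
the null model shares p2 (5 parameters), the full model is two independent
fits (6 parameters), F = (SSE_null − SSE_full)/(SSE_full/(n_total − 6)).
With two 11-point curves the denominator df is 16.

**Known estimator bias (end-to-end).** For generator units whose bump
amplitude is A·L(w), the binned curve is c0 + c1·L(x) with a small negative
offset c0 (the unit's own bumps inflate the normalization mean) plus a
within-bin Jensen distortion (bins average L(w) but are placed at the median
w). Fitting the offset-free 3-parameter model to such data biases p2 upward
by roughly 10% at p2 ≈ 1. Consequently profile-CI coverage of the
*generator* slope holds at the curve level (data generated from the model
itself: measured 90–94% over 50 replicates) but not end-to-end once the CI
narrows; the end-to-end test asserts recovery within a 20% relative band
and monotonicity (steeper generators yield steeper fits) instead. The
behavioral ECDF fit has strongly correlated residuals, so its nominal CI
understates the estimator's replicate-to-replicate scatter; behavioral
recovery is likewise asserted as a relative band.

## Movement-onset detection

Each axis is band-passed 0.25–6 Hz with a 4th-order Butterworth applied
forward-backward — zero-phase filtering so onsets are not delayed by group
delay (phase handling is unstated in the source procedure; causal filtering
would bias onsets late). The Euclidean norm across axes is segmented into
10-sample windows stepped to 80-ms resolution (no overlap at 125 Hz, 80%
overlap at 25 Hz); windows with sample SD (ddof = 1) below 3.5 device units
are no-movement. The onset for a port entry is the start of the movement
run leading into the entry, with three operationalizations of the
stated-only-in-outline rule:

1. runs may bridge up to 2 consecutive sub-threshold windows — an 80-ms
   window of a ≤ 6 Hz band-limited signal holds ≈ 1 effective degree of
   freedom, so genuine movements show single-window SD dropouts;
2. with overlapping windows, the onset is stamped at the trailing step of
   the run's first window (an earlier movement start would have triggered
   the preceding window);
3. a run reaching back to the previous port exit yields no onset —
   continuous movement since the last trial has no initiation to time.

Onsets more than 1.2 s before entry are discarded, and only trials with
waits under 5 s are analyzed. On 125-Hz synthetic sessions the detector's
mean absolute error is ~0.06–0.07 s (one window step) with < 1% false
positives on burst-free noise; at 25 Hz the 0.36-s window span limits
absolute accuracy to ~0.1 s early bias even though the step resolution is
still 80 ms — the accuracy benchmark therefore uses the 125-Hz
configuration.

## Synthetic session generator

The generator defines the study conditions; defaults are fixed once:

- **Waiting times**: mixture of a premature log-normal (median ≈ 1.3 s,
  σ_log = 0.45, truncated below the criterion) with weight 0.3, and
  criterion + Gamma(k = 1.3, θ = 1.2 s) — premature and just-post-criterion
  peaks with a long right tail, the shape empirical waiting histograms show
  mid-training.
- **Licking**: first-lick latency ~ Gamma(mean 0.35 s); inter-lick
  intervals Gamma with mean 0.14 s and CV 0.15 (rodent lick rhythm ≈ 7 Hz;
  no magnitudes are reported for this task, so these are documented choices,
  not source facts). 75% of trials complete the 8-lick sequence; rewarded
  trials get ~12 extra licks vs ~3 on unrewarded ones (post-outcome licking
  diverges by outcome).
- **Reward**: balanced shuffled halves in blocks of two over timely seq8
  trials ("pseudo-random" rather than independent Bernoulli; stabilizes
  small-n tests). Cue 200 ms after timely entries.
- **Spikes**: each unit is an inhomogeneous Poisson process realized
  exactly by superposition — homogeneous baseline plus one Poisson-count
  Gaussian cloud per event-anchored bump, plus homogeneous inter-trial
  segments for tonic units. Entry-bump amplitudes are multiplied by
  logistic(w) of the trial's wait when waiting modulation is on. Peak rates
  above 500 Hz are a configuration error.
- **Amplitude calibration**: the builder solves for the bump amplitude whose
  *expected* detection-window z equals threshold + margin (default 1 SD),
  accounting for the unit's own inflation of the normalization statistics
  via a representative-cycle grid model (time-averaged bump rate, temporal
  rate variance, occurrence probabilities per trial type). Amplitudes are
  capped at 200 Hz; roles whose target is structurally unreachable under
  the session's timing (tonic, and the two-bump boundary units whose
  occupancy variance saturates the z) are capped with a logged warning.
- **Ground-truth category flags** follow from the generator's rate
  function, not the bare role name: lick-locked bumps genuinely elevate the
  inside-port window (licks happen inside the port) and an inside-port bump
  elevates the lick window, so those roles are positive for both categories
  — mirroring the overlapping category counts real data show.
- **Accelerometer**: white noise (SD 1) per axis; movement bursts are
  two-component 3–6 Hz sinusoids (amplitude 40) starting 0.4 s before each
  entry and around exits. Wide-band bursts would lose > 90% of their
  variance to the analysis band-pass; real head movements are in-band.

What the generator does *not* emulate: learning dynamics (stage labels come
from configuration, not an adapting agent), bursting/refractory spike
statistics (Poisson only), cross-unit correlations, electrode drift, and
body movements beyond the head-borne burst model. Passing recovery tests
therefore demonstrates the correctness of the analysis rules under the
stated statistical model, not robustness to every property of real
recordings.

## Problem sizes and numerics

Tests and the acceptance script run single-CPU in minutes: 120–300-trial
sessions, 20–200-unit populations, 50-replicate coverage/power simulations
on 11-point curves — sizes at which every targeted property (exact label
recovery, ≥ 0.9 sensitivity/specificity, ≥ 90% CI coverage, ≥ 90% power,
≤ 0.08 s onset MAE) is measurable with margin. Degenerate inputs are
explicit: silent units (σ = 0) are excluded with a logged reason,
constant-y or constant-x curves refuse to fit, zero-reward sessions report
infinite premature-per-reward ratios with a warning, duplicate spike times
within 1 µs are collapsed with a warning, and unpaired final entries are
dropped. Timestamps are serialized at microsecond precision; with a fixed
seed the full pipeline is byte-reproducible, which the suite asserts.
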