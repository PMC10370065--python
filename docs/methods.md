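# Methods

## Task and coordinate model

The simulated task is peripheral letter identification under crowding. Each
trial presents a trigram — a target letter flanked left and right by two
distinct letters, all drawn without replacement from the nine-letter Sloan
set DHKNORSVZ — for 150 ms, centered at −10 or +10 deg on the horizontal
meridian. Flankers sit radially, symmetric about the target, at a
center-to-center spacing controlled by the staircase; letter size is locked
to spacing at 1.4:1, so spacing is the only free stimulus variable. The
response (one of nine letters) is collected 700 ms after stimulus offset;
in simulation the response phase is instantaneous and response time is not
modeled.

Two coordinate systems are used. Screen coordinates are pixels, origin at
the display's upper-left corner, y down. Visual coordinates are degrees of
visual angle relative to the current crosshair center, y up. The default
degree→pixel mapping is linear with `px_per_deg = px_per_cm ·
viewing_distance_cm · tan(1°)` — exactly 60 px/deg for the default 40 cm
viewing distance — because at 10 deg eccentricity on such a display the
full tangent projection differs by only ~1%, and the linear constant is the
convention of the apparatus being modeled. A per-axis tangent mapping is
available behind `DisplayGeometry(tangent_mapping=True)` for larger
eccentricities.

## Fixation by cursor tracking

Instead of a static fixation mark, the crosshair orbits the screen center:
radius 0.5 deg, period 10 s (tangential speed 2π·0.5/10 ≈ 0.314 deg/s,
reported as 0.3), counterclockwise *as seen by the observer* (clockwise in
raw y-down pixel coordinates), starting each trial at a uniformly random
phase. The observer tracks its center with the cursor; tracking counts as
successful while the cursor tip lies in an invisible 0.1 deg-radius
hotspot, and the crosshair is drawn bold as feedback.

The pre-stimulus interval starts a timer when the cursor first enters the
hotspot, with a duration drawn uniformly from 0.75–1.25 s and quantized to
the nearest 60 Hz frame (the quantization convention is ours; the protocol
does not specify one). Two criteria are implemented:

* **endpoints** (default — the protocol under which the reference data were
  collected): the cursor is checked only when the timer starts and when it
  fires; mid-interval excursions are ignored.
* **continuous** (the later, stricter protocol): any frame outside the
  hotspot aborts the interval.

On failure the timer restarts at the next frame with the cursor inside the
hotspot, leaving the crosshair's motion undisturbed. A 60 s simulated-time
timeout guards against observers that can never satisfy the criterion (the
protocol itself specifies no limit). During the 150 ms stimulus the
crosshair and cursor are hidden; the target is anchored 10 deg from the
crosshair's position at fire time.

For comparison, the classic gaze-contingent mode ("awaited fixation") is
provided: a static crosshair, stimulus onset after 250 ms of continuous
gaze within 1.5 deg, rejection of trials in which gaze leaves 1.5 deg
during the stimulus, and a recalibration prompt if fixation takes more
than 10 s.

## Threshold estimation (QUEST)

The staircase maintains a discrete posterior over the log10 crowding
distance T on a fixed grid and is fully Bayesian: each trial is placed at
the posterior mean (the robust "mean" variant), and the final threshold is
the posterior mean after the last trial. The psychometric family is a
Weibull in log10 spacing x,

    Ψ(x | T) = δγ + (1 − δ)(1 − (1 − γ) exp(−10^{β(x − T + ε)})),

with guess rate γ = 1/9 (nine-alternative identification), lapse rate
δ = 0.01, steepness β = 2.3 (typical for letter identification), and ε
chosen in closed form so that Ψ(T | T) equals the criterion proportion
correct, 0.70, exactly. β, δ, the prior, and the estimator variant are
conventional defaults, all configurable: the source protocol does not
print them.

Numerical choices: grid from −1.5 to 1.5 log10 deg in 0.005 steps; Gaussian
prior (SD 2.0 log units, i.e. nearly flat over the presentable range)
centered on a 3 deg guess; posterior kept in log space and renormalized
with log-sum-exp after every update; proposals clamped to the presentable
spacing range [0.2, 12] deg rather than erroring. A standard condition uses
35 trials. Sanity properties verified by the tests: Ψ is monotone
nondecreasing in spacing, the posterior stays normalized to 1e−9 over a
session, and with 600 trials on a noiseless Weibull responder the mean
estimate is within 0.01 log units of the truth.

## The generative observer

The observer model produces everything the real apparatus logs.

* **Responses.** Correct with probability Ψ(log10 spacing | true T for that
  meridian); errors are uniform over the eight non-target letters.
* **Cursor.** The crosshair position delayed by `cursor_lag_s` (default
  50 ms) plus white isotropic Gaussian noise of 0.08/√2 deg per axis, so the
  radial tracking RMSE is 0.08 deg — the level skilled trackers reach. With
  the 0.1 deg hotspot this yields a realistic endpoint-check failure rate
  (~20% of trials see at least one timer restart).
* **Gaze.** Smooth pursuit of the crosshair delayed by `pursuit_lag_s`
  (default 100 ms — pursuit is known to lag its target; the exact lag is
  unreported, so a conventional latency is used), plus anisotropic Gaussian
  jitter, SD (0.45, 0.37) deg in (x, y). These defaults reproduce a typical
  observer's stimulus-epoch dispersion and give a pursuit RMS near 0.6 deg.
  Jitter is white per 10 ms sample by default — adequate because every
  downstream statistic consumes only positional deviations — with an
  optional AR(1) coefficient for autocorrelated noise.
* **Peeks.** With per-trial probability 0.05 (most observers peek rarely; a
  rare observer peeks often) a saccade lands at the target plus 1 deg
  Gaussian scatter 120 ms after stimulus onset and returns at offset.
  Saccades are instantaneous position jumps; no biomechanics are modeled.
* **Looking at nothing.** With probability 0.9 the gaze revisits the
  now-empty target location 150 ms after stimulus offset, producing the
  characteristic post-stimulus blow-up of horizontal gaze variance.
* **Calibration bias.** A constant per-session offset added to every gaze
  sample, default (0.5, −0.4) deg — 0.64 deg radial, the typical magnitude
  of tracker miscalibration in this setting.
* **Clocks.** The frame log ticks at 60 Hz and the gaze log every 10 ms
  (the rate at which the tracker stream is logged, not the tracker's native
  rate), both as absolute POSIX seconds from a shared origin, so the pre-
  onset 750 ms window always contains exactly 75 gaze samples.

A session is 140 trials: two blocks ("test", "retest"), each a random
interleave with exact counts (Fisher–Yates on a labeled sequence) of 35
trials per meridian; each block × meridian runs its own staircase.
`simulate_threshold_table` extends this to a cohort: each observer gets a
latent threshold (between-observer SD 0.2 log units, shared across
methods), a small per-meridian deviation (SD 0.05), and a practice effect
shrinking retest thresholds by ×0.8; methods add no systematic effect.
This reproduces the qualitative reliability structure of human cohorts —
test-retest SDs of order 0.1 log units, high cross-method correlations,
ICC near 1, null method ANOVA — though an ideal Weibull responder is less
variable than people (its Weibull-only paired-run SD is ≈0.04 log units;
attention lapses, fatigue, and criterion drift are not modeled).

### What the generator does not emulate

Oculomotor dynamics (saccade main-sequence, pursuit gain <1, catch-up
saccades), blinks and tracker dropout, pupil-size artifacts, head motion,
display latency jitter, and learning within a block. Passing tests
therefore certify the *analysis pipeline* — that it recovers what the
generator put in — and the internal consistency of the protocol, not that
human data would show those exact numbers.

## Gaze-validation pipeline

`merge_logs` joins each gaze sample to the nearest frame (tolerance 10 ms;
the 10 ms vs 16.7 ms grids guarantee a match within 8.4 ms when the clocks
agree), segments trials from runs of stimulus frames, and labels epochs:
pre = [onset − 0.75 s, onset), stimulus = [onset, offset), post = [offset,
offset + 0.55 s] (the post span is configurable; analyses of the original
recordings do not pin its exact end). Gaze is expressed in degrees relative
to the crosshair: linearly interpolated between frames during pre (error
< 1e−3 deg for a 0.3 deg/s trajectory; samples past the trial's final
crosshair frame clamp to it rather than bridging the hidden gap), and the
*last crosshair center* — its position on the final frame before onset —
during stimulus and post, since the crosshair is hidden from onset on.

The calibration offset is the mean gaze-minus-crosshair vector over all
pre-stimulus samples of a session (75 × n_trials when logs are complete),
estimated once per session and subtracted from every sample before any
downstream statistic; a flag disables the correction.

Radial RMSE takes the root-mean-square of radial distances within each
trial and averages across trials (a pooled-over-all-samples mode is
provided; the two agree for equal trial lengths). Tracking error pairs
cursor with crosshair on frames; pursuit error pairs gaze with crosshair
on gaze samples.

A **peek** is any stimulus-epoch gaze sample more than 1.5 deg (the
criterion used with gaze-contingent displays) from the last crosshair
center. Note the detector has a small false-positive rate under human-scale
jitter — with SD 0.45 deg, ~2–3% of non-peek trials contain a >1.5 deg
excursion by chance — which is a property of the criterion itself, not of
the implementation.

Per-epoch dispersion pools all samples of an epoch across trials and
reports the mean and SD of gaze in x and y; dispersion is computed after
offset correction (whether the original tables were computed before or
after correction is unstated; a flag allows skipping the correction).

## Problem sizes and determinism

Statistical tests run at sizes chosen so Monte-Carlo error is far below
the tolerances asserted: 200 staircases for threshold recovery, 20
injected offsets against a 3-standard-error budget that accounts for both
white jitter and the pursuit-lag bias (whose direction randomizes with the
trial's trajectory phase), full 140-trial sessions for dispersion and
sample-count checks, 100 cohort replicates for the ICC variance-components
check. All randomness flows from `numpy.random.Generator` objects seeded
explicitly; the same seed reproduces every CSV byte for byte.

## Known limitations

* The linear degree↔pixel mapping under-places stimuli by ~1% at 10 deg;
  the tangent mode exists but is not the default.
* Timer-restart semantics after a failed endpoint check (restart on the
  next in-hotspot frame) are one reasonable reading of an under-specified
  protocol step.
* The ICC form behind published single-number reliability coefficients is
  rarely stated; both ICC(2,1) and ICC(2,k) are reported, with ICC(2,1)
  (two-way random effects, absolute agreement, single measurement) as the
  default.
* Thresholds, not raw staircase posteriors, are what the statistics layer
  consumes; joint inference across sessions is out of scope.
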