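# Methods

This note documents the models, parameter choices, and numerical decisions
behind the package, and what the synthetic-data tests do and do not show.

## Experimental design generator

A session is 128 trials in 4 blocks of 32. Streams are 7 s of 50 ms tone
pips with 50 ms inter-tone intervals; the two ears' tone grids are offset
by half a slot (left ear on the 0.1 s grid, right ear 0.05 s later) so a
tone in one ear always falls in the other ear's silent interval. The
attended stream starts 1 s before the ignored stream. Frequencies come from
a 14-value pool, log-spaced from 445 to 2000 Hz (ratio (2000/445)^(1/13) ≈
1.1225, i.e. "12% steps"); every simultaneous left/right combination —
including pre- and post-step frequencies of STEP streams — must be at
least eight pool indices apart, enforced by internal resampling.

Per block: 8 trials carry the behavioral target event type (4 attended /
4 ignored) and the other 24 carry the task-irrelevant event in the
attended stream only, the ignored stream only, both, or neither (6 each,
giving the 24/24/24/24 session composition). Decisions where the design
was open:

- **Event times** are sampled uniformly over [2, 5] s after the containing
  stream's onset, quantized to that ear's tone grid — events are
  slot-aligned by construction of the stimulus. When both ears carry
  events, trial-absolute onsets must differ by ≥ 2 s (rejection sampling).
- **Ear assignment** is balanced exactly 16/16 within each block
  (counterbalanced reading of "quasi-random").
- **The 24/24/24/24 composition** is balanced 6/6/6/6 within blocks to
  avoid block-level confounds; only the session totals are externally
  constrained.
- **No audio is synthesized**: schedules carry all timing/frequency
  metadata; no analysis stage consumes waveforms.
- **Control epochs**: each no-event trial stores two dummy event times
  (one per ear role, drawn like a both-events trial), so the control
  condition yields 48 epochs per participant like the event conditions.

## Synthetic ocular data

The generator's defaults are the emulated study's conditions; they are not
tuning knobs.

**Microsaccade process.** Events are an inhomogeneous Poisson process
(thinning) with baseline 1.27 events/s. Each task-relevant or irrelevant
event adds a gamma-shaped rate dip with onset latency 0.07 s, trough
latency 0.27 s, and depth 0.68 (attended) / 0.52 (ignored) events/s
(0.80/0.61 for gap-evoked inhibition in Experiment 2). The dip is
depth·u^a·e^(a(1−u)) with u the time since dip onset in units of
(trough − onset); the exponent a is set in closed form so the dip decays to
10% of its depth `msi_recovery_time` = 0.4 s after the trough (full
recovery by ~0.7 s post-onset). A 50 ms refractory interval is enforced by
deletion; the thinning intensity is inflated by 1/(1 − rate·refractory) so
the *observable* post-deletion rate matches the requested profile (the
quoted rates are measured rates).

**Waveforms.** Each microsaccade is a conjugate horizontal minimum-jerk
displacement (amplitude lognormal, median 0.4°, clipped to 0.25–1°;
duration 12–25 ms; inter-eye onset disparity uniform 0–6 ms), with
direction biased back toward fixation. Background is shared slow drift
(0.12° SD, 0.2 s smoothing) plus 0.005° white noise per eye. These choices
put every rendered event above the λ = 6 detection threshold while keeping
the false-positive rate of the detector on event-free data near zero —
detection recovers ≈ 99–100% of injected events. Only horizontal dynamics
are modeled because detection uses horizontal velocity.

**Pupil.** Arbitrary-unit traces around 1500 with slow drift (SD 60 units,
8 s smoothing), hippus-like fluctuations (SD 8 units, 0.3 s smoothing),
and white measurement noise. Event-evoked component: a gamma dilation lobe
rising from 0.3 s after the event to its peak 0.45 s later, followed by a
constriction lobe that is zero until 0.6 s post-onset (so the dilation
peak latency is analytically exact at 0.75 s) and whose weight is scaled
by 1.5 for attended events. Amplitudes (0.15 attended / 0.07 ignored) are
expressed relative to the drift SD, so they survive block z-scoring
approximately unchanged. This reproduces the qualitative pattern the
analysis targets: a larger attended PDR around 0.5–0.9 s and a higher
attended constriction-event incidence in the post-peak window.

**Missing data.** Blinks (0.15/s, ~0.25 s), occasional long closures
(0.01/s, ~1.5 s) invalidating both eyes, and gaze excursions (0.02/s)
beyond the fixation box. At these rates roughly 1–2 of 48 epochs per
condition fail the > 50% missing rule, matching the emulated retention
(~45–47 valid trials per condition).

**Population and behavior.** Per-participant unit-mean lognormal
multipliers: CV 0.45 on the whole microsaccade rate profile (so dip depth
scales with baseline and the profile stays non-negative; the CV follows
from the emulated between-subject spread of the baseline rate) and CV 0.3
on pupil amplitudes. Targets are hit with probability 0.938 (RT lognormal,
median 0.85 s, truncated to the 2 s response window); ignored-stream
target-type events draw false alarms with probability 0.056. All
randomness flows from one seed via `numpy.random.SeedSequence` spawning,
so any participant regenerates in isolation.

**What the simulator does not emulate:** drift/tremor spectra of real
fixational data, vertical saccade components, pupil foreshortening,
luminance responses, serial dependence between trials, and any coupling
between microsaccades and pupil dynamics. Passing recovery tests therefore
demonstrates the *analysis machinery* is unbiased and calibrated on data
matching its assumptions — not that real recordings meet those assumptions.

## Analysis decisions

- **Velocity**: the canonical five-point central-difference stencil,
  v_n = (x_{n+2} + x_{n+1} − x_{n−1} − x_{n−2})·fs/6, zero at the two edge
  samples. The median-based SD is floored at 1e−6 °/s so constant traces
  cannot produce a zero threshold.
- **Duration rule**: a run of n samples has duration n/fs and both bounds
  are strict (5 ms < d < 100 ms), so at 1000 Hz a run needs ≥ 6 samples.
- **Binocular matching** is greedy by onset proximity (ties toward the
  earlier left-eye candidate), each monocular candidate used at most once;
  the merged event takes the earlier onset and later offset. The
  refractory rule discards any event starting ≤ 50 ms after the previously
  kept one. Events overlapping invalid samples are dropped.
- **Kernel**: ω(τ) = α²τe^(−ατ), sampled at 1000 Hz, truncated where the
  continuous kernel has all but 1e−8 of its mass, and normalized to unit
  sum so rates are in events/s. Its peak at τ = 1/α makes the 0.05 s shift
  exact for the default α = 1/50 ms. Epoch rate curves include events from
  the kernel's support before the window start, which removes the edge
  bias a per-epoch convolution would otherwise have near the window onset.
  Kernel smoothing attenuates a dip whose width is comparable to 1/α: with
  the default parameters the measured trough of a 0.68 events/s generative
  dip is ≈ 0.5 events/s. Reported troughs should be read accordingly.
- **Epoch windows**: QC and pupil preprocessing use the −0.2…+2 s epoch
  (2201 samples). The cluster statistic, however, needs a 2 s pre-onset
  control interval, so all statistical time series are computed on a wider
  −2…+2 s event-locked window cut from the continuous block traces (after
  block z-scoring and QC on the canonical window). Baseline correction
  always uses −0.2…0 s.
- **QC semantics**: thresholds are strict as printed (gaze > 2.56°/2.57°,
  missing > 50%); boundary cases are measure-zero. The right eye is
  analyzed where possible, falling back to the left eye when only the
  right fails the missing-data rule.
- **Interpolation**: scipy's PCHIP (monotone piecewise cubic) after
  epoching; interior gaps cannot overshoot their anchors, and edge gaps are
  held at the nearest valid value (PCHIP extrapolation is not shape-safe).
- **Pupil events**: the event timestamp is the extremum sample;
  "continued dilation/constriction" is non-strict monotonicity over the
  0.1 s persistence window (plateaus at machine precision do not break an
  event); endpoints never count. The Hanning window is symmetric,
  unit-sum, rounded to an odd sample count, with reflected edges.
- **Bootstrap**: one participant-resampling per iteration applied across
  all time points (preserving temporal dependence); "more than 95%" is
  strict, zero-valued means count as neither direction; clusters must
  strictly exceed the pre-onset threshold, which is computed per
  comparison.
- **Behavior**: press categories have precedence hit > (a) > (b) > (c)
  with earliest eligible event first and one press per event; exclusion is
  disjunctive (failing either the 70% hit or the 30% false-alarm criterion
  excludes, as does a baseline microsaccade rate below 0.25 events/s);
  d′ clamps extreme rates at 1/(2N). Trials containing a target-type event
  or any button press are excluded from all ocular analyses.

## Parameter recovery

`ocumsi.pipeline.msi_recovery_experiment` is the harness for recovery
checks at the study scale (24 participants × 48 epochs/condition,
simulation → detection → rate estimation). Two details matter:

- The baseline-rate check compares the recovered group rate against the
  *injected* rate (baseline × the realized participant multipliers), so it
  measures estimator bias rather than participant-sampling noise;
  agreement is within a few percent.
- The depth-difference sign check uses the paired within-participant
  contrast of *uncorrected* rates over the 0.1–0.5 s inhibition window.
  Both conditions share a participant's baseline, so the baseline cancels
  exactly in the pair; subtracting a separately estimated 0.2 s baseline
  would instead add the dominant share of the contrast's variance (the
  baseline window is only 0.2 s of data per epoch). The injected 0.16
  events/s difference is recovered with the correct sign in ≈ 96% of
  independent runs.

## Problem sizes and runtime

Defaults run comfortably on one CPU: the full 24-participant pipeline
takes ~20 s, the 50-replicate sign-recovery study ~2 minutes, and the
whole test suite a couple of minutes. The simulator generates each block
as one continuous array (10 s per trial segment), so memory stays below a
few hundred MB with participants processed one at a time.

## Known limitations

- Measured trough depths are kernel-attenuated (see above); the package
  reports observable quantities and does not deconvolve.
- The bootstrap cluster procedure controls noise via the pre-onset
  threshold heuristic, not a formal family-wise error rate; its observed
  symmetry and power properties are documented by the test suite.
- The detector's monocular candidates are horizontal-velocity only; 2-D
  velocity detection is out of scope.
- With a fully significant pre-onset control window the threshold equals
  the window length and no post-onset cluster can qualify — intended,
  degenerate-input behavior.
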