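"""Synthetic binocular gaze and pupil recordings with known ground truth.

The simulator emulates the ocular signatures the analysis targets:

* a baseline microsaccade incidence of ~1.27 events/s with an event-locked
  transient inhibition (MSI) whose depth depends on whether the evoking
  event sat in the attended (-0.68 events/s) or ignored (-0.52 events/s)
  stream, rendered as an inhomogeneous Poisson process (thinning) with a
  50 ms refractory interval;
* conjugate horizontal microsaccade waveforms (minimum-jerk displacement,
  0.012-0.025 s, inter-eye onset disparity below 0.01 s) on top of slow
  fixational drift and white measurement noise;
* an event-evoked pupil dilation (onset ~0.3 s) with a later constriction
  phase whose steepness is scaled for attended events, over slow pupil
  drift, hippus-like fluctuations, and measurement noise;
* blinks, longer eye closures, and gaze excursions outside the fixation
  box, producing realistic missing-data patterns;
* button presses for behavioral targets with configurable hit probability
  and reaction-time distribution.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning, so any participant is regenerable in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .design import SessionDesign, TrialSpec
from .recording import OcularRecording

#: simulated segment around each trial: 1 s lead-in before the attended
#: stream onset and enough tail for the widest event-locked window
TRIAL_LEAD = 1.0
TRIAL_SPAN = 10.0


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults are the emulated study's conditions."""

    sampling_rate: float = 1000.0
    # microsaccade process
    baseline_ms_rate: float = 1.27          # events/s
    msi_depth_attended: float = 0.68        # events/s below baseline
    msi_depth_ignored: float = 0.52
    msi_onset_latency: float = 0.07         # s after the evoking event
    msi_trough_latency: float = 0.27        # s after the evoking event
    msi_recovery_time: float = 0.4          # s from trough to 10% of depth
    ms_refractory: float = 0.05
    # microsaccade waveforms
    ms_amplitude_median: float = 0.4        # deg, lognormal
    ms_amplitude_sigma: float = 0.3
    ms_amplitude_clip: tuple = (0.25, 1.0)
    ms_duration_range: tuple = (0.012, 0.025)
    max_onset_disparity: float = 0.006      # s between the eyes
    # gaze background
    gaze_noise_sd: float = 0.005            # deg, white, per eye
    gaze_drift_sd: float = 0.12             # deg, shared slow drift
    gaze_drift_smooth: float = 0.2          # s, Gaussian smoothing
    # pupil
    pdr_amplitude_attended: float = 0.15    # ~z units (relative to drift SD)
    pdr_amplitude_ignored: float = 0.07
    pdr_latency: float = 0.3                # s, evoked-component onset
    pdr_rise_time: float = 0.45             # s from onset to dilation peak
    constriction_rate_gain_attended: float = 1.5
    pupil_base: float = 1500.0              # arbitrary units
    pupil_drift_sd: float = 60.0            # units; sets the z scale
    pupil_drift_smooth: float = 8.0         # s
    pupil_hippus_sd: float = 8.0            # units
    pupil_hippus_smooth: float = 0.3        # s
    pupil_noise_sd: float = 2.0             # units, per eye
    # missing data
    blink_rate: float = 0.15                # events/s
    blink_duration_mean: float = 0.25       # s, lognormal
    closure_rate: float = 0.01              # long eye closures
    closure_duration_mean: float = 1.5
    excursion_rate: float = 0.02            # gaze leaves the fixation box
    excursion_duration: float = 0.8
    # behavior
    hit_probability: float = 0.938
    fa_probability: float = 0.056
    rt_median: float = 0.85                 # s, lognormal
    rt_sigma: float = 0.3
    # population
    n_participants: int = 24
    between_subject_cv_rate: float = 0.45   # lognormal CV on the MS process
    between_subject_cv_amp: float = 0.3     # lognormal CV on pupil amplitudes
    rng_seed: int = 0

    def __post_init__(self):
        if self.baseline_ms_rate < 0:
            raise ValueError("rates must be non-negative")
        if max(self.msi_depth_attended, self.msi_depth_ignored) > self.baseline_ms_rate:
            raise ValueError("MSI depth exceeds the baseline rate (negative rate)")
        if self.sampling_rate != 1000.0:
            raise ValueError("the recording model is fixed at 1000 Hz")


# ---------------------------------------------------------------------------
# microsaccade rate process


def _dip_shape(params: SimParams) -> float:
    """Gamma-like dip exponent from the trough-to-recovery time.

    The dip is depth * u**a * exp(a * (1 - u)) with u the time since MSI
    onset in units of (trough - onset); ``a`` is chosen in closed form so
    the dip has decayed to 10% of its depth ``msi_recovery_time`` after the
    trough.
    """
    rise = params.msi_trough_latency - params.msi_onset_latency
    u_r = 1.0 + params.msi_recovery_time / rise
    return float(np.log(0.1) / (np.log(u_r) + 1.0 - u_r))


def ms_rate_profile(
    t: np.ndarray,
    events,
    params: SimParams,
    rate_multiplier: float = 1.0,
) -> np.ndarray:
    """Instantaneous microsaccade rate (events/s) over the grid ``t``.

    ``events`` is a sequence of (time, role) pairs with role "attended" or
    "ignored"; each contributes a smooth unimodal inhibition dip of the
    corresponding depth with the configured onset and trough latencies.
    With no events the profile is the constant baseline.
    """
    t = np.asarray(t, dtype=float)
    depth_of = {
        "attended": params.msi_depth_attended,
        "ignored": params.msi_depth_ignored,
    }
    profile = np.full_like(t, params.baseline_ms_rate)
    a = _dip_shape(params)
    rise = params.msi_trough_latency - params.msi_onset_latency
    # dips are negligible beyond ~6 rise times past the trough; restrict
    # the computation to that support for speed on long recordings
    support = params.msi_onset_latency + rise * 8.0
    for time, role in events:
        depth = depth_of[role]
        if depth > params.baseline_ms_rate:
            raise ValueError("MSI depth exceeds baseline: negative rate")
        lo = np.searchsorted(t, time + params.msi_onset_latency)
        hi = np.searchsorted(t, time + support)
        u = (t[lo:hi] - time - params.msi_onset_latency) / rise
        pos = u > 0
        profile[lo:hi][pos] -= depth * u[pos] ** a * np.exp(a * (1.0 - u[pos]))
    return np.clip(profile * rate_multiplier, 0.0, None)


def simulate_ms_times(
    t: np.ndarray,
    profile: np.ndarray,
    rng: np.random.Generator,
    refractory: float = 0.05,
    compensate: bool = True,
) -> np.ndarray:
    """Draw event times from an inhomogeneous Poisson profile by thinning.

    A refractory floor is enforced by deleting any event within
    ``refractory`` of the previously kept one. With ``compensate`` the
    thinning intensity is inflated by 1/(1 - rate * refractory) so the
    post-deletion (observable) rate matches the requested profile.
    """
    t = np.asarray(t, dtype=float)
    profile = np.asarray(profile, dtype=float)
    if (profile < 0).any():
        raise ValueError("rate profile must be non-negative")
    lam = profile.copy()
    if compensate and refractory > 0:
        dead = lam * refractory
        if (dead >= 0.9).any():
            raise ValueError("rate too high for the refractory correction")
        lam = lam / (1.0 - dead)
    lam_max = float(lam.max(initial=0.0))
    if lam_max == 0.0:
        return np.empty(0)
    span = t[-1] - t[0]
    n = rng.poisson(lam_max * span)
    times = np.sort(t[0] + rng.uniform(0.0, span, size=n))
    accept = rng.uniform(0.0, lam_max, size=n) < np.interp(times, t, lam)
    times = times[accept]
    kept = []
    last = -np.inf
    for time in times:
        if time - last > refractory:
            kept.append(time)
            last = time
    return np.asarray(kept)


# ---------------------------------------------------------------------------
# gaze rendering


def _min_jerk_displacement(n: int) -> np.ndarray:
    """Unit minimum-jerk position profile over n samples (0 -> 1)."""
    s = np.linspace(0.0, 1.0, n)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def _smoothed_noise(
    n: int, sd: float, smooth_s: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited Gaussian noise with the requested standard deviation.

    For long smoothing constants the noise is generated on a decimated
    grid, filtered there, and linearly upsampled — the result is band
    limited either way and the cost stays linear in the trace length.
    """
    sigma = smooth_s * fs
    step = max(int(sigma // 8), 1)
    if step > 1:
        m = n // step + 3
        raw = gaussian_filter1d(rng.standard_normal(m), sigma / step, mode="reflect")
        out = np.interp(np.arange(n), np.arange(m) * step, raw)
    else:
        out = gaussian_filter1d(rng.standard_normal(n), sigma, mode="reflect")
    scale = out.std()
    return out * (sd / scale) if scale > 0 else out


def inject_saccade_waveforms(
    ms_times: np.ndarray,
    n_samples: int,
    params: SimParams,
    rng: np.random.Generator,
    t0: float = 0.0,
):
    """Render binocular horizontal gaze traces containing the given events.

    Each microsaccade is a conjugate horizontal minimum-jerk displacement
    present in both eyes with a small onset disparity; the background is
    shared fixational drift plus per-eye white noise. Returns
    ``(xl, xr, truth)`` where truth lists per-event amplitude, duration and
    rendered disparity.
    """
    fs = params.sampling_rate
    # accumulate per-sample displacement increments and integrate once at
    # the end, so each event costs O(duration) rather than O(recording)
    increments = {"left": np.zeros(n_samples), "right": np.zeros(n_samples)}
    offset = 0.0
    truth = []
    for time in np.sort(np.asarray(ms_times, dtype=float)):
        amp = float(
            np.clip(
                params.ms_amplitude_median
                * np.exp(params.ms_amplitude_sigma * rng.standard_normal()),
                *params.ms_amplitude_clip,
            )
        )
        # bias direction back toward fixation so gaze stays in the box
        if abs(offset) > 0.5:
            sign = -np.sign(offset)
        else:
            sign = rng.choice([-1.0, 1.0])
        dur = float(rng.uniform(*params.ms_duration_range))
        n_dur = max(int(round(dur * fs)), 4)
        disparity = float(rng.uniform(0.0, params.max_onset_disparity))
        lagged_eye = rng.choice(["left", "right"])
        onsets = {"left": time, "right": time}
        onsets[lagged_eye] += disparity
        ok = True
        for eye in ("left", "right"):
            i0 = int(round((onsets[eye] - t0) * fs))
            if i0 < 0 or i0 + n_dur > n_samples:
                ok = False
        if not ok:
            continue
        dwave = sign * amp * np.diff(_min_jerk_displacement(n_dur))
        for eye in ("left", "right"):
            i0 = int(round((onsets[eye] - t0) * fs))
            increments[eye][i0 + 1 : i0 + n_dur] += dwave
        offset += sign * amp
        truth.append(
            {
                "onset": time,
                "amplitude": amp,
                "duration": dur,
                "disparity": disparity,
            }
        )
    drift = _smoothed_noise(
        n_samples, params.gaze_drift_sd, params.gaze_drift_smooth, fs, rng
    )
    noise = params.gaze_noise_sd
    xl = np.cumsum(increments["left"]) + drift + noise * rng.standard_normal(n_samples)
    xr = np.cumsum(increments["right"]) + drift + noise * rng.standard_normal(n_samples)
    return xl, xr, truth


# ---------------------------------------------------------------------------
# pupil rendering


def evoked_pupil_kernel(
    tau: np.ndarray, amplitude: float, constriction_gain: float, params: SimParams
) -> np.ndarray:
    """Event-evoked pupil component (z-ish units) at lags ``tau``.

    A gamma-shaped dilation lobe rising from ``pdr_latency`` to its peak
    ``pdr_rise_time`` later, followed by a constriction lobe (zero until
    0.6 s after onset, so the dilation peak latency is exact) whose weight
    is scaled by ``constriction_gain``.
    """
    tau = np.asarray(tau, dtype=float)
    x = tau - params.pdr_latency
    out = np.zeros_like(tau)
    rising = x > 0
    u = x[rising] / params.pdr_rise_time
    out[rising] = u**3 * np.exp(3.0 * (1.0 - u))
    v = (x - 0.6) / 0.5
    late = v > 0
    out[late] -= 0.5 * constriction_gain * v[late] ** 2 * np.exp(2.0 * (1.0 - v[late]))
    return amplitude * out


def evoked_peak_latency(params: SimParams) -> float:
    """Analytic latency of the evoked dilation peak after event onset."""
    return params.pdr_latency + params.pdr_rise_time


def simulate_pupil(
    n_samples: int,
    events,
    params: SimParams,
    rng: np.random.Generator,
    t0: float = 0.0,
    amp_multiplier: float = 1.0,
):
    """Simulate a pupil trace (arbitrary units) plus evoked ground truth.

    ``events`` is a sequence of (time, role) pairs; attended events get the
    larger dilation amplitude and the constriction gain. The trace is slow
    drift + hippus-like fluctuations + evoked components + white noise
    around ``pupil_base``; amplitudes are expressed relative to the drift
    SD so they survive block z-scoring roughly unchanged.
    """
    fs = params.sampling_rate
    t = t0 + np.arange(n_samples) / fs
    amp_of = {
        "attended": params.pdr_amplitude_attended,
        "ignored": params.pdr_amplitude_ignored,
    }
    gain_of = {
        "attended": params.constriction_rate_gain_attended,
        "ignored": 1.0,
    }
    trace = params.pupil_base + _smoothed_noise(
        n_samples, params.pupil_drift_sd, params.pupil_drift_smooth, fs, rng
    )
    trace += _smoothed_noise(
        n_samples, params.pupil_hippus_sd, params.pupil_hippus_smooth, fs, rng
    )
    truth = []
    # the evoked kernel is negligible past ~5 s; add it on a local slice
    support = params.pdr_latency + 5.0
    for time, role in events:
        amp = amp_of[role] * amp_multiplier
        lo = max(int(round((time - t0) * fs)), 0)
        hi = min(int(round((time - t0 + support) * fs)), n_samples)
        kernel = evoked_pupil_kernel(t[lo:hi] - time, amp, gain_of[role], params)
        trace[lo:hi] += params.pupil_drift_sd * kernel
        truth.append(
            {
                "onset": time,
                "role": role,
                "amplitude": amp,
                "peak_time": time + evoked_peak_latency(params),
            }
        )
    return trace, truth


# ---------------------------------------------------------------------------
# missing data


def _poisson_intervals(
    duration: float,
    rate: float,
    mean_len: float,
    rng: np.random.Generator,
    lognormal_sigma: float = 0.4,
) -> list:
    """Random (start, stop) intervals from a Poisson onset process."""
    if rate <= 0:
        return []
    n = rng.poisson(rate * duration)
    starts = np.sort(rng.uniform(0.0, duration, size=n))
    mu = np.log(mean_len) - 0.5 * lognormal_sigma**2
    lengths = np.exp(mu + lognormal_sigma * rng.standard_normal(n))
    return [(float(s), float(min(s + l, duration))) for s, l in zip(starts, lengths)]


def inject_blinks_and_excursions(
    rec: OcularRecording, params: SimParams, rng: np.random.Generator
):
    """Mark blink/closure intervals missing and add gaze excursions.

    Blinks and longer closures invalidate both eyes (pupil set to missing);
    excursions displace gaze beyond the fixation box without touching the
    validity flags — downstream QC is expected to catch them. Returns the
    modified recording and the list of injected missing intervals.
    """
    fs = rec.sampling_rate
    duration = len(rec) / fs
    t_start = float(rec.t[0])
    blink_like = _poisson_intervals(
        duration, params.blink_rate, params.blink_duration_mean, rng
    ) + _poisson_intervals(
        duration, params.closure_rate, params.closure_duration_mean, rng
    )
    for start, stop in blink_like:
        i0, i1 = int(start * fs), int(stop * fs) + 1
        rec.lvalid[i0:i1] = False
        rec.rvalid[i0:i1] = False
        rec.lp[i0:i1] = np.nan
        rec.rp[i0:i1] = np.nan
    for start, stop in _poisson_intervals(
        duration, params.excursion_rate, params.excursion_duration, rng,
        lognormal_sigma=0.1,
    ):
        i0, i1 = int(start * fs), int(stop * fs) + 1
        shift = rng.choice([-1.0, 1.0]) * rng.uniform(3.0, 5.0)
        rec.lx[i0:i1] += shift
        rec.rx[i0:i1] += shift
    intervals = [(t_start + s, t_start + e) for s, e in blink_like]
    return rec, intervals


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class ParticipantData:
    """One simulated participant: recordings, presses, and ground truth."""

    participant: int
    recordings: list                      # one OcularRecording per block
    trial_onsets: dict                    # block -> array of onsets (s)
    presses: list                         # (trial_index, time rel. trial onset)
    ground_truth: dict
    rate_multiplier: float
    amp_multiplier: float


def trial_events_with_roles(trial: TrialSpec) -> list:
    """All (trial-absolute time, role) events of a trial, both types."""
    events = []
    for event_type in ("step", "gap"):
        for ear, time in trial.events_abs(event_type):
            events.append((time, trial.ear_role(ear)))
    return sorted(events)


def _lognormal_multiplier(cv: float, rng: np.random.Generator) -> float:
    """Unit-mean lognormal draw with the requested coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma2 = np.log(1.0 + cv**2)
    return float(np.exp(rng.standard_normal() * np.sqrt(sigma2) - sigma2 / 2.0))


def generate_participant(
    design: SessionDesign,
    params: SimParams,
    participant: int,
    seed_seq: np.random.SeedSequence,
) -> ParticipantData:
    """Simulate one participant's full session.

    Each block is a continuous recording in which trial segments start
    every ``TRIAL_SPAN`` seconds with a ``TRIAL_LEAD`` lead-in. Microsaccade
    and pupil processes receive the trial's events (task-relevant and
    irrelevant alike, with attended/ignored roles by ear); control trials
    carry no evoked component.
    """
    rng = np.random.default_rng(seed_seq)
    fs = params.sampling_rate
    rate_mult = _lognormal_multiplier(params.between_subject_cv_rate, rng)
    amp_mult = _lognormal_multiplier(params.between_subject_cv_amp, rng)

    recordings = []
    trial_onsets: dict = {}
    ms_truth: dict = {}
    pupil_truth: dict = {}
    blink_truth: dict = {}
    presses: list = []
    blocks = sorted({t.block_index for t in design.trials})
    for b in blocks:
        trials = design.block_trials(b)
        n_samples = int(round(len(trials) * TRIAL_SPAN * fs))
        t = np.arange(n_samples) / fs
        onsets = TRIAL_LEAD + TRIAL_SPAN * np.arange(len(trials))
        trial_onsets[b] = {
            trial.trial_index: float(onset) for trial, onset in zip(trials, onsets)
        }
        events = []
        for trial, onset in zip(trials, onsets):
            events.extend(
                (onset + time, role) for time, role in trial_events_with_roles(trial)
            )
        profile = ms_rate_profile(t, events, params, rate_multiplier=rate_mult)
        ms_times = simulate_ms_times(t, profile, rng, refractory=params.ms_refractory)
        xl, xr, wave_truth = inject_saccade_waveforms(ms_times, n_samples, params, rng)
        rendered = np.asarray([w["onset"] for w in wave_truth])
        yl = _smoothed_noise(
            n_samples, params.gaze_drift_sd, params.gaze_drift_smooth, fs, rng
        ) + params.gaze_noise_sd * rng.standard_normal(n_samples)
        yr = yl + params.gaze_noise_sd * rng.standard_normal(n_samples)
        pupil, evoked = simulate_pupil(
            n_samples, events, params, rng, amp_multiplier=amp_mult
        )
        lp = pupil + params.pupil_noise_sd * rng.standard_normal(n_samples)
        rp = pupil + params.pupil_noise_sd * rng.standard_normal(n_samples)
        rec = OcularRecording(
            t=t,
            lx=xl, ly=yl, rx=xr, ry=yr,
            lp=lp, rp=rp,
            lvalid=np.ones(n_samples, dtype=bool),
            rvalid=np.ones(n_samples, dtype=bool),
            block=np.full(n_samples, b, dtype=int),
        )
        rec, blink_intervals = inject_blinks_and_excursions(rec, params, rng)
        recordings.append(rec)
        ms_truth[b] = rendered
        pupil_truth[b] = evoked
        blink_truth[b] = blink_intervals
        # behavior
        for trial in trials:
            targets = trial.events_abs(trial.target_type)
            for ear, time in targets:
                role = trial.ear_role(ear)
                if role == "attended" and rng.uniform() < params.hit_probability:
                    rt = _truncated_rt(params, rng)
                    presses.append((trial.trial_index, time + rt))
                elif role == "ignored" and rng.uniform() < params.fa_probability:
                    rt = _truncated_rt(params, rng)
                    presses.append((trial.trial_index, time + rt))
    return ParticipantData(
        participant=participant,
        recordings=recordings,
        trial_onsets=trial_onsets,
        presses=presses,
        ground_truth={
            "ms_times": ms_truth,
            "pupil_events": pupil_truth,
            "blink_intervals": blink_truth,
        },
        rate_multiplier=rate_mult,
        amp_multiplier=amp_mult,
    )


def _truncated_rt(params: SimParams, rng: np.random.Generator) -> float:
    """Lognormal reaction time truncated to the 2 s response window."""
    for _ in range(100):
        rt = params.rt_median * np.exp(params.rt_sigma * rng.standard_normal())
        if 0.1 < rt < 2.0:
            return float(rt)
    return 1.0


def generate_dataset(
    design: SessionDesign, params: SimParams, rng_seed: int | None = None
) -> list:
    """Simulate all participants (deterministic given the seed)."""
    seed = params.rng_seed if rng_seed is None else rng_seed
    children = np.random.SeedSequence(seed).spawn(params.n_participants)
    return [
        generate_participant(design, params, pid, child)
        for pid, child in enumerate(children)
    ]
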