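"""Microsaccade detection and rate estimation.

Detection follows the classic binocular velocity-threshold algorithm:
horizontal gaze velocity (5-point central difference) is thresholded at
lambda = 6 times a median-based standard deviation computed per eye per
block; supra-threshold runs lasting more than 5 ms and less than 100 ms are
candidate monocular events; candidates are kept when detected in both eyes
with onset disparity below 10 ms, and successive events closer than 50 ms
are collapsed to the first.

Rates are estimated by convolving event-onset impulse trains with a causal
kernel w(tau) = alpha^2 tau exp(-alpha tau) (unit integral, peak at
tau = 1/alpha), shifting the curve earlier by the kernel's 50 ms peak lag,
averaging across epochs then participants, and subtracting the mean over
the 0.2 s pre-event baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VELOCITY_SD_FLOOR = 1e-6  # deg/s; guards degenerate (constant) traces


@dataclass(frozen=True)
class DetectionParams:
    lam: float = 6.0
    min_duration: float = 0.005
    max_duration: float = 0.1
    max_binocular_disparity: float = 0.01
    min_inter_ms_interval: float = 0.05

    def __post_init__(self):
        if min(self.lam, self.min_duration, self.max_duration,
               self.max_binocular_disparity, self.min_inter_ms_interval) <= 0:
            raise ValueError("detection parameters must be positive")
        if self.min_duration >= self.max_duration:
            raise ValueError("min_duration must be below max_duration")


@dataclass(frozen=True)
class MicrosaccadeEvent:
    onset: float
    offset: float
    onset_left: float
    onset_right: float
    peak_velocity: float
    amplitude: float = np.nan

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def disparity(self) -> float:
        return abs(self.onset_left - self.onset_right)


@dataclass(frozen=True)
class Candidate:
    """Monocular supra-threshold run (sample indices are inclusive)."""

    onset_idx: int
    offset_idx: int
    onset: float
    offset: float
    peak_velocity: float


def compute_velocity(x: np.ndarray, sampling_rate: float) -> np.ndarray:
    """5-point central-difference velocity; the two edge samples are zero.

    v[n] = (x[n+2] + x[n+1] - x[n-1] - x[n-2]) * fs / 6
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 samples to compute velocity")
    v = np.zeros_like(x)
    v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) * (sampling_rate / 6.0)
    return v


def median_based_sd(v: np.ndarray) -> float:
    """Robust spread sqrt(median(v^2) - median(v)^2), floored above zero."""
    v = np.asarray(v, dtype=float)
    var = float(np.median(v**2) - np.median(v) ** 2)
    return max(np.sqrt(max(var, 0.0)), VELOCITY_SD_FLOOR)


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs; stop is inclusive."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[::2], idx[1::2] - 1))


def detect_monocular(
    v: np.ndarray,
    params: DetectionParams,
    sd: float,
    sampling_rate: float,
    t0: float = 0.0,
) -> list[Candidate]:
    """Supra-threshold velocity runs with admissible duration.

    Duration is the run length in samples over the sampling rate; the
    bounds are strict on both sides (0.005 s < d < 0.1 s).
    """
    mask = np.abs(v) > params.lam * sd
    out = []
    for start, stop in _runs(mask):
        d = (stop - start + 1) / sampling_rate
        if params.min_duration < d < params.max_duration:
            out.append(
                Candidate(
                    onset_idx=int(start),
                    offset_idx=int(stop),
                    onset=t0 + start / sampling_rate,
                    offset=t0 + stop / sampling_rate,
                    peak_velocity=float(np.max(np.abs(v[start : stop + 1]))),
                )
            )
    return out


def binocular_match(
    left: list[Candidate],
    right: list[Candidate],
    params: DetectionParams,
) -> list[MicrosaccadeEvent]:
    """Pair monocular candidates across eyes and enforce the refractory rule.

    Greedy matching by onset proximity (each candidate used at most once;
    ties broken toward the earlier left-eye candidate). A matched event
    takes the earlier onset and the later offset. Events whose onset
    follows the previous kept event by 0.05 s or less are discarded.
    """
    r_onsets = np.asarray([r.onset for r in right])
    order = np.argsort(r_onsets, kind="stable")
    r_sorted = r_onsets[order]
    pairs = []
    for i, l in enumerate(left):
        lo = np.searchsorted(r_sorted, l.onset - params.max_binocular_disparity)
        hi = np.searchsorted(r_sorted, l.onset + params.max_binocular_disparity)
        for k in range(lo, hi):
            j = int(order[k])
            d = abs(l.onset - right[j].onset)
            if d < params.max_binocular_disparity:
                pairs.append((d, l.onset, i, j))
    pairs.sort()
    used_l: set = set()
    used_r: set = set()
    events = []
    for _, _, i, j in pairs:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        l, r = left[i], right[j]
        events.append(
            MicrosaccadeEvent(
                onset=min(l.onset, r.onset),
                offset=max(l.offset, r.offset),
                onset_left=l.onset,
                onset_right=r.onset,
                peak_velocity=max(l.peak_velocity, r.peak_velocity),
            )
        )
    events.sort(key=lambda e: e.onset)
    kept: list[MicrosaccadeEvent] = []
    for ev in events:
        if kept and ev.onset - kept[-1].onset <= params.min_inter_ms_interval:
            continue
        kept.append(ev)
    return kept


def detect_binocular(
    xl: np.ndarray,
    xr: np.ndarray,
    sampling_rate: float,
    params: DetectionParams = DetectionParams(),
    t0: float = 0.0,
    valid: np.ndarray | None = None,
    sd_left: float | None = None,
    sd_right: float | None = None,
) -> list[MicrosaccadeEvent]:
    """Full detection on one pair of horizontal traces.

    ``sd_left``/``sd_right`` allow thresholds computed over a larger scope
    (the per-block rule) to be supplied; otherwise they are computed from
    the given traces. Events overlapping invalid samples are dropped.
    """
    vl = compute_velocity(xl, sampling_rate)
    vr = compute_velocity(xr, sampling_rate)
    sd_l = median_based_sd(vl) if sd_left is None else sd_left
    sd_r = median_based_sd(vr) if sd_right is None else sd_right
    cand_l = detect_monocular(vl, params, sd_l, sampling_rate, t0)
    cand_r = detect_monocular(vr, params, sd_r, sampling_rate, t0)
    events = binocular_match(cand_l, cand_r, params)
    if valid is not None:
        events = [
            ev
            for ev in events
            if valid[
                int(round((ev.onset - t0) * sampling_rate)) :
                int(round((ev.offset - t0) * sampling_rate)) + 1
            ].all()
        ]
    # amplitude: horizontal displacement over the event, averaged over eyes
    out = []
    for ev in events:
        i0 = int(round((ev.onset - t0) * sampling_rate))
        i1 = int(round((ev.offset - t0) * sampling_rate))
        amp = 0.5 * (abs(xl[i1] - xl[i0]) + abs(xr[i1] - xr[i0]))
        out.append(
            MicrosaccadeEvent(
                onset=ev.onset,
                offset=ev.offset,
                onset_left=ev.onset_left,
                onset_right=ev.onset_right,
                peak_velocity=ev.peak_velocity,
                amplitude=float(amp),
            )
        )
    return out


def detect(recording, params: DetectionParams = DetectionParams()):
    """Detect microsaccades in a recording, block by block.

    The velocity threshold is computed per eye over all samples of each
    block. Returns a flat, time-sorted list of events (onsets in recording
    time).
    """
    fs = recording.sampling_rate
    events = []
    for b in recording.blocks():
        sl = recording.block_slice(b)
        xl, xr = recording.lx[sl], recording.rx[sl]
        valid = recording.lvalid[sl] & recording.rvalid[sl]
        events.extend(
            detect_binocular(
                xl, xr, fs, params, t0=float(recording.t[sl][0]), valid=valid
            )
        )
    events.sort(key=lambda e: e.onset)
    return events


# ---------------------------------------------------------------------------
# rate estimation


@dataclass(frozen=True)
class KernelParams:
    """Causal rate kernel w(tau) = alpha^2 tau exp(-alpha tau).

    The default decay parameter alpha = 1/50 ms puts the kernel's peak —
    and hence the compensating shift — at 0.05 s. Alternates alpha = 1/10
    and 1/100 ms are used for robustness checks.
    """

    alpha: float = 1.0 / 0.05
    shift: float | None = None          # None -> 1/alpha (the kernel peak)
    baseline_window: float = 0.2

    @property
    def effective_shift(self) -> float:
        return 1.0 / self.alpha if self.shift is None else self.shift


def rate_kernel(alpha: float, sampling_rate: float) -> np.ndarray:
    """Sampled causal kernel, normalized to unit sum (unit time integral).

    Support is truncated where the continuous kernel has accumulated all
    but 1e-8 of its mass.
    """
    # (1 + a t) exp(-a t) = 1e-8  ->  a t ~= 21.4; round up generously
    n = int(np.ceil(25.0 / alpha * sampling_rate)) + 1
    tau = np.arange(n) / sampling_rate
    w = alpha**2 * tau * np.exp(-alpha * tau)
    return w / w.sum()


@dataclass
class RateSeries:
    """Event-incidence time series on a uniform event-locked grid."""

    t: np.ndarray
    rate: np.ndarray
    baseline_corrected: bool
    n_epochs: int
    per_participant: np.ndarray | None = None   # (n_participants, n_time)


def _epoch_rate(
    event_times: list,
    window: tuple,
    kernel: KernelParams,
    sampling_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean rate across epochs for one participant.

    ``event_times`` is a sequence of per-epoch arrays of event onsets in
    seconds relative to the epoch's alignment event. Events earlier than
    the window start (up to the kernel support) contribute through the
    causal kernel, so callers should include them where available.
    """
    if len(event_times) == 0:
        raise ValueError("at least one epoch is required")
    w = rate_kernel(kernel.alpha, sampling_rate)
    shift_n = int(round(kernel.effective_shift * sampling_rate))
    pre_pad = len(w)                    # causal kernel support before window
    post_pad = shift_n                  # the shift reads this far forward
    n_out = int(round((window[1] - window[0]) * sampling_rate)) + 1
    t = window[0] + np.arange(n_out) / sampling_rate
    grid_n = pre_pad + n_out + post_pad
    counts = np.zeros(grid_n)
    t_grid0 = window[0] - pre_pad / sampling_rate
    for times in event_times:
        times = np.asarray(times, dtype=float)
        idx = np.round((times - t_grid0) * sampling_rate).astype(int)
        idx = idx[(idx >= 0) & (idx < grid_n)]
        np.add.at(counts, idx, 1.0)
    smoothed = np.convolve(counts, w)[:grid_n] * sampling_rate
    # shift earlier by the kernel peak lag, then crop the pads
    rate = smoothed[pre_pad + shift_n : pre_pad + shift_n + n_out]
    return t, rate / len(event_times)


def ms_rate(
    events_by_participant,
    window: tuple = (-0.2, 2.0),
    kernel: KernelParams = KernelParams(),
    sampling_rate: float = 1000.0,
    baseline_corrected: bool = True,
) -> RateSeries:
    """Kernel-smoothed event rate, averaged across epochs then participants.

    ``events_by_participant`` is a sequence over participants, each a
    sequence over epochs of event-onset arrays (seconds relative to the
    epoch event). Baseline correction subtracts each participant's mean
    rate over the 0.2 s pre-event interval.
    """
    if len(events_by_participant) == 0:
        raise ValueError("no participants")
    per = []
    n_epochs = 0
    for epochs in events_by_participant:
        t, rate = _epoch_rate(epochs, window, kernel, sampling_rate)
        n_epochs += len(epochs)
        if baseline_corrected:
            base = (t >= -kernel.baseline_window) & (t < 0)
            if not base.any():
                raise ValueError("window does not cover the baseline interval")
            rate = rate - rate[base].mean()
        per.append(rate)
    per = np.asarray(per)
    return RateSeries(
        t=t,
        rate=per.mean(axis=0),
        baseline_corrected=baseline_corrected,
        n_epochs=n_epochs,
        per_participant=per,
    )
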