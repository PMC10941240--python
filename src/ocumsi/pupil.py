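"""Pupil preprocessing, evoked responses, and dilation/constriction events.

Pupil traces are z-scored per participant per block (mean and SD over all
valid samples of the block), baseline-corrected against the pre-onset mean,
and smoothed with a 0.15 s Hanning window. Dilation (constriction) events
are local minima (maxima) of the smoothed trace followed by at least 0.1 s
of continued non-decreasing (non-increasing) signal; their incidence rate
uses the same causal-kernel machinery as the microsaccade rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .microsaccade import KernelParams, RateSeries, ms_rate


@dataclass(frozen=True)
class PupilPreprocParams:
    smoothing_window: float = 0.15      # s, Hanning
    baseline_window: float = 0.2        # s pre-onset mean subtracted

    def __post_init__(self):
        if self.smoothing_window <= 0:
            raise ValueError("smoothing window must be positive")


@dataclass(frozen=True)
class PupilEventParams:
    min_persistence: float = 0.1        # s of continued dilation/constriction
    event_smoothing: float = 0.15       # s, Hanning, applied before extrema

    def __post_init__(self):
        if self.min_persistence <= 0:
            raise ValueError("min_persistence must be positive")


def hanning_window(duration: float, sampling_rate: float) -> np.ndarray:
    """Symmetric unit-sum Hanning window, nearest odd sample count."""
    n = int(round(duration * sampling_rate))
    if n % 2 == 0:
        n += 1
    n = max(n, 3)
    w = np.hanning(n)
    return w / w.sum()


def smooth(trace: np.ndarray, duration: float, sampling_rate: float) -> np.ndarray:
    """Hanning smoothing with reflected edges (mean-preserving window)."""
    w = hanning_window(duration, sampling_rate)
    half = len(w) // 2
    padded = np.concatenate(
        [trace[half:0:-1], trace, trace[-2 : -half - 2 : -1]]
    )
    return np.convolve(padded, w, mode="valid")


def zscore_block(values: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Z-score a block's samples by its own (valid-sample) mean and SD.

    Missing samples (NaN or flagged invalid) do not enter the statistics
    and stay missing in the output.
    """
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values)
    if valid is not None:
        mask &= np.asarray(valid, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("block needs at least two valid samples")
    mu = values[mask].mean()
    sd = values[mask].std()
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("degenerate block: zero spread across valid samples")
    out = (values - mu) / sd
    out[~np.isfinite(values)] = np.nan
    return out


def evoked_pdr(
    epochs_by_participant,
    t: np.ndarray,
    preproc: PupilPreprocParams = PupilPreprocParams(),
    sampling_rate: float = 1000.0,
):
    """Group-mean evoked pupil-diameter response.

    ``epochs_by_participant`` is a sequence over participants of 2-D arrays
    (n_epochs, n_time) of z-scored, gap-filled pupil traces on the common
    event-locked grid ``t``. Each epoch is baseline-corrected by its mean
    over the pre-onset interval and smoothed; epochs are averaged within
    and then across participants.

    Returns ``(group_mean, per_participant)`` where ``per_participant`` is
    (n_participants, n_time).
    """
    if len(epochs_by_participant) == 0:
        raise ValueError("no participants")
    base = (t >= -preproc.baseline_window) & (t < 0)
    if not base.any():
        raise ValueError("grid does not cover the pre-onset baseline")
    per = []
    for epochs in epochs_by_participant:
        epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
        if epochs.shape[0] == 0:
            raise ValueError("participant with zero epochs")
        corrected = epochs - epochs[:, base].mean(axis=1, keepdims=True)
        smoothed = np.apply_along_axis(
            smooth, 1, corrected, preproc.smoothing_window, sampling_rate
        )
        per.append(smoothed.mean(axis=0))
    per = np.asarray(per)
    return per.mean(axis=0), per


def detect_pupil_events(
    trace: np.ndarray,
    sampling_rate: float = 1000.0,
    params: PupilEventParams = PupilEventParams(),
    presmoothed: bool = True,
):
    """Indices of dilation and constriction events in a pupil trace.

    A dilation event is a local minimum followed by at least 0.1 s of
    non-decreasing trace; a constriction event is a local maximum followed
    by at least 0.1 s of non-increasing trace. Plateaus extend the
    prevailing direction (non-strict monotonicity); endpoints never count.
    Set ``presmoothed=False`` to apply the 0.15 s Hanning smoothing here.
    """
    trace = np.asarray(trace, dtype=float)
    if not presmoothed:
        trace = smooth(trace, params.event_smoothing, sampling_rate)
    d = np.diff(trace)
    s = np.sign(d)
    # plateaus inherit the previous direction (vectorized forward fill)
    nz = s != 0
    if nz.any():
        idx = np.where(nz, np.arange(len(s)), -1)
        last = np.maximum.accumulate(idx)
        s = np.where(last >= 0, s[np.maximum(last, 0)], 0.0)
    min_run = int(np.ceil(params.min_persistence * sampling_rate))
    dilations, constrictions = [], []
    # boundaries of maximal constant-sign runs of s
    change = np.flatnonzero(s[1:] != s[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(s)]))
    for k in range(1, len(starts)):
        prev_sign = s[starts[k - 1]]
        sign = s[starts[k]]
        run = stops[k] - starts[k]
        if run < min_run:
            continue
        i = starts[k]                   # extremum sample index in `trace`
        if prev_sign < 0 and sign > 0:
            dilations.append(i)
        elif prev_sign > 0 and sign < 0:
            constrictions.append(i)
    return np.asarray(dilations, dtype=int), np.asarray(constrictions, dtype=int)


def pupil_event_rate(
    events_by_participant,
    window: tuple = (-0.2, 2.0),
    kernel: KernelParams = KernelParams(),
    sampling_rate: float = 1000.0,
    baseline_corrected: bool = True,
) -> RateSeries:
    """Pupil-event incidence rate; shares the microsaccade rate operator."""
    return ms_rate(
        events_by_participant,
        window=window,
        kernel=kernel,
        sampling_rate=sampling_rate,
        baseline_corrected=baseline_corrected,
    )
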