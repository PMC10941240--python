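"""Shared test utilities: independent oracles and focused simulators.

The detection oracle re-implements the binocular velocity-threshold
algorithm with explicit loops and exhaustive pair matching, independent of
the vectorized implementation it checks.
"""

from __future__ import annotations

import numpy as np

from ocumsi import pupil as pup
from ocumsi import simulate as sim
from ocumsi.microsaccade import DetectionParams


def oracle_velocity(x: np.ndarray, fs: float) -> np.ndarray:
    v = np.zeros(len(x))
    for n in range(2, len(x) - 2):
        v[n] = (x[n + 2] + x[n + 1] - x[n - 1] - x[n - 2]) * fs / 6.0
    return v


def oracle_median_sd(v: np.ndarray) -> float:
    var = np.median(np.sort(v**2)[...]) - np.median(v) ** 2
    return max(float(np.sqrt(max(var, 0.0))), 1e-6)


def oracle_monocular(v, lam, sd, fs, min_d, max_d):
    """Explicit run scan over the supra-threshold mask."""
    events = []
    n = len(v)
    i = 0
    while i < n:
        if abs(v[i]) > lam * sd:
            j = i
            while j + 1 < n and abs(v[j + 1]) > lam * sd:
                j += 1
            duration = (j - i + 1) / fs
            if min_d < duration < max_d:
                events.append((i / fs, j / fs, max(abs(v[k]) for k in range(i, j + 1))))
            i = j + 1
        else:
            i += 1
    return events


def oracle_detect(xl, xr, fs, params: DetectionParams = DetectionParams()):
    """Brute-force binocular detection; returns (onset, offset) pairs."""
    out = []
    cands = {}
    for eye, x in (("left", xl), ("right", xr)):
        v = oracle_velocity(x, fs)
        sd = oracle_median_sd(v)
        cands[eye] = oracle_monocular(
            v, params.lam, sd, fs, params.min_duration, params.max_duration
        )
    pairs = []
    for i, l in enumerate(cands["left"]):
        for j, r in enumerate(cands["right"]):
            d = abs(l[0] - r[0])
            if d < params.max_binocular_disparity:
                pairs.append((d, l[0], i, j))
    pairs.sort()
    used_l, used_r, matched = set(), set(), []
    for _, _, i, j in pairs:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        l, r = cands["left"][i], cands["right"][j]
        matched.append((min(l[0], r[0]), max(l[1], r[1])))
    matched.sort()
    kept = []
    for onset, offset in matched:
        if kept and onset - kept[-1][0] <= params.min_inter_ms_interval:
            continue
        kept.append((onset, offset))
    return kept


def simulate_pupil_condition(
    params: sim.SimParams,
    role: str | None,
    n_participants: int,
    n_epochs: int,
    seed: int,
    window: tuple = (-0.2, 2.0),
    fs: float = 1000.0,
    segment: float = 3.2,
    event_offset: float = 0.8,
):
    """Z-scored event-locked pupil epochs plus detected pupil events.

    One continuous trace per participant with ``n_epochs`` events (or none
    for the control, role=None); returns (epochs_by_participant,
    events_by_participant) where events are (dilation, constriction) lists
    of epoch-relative times, and the epoch time grid.
    """
    n_len = int(round((window[1] - window[0]) * fs)) + 1
    t = window[0] + np.arange(n_len) / fs
    epochs_by_p, events_by_p = [], []
    for child in np.random.SeedSequence(seed).spawn(n_participants):
        rng = np.random.default_rng(child)
        amp_mult = sim._lognormal_multiplier(params.between_subject_cv_amp, rng)
        n = int(segment * fs) * n_epochs
        events = (
            [(event_offset + k * segment, role) for k in range(n_epochs)]
            if role
            else []
        )
        trace, _ = sim.simulate_pupil(n, events, params, rng, amp_multiplier=amp_mult)
        z = (trace - trace.mean()) / trace.std()
        epochs, dil_times, con_times = [], [], []
        for k in range(n_epochs):
            i0 = int(round((event_offset + k * segment + window[0]) * fs))
            ep = z[i0 : i0 + n_len]
            epochs.append(ep)
            sm = pup.smooth(ep, 0.15, fs)
            d, c = pup.detect_pupil_events(sm, fs)
            dil_times.append(t[d])
            con_times.append(t[c])
        epochs_by_p.append(np.asarray(epochs))
        events_by_p.append((dil_times, con_times))
    return epochs_by_p, events_by_p, t
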