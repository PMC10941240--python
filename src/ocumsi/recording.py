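"""Binocular sample data model, tabular I/O, epoching and QC.

Recordings hold 1000 Hz binocular gaze (degrees of visual angle relative to
fixation) and pupil diameter (arbitrary units) with per-eye validity flags.
Samples where gaze leaves the fixation box (> 2.56 deg horizontal or > 2.57
deg vertical) or the eye is (partially) closed are treated as missing;
epochs cut from -0.2 to +2 s around an event are rejected when more than
50% of analysis-eye pupil samples are missing, and remaining gaps are
filled with shape-preserving (monotone) piecewise-cubic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

DEFAULT_SAMPLING_RATE = 1000.0
EPOCH_WINDOW = (-0.2, 2.0)

_COLUMNS = ["t", "lx", "ly", "rx", "ry", "lp", "rp", "lvalid", "rvalid", "block"]


@dataclass(frozen=True)
class QCParams:
    """Validity and epoch-rejection thresholds (strict inequalities)."""

    gaze_box_x: float = 2.56
    gaze_box_y: float = 2.57
    max_missing_fraction: float = 0.5
    analysis_eye: str = "right"

    def __post_init__(self):
        if min(self.gaze_box_x, self.gaze_box_y, self.max_missing_fraction) <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class OcularRecording:
    """Continuous binocular samples on a uniform 1000 Hz grid."""

    t: np.ndarray
    lx: np.ndarray
    ly: np.ndarray
    rx: np.ndarray
    ry: np.ndarray
    lp: np.ndarray
    rp: np.ndarray
    lvalid: np.ndarray
    rvalid: np.ndarray
    block: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        n = len(self.t)
        for name in ("lx", "ly", "rx", "ry", "lp", "rp"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.lvalid = np.asarray(self.lvalid, dtype=bool)
        self.rvalid = np.asarray(self.rvalid, dtype=bool)
        self.block = np.asarray(self.block, dtype=int)
        for name in _COLUMNS[1:]:
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")
        _check_uniform(self.t)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def __len__(self) -> int:
        return len(self.t)

    def gaze_x(self, eye: str) -> np.ndarray:
        return self.lx if eye == "left" else self.rx

    def gaze_y(self, eye: str) -> np.ndarray:
        return self.ly if eye == "left" else self.ry

    def pupil(self, eye: str) -> np.ndarray:
        return self.lp if eye == "left" else self.rp

    def valid(self, eye: str) -> np.ndarray:
        return self.lvalid if eye == "left" else self.rvalid

    def blocks(self) -> np.ndarray:
        return np.unique(self.block)

    def block_slice(self, b: int) -> slice:
        idx = np.nonzero(self.block == b)[0]
        return slice(int(idx[0]), int(idx[-1]) + 1)


def _check_uniform(t: np.ndarray) -> None:
    if len(t) < 2:
        return
    dt = np.diff(t)
    step = np.median(dt)
    bad = np.nonzero(np.abs(dt - step) > step * 0.01)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"non-uniform timestamps: gap of {dt[i]:.6f} s between samples "
            f"{i} and {i + 1} (t={t[i]:.6f})"
        )


def to_frame(rec: OcularRecording) -> pd.DataFrame:
    data = {c: getattr(rec, c) for c in _COLUMNS}
    frame = pd.DataFrame(data)
    frame["lvalid"] = frame["lvalid"].astype(int)
    frame["rvalid"] = frame["rvalid"].astype(int)
    return frame


def write_samples(rec: OcularRecording, path) -> None:
    """Write a recording as tab-separated text (one sample per row)."""
    to_frame(rec).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_samples(path) -> OcularRecording:
    """Read a recording written by :func:`write_samples`.

    Raises a descriptive error on malformed headers or non-uniform
    timestamps (naming the offending line).
    """
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in frame.columns]
    unknown = [c for c in frame.columns if c not in _COLUMNS]
    if missing or unknown:
        raise ValueError(
            f"{path}: malformed header; missing columns {missing}, "
            f"unknown columns {unknown}"
        )
    try:
        return OcularRecording(**{c: frame[c].to_numpy() for c in _COLUMNS})
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None


def read_asc_samples(path, block: int = 0) -> OcularRecording:
    """Thin adapter for Eyelink-style ASC binocular sample lines.

    Expects lines of the form ``<time_ms> <xl> <yl> <pl> <xr> <yr> <pr> ...``
    with ``.`` marking missing values; non-sample lines (messages, events)
    are skipped. Gaze is taken as already expressed in degrees relative to
    fixation. Samples with missing pupil are flagged invalid.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 7:
                continue
            try:
                stamp = float(parts[0])
            except ValueError:
                continue
            values = [
                np.nan if p in (".", "0.0...") else float(p) for p in parts[1:7]
            ]
            rows.append([stamp] + values)
    if not rows:
        raise ValueError(f"{path}: no sample lines found")
    arr = np.asarray(rows, dtype=float)
    t = (arr[:, 0] - arr[0, 0]) / 1000.0
    lx, ly, lp, rx, ry, rp = (arr[:, k] for k in range(1, 7))
    return OcularRecording(
        t=t, lx=lx, ly=ly, rx=rx, ry=ry, lp=lp, rp=rp,
        lvalid=np.isfinite(lp), rvalid=np.isfinite(rp),
        block=np.full(len(t), block, dtype=int),
    )


def mark_invalid(rec: OcularRecording, qc: QCParams = QCParams()) -> OcularRecording:
    """Flag out-of-box gaze and eye-closure samples as missing.

    Strictly monotone: a sample can only lose validity. Pupil values of
    invalid samples are set to NaN (closure is encoded as missing pupil).
    """
    out = replace(rec)
    for eye in ("left", "right"):
        x, y, p = rec.gaze_x(eye), rec.gaze_y(eye), rec.pupil(eye)
        ok = (
            rec.valid(eye)
            & (np.abs(x) <= qc.gaze_box_x)
            & (np.abs(y) <= qc.gaze_box_y)
            & np.isfinite(p)
        )
        p = p.copy()
        p[~ok] = np.nan
        if eye == "left":
            out.lvalid, out.lp = ok, p
        else:
            out.rvalid, out.rp = ok, p
    return out


@dataclass
class Epoch:
    """Event-locked window of samples (default -0.2 ... +2.0 s)."""

    condition: str
    event_time: float
    t: np.ndarray                      # seconds relative to the event
    lx: np.ndarray
    rx: np.ndarray
    lp: np.ndarray
    rp: np.ndarray
    lvalid: np.ndarray
    rvalid: np.ndarray
    block: int
    participant: int | None = None
    analysis_eye: str = "right"
    window: tuple = EPOCH_WINDOW

    def missing_fraction(self, eye: str | None = None) -> float:
        valid = self.lvalid if (eye or self.analysis_eye) == "left" else self.rvalid
        return float(1.0 - valid.mean())

    def pupil(self, eye: str | None = None) -> np.ndarray:
        return self.lp if (eye or self.analysis_eye) == "left" else self.rp

    def __len__(self) -> int:
        return len(self.t)


def epoch_recording(
    rec: OcularRecording,
    events,
    window: tuple = EPOCH_WINDOW,
    participant: int | None = None,
) -> list[Epoch]:
    """Cut one epoch per (event_time, condition) pair.

    Events whose window extends beyond the recording raise an error naming
    the offender. The default window (-0.2 ... 2.0 s) yields 2201 samples
    at 1000 Hz.
    """
    fs = rec.sampling_rate
    n = int(round((window[1] - window[0]) * fs)) + 1
    t_rel = window[0] + np.arange(n) / fs
    t0 = rec.t[0]
    epochs = []
    for event_time, condition in events:
        start = int(round((event_time + window[0] - t0) * fs))
        stop = start + n
        if start < 0 or stop > len(rec):
            raise ValueError(
                f"event at {event_time:.3f} s ({condition}): window "
                f"[{event_time + window[0]:.3f}, {event_time + window[1]:.3f}] s "
                f"exceeds the recording span [{rec.t[0]:.3f}, {rec.t[-1]:.3f}] s"
            )
        sl = slice(start, stop)
        epochs.append(
            Epoch(
                condition=condition,
                event_time=float(event_time),
                t=t_rel.copy(),
                lx=rec.lx[sl].copy(),
                rx=rec.rx[sl].copy(),
                lp=rec.lp[sl].copy(),
                rp=rec.rp[sl].copy(),
                lvalid=rec.lvalid[sl].copy(),
                rvalid=rec.rvalid[sl].copy(),
                block=int(rec.block[start]),
                participant=participant,
                window=window,
            )
        )
    return epochs


def reject_epochs(epochs, qc: QCParams = QCParams()):
    """Split epochs into (kept, rejected) by the > 50% missing-data rule.

    The preferred analysis eye (right) is used where possible; when it
    fails the missing-data criterion but the other eye passes, the epoch is
    kept with the other eye selected. Rejected epochs are returned with a
    reason string.
    """
    kept, rejected = [], []
    other = {"right": "left", "left": "right"}
    for ep in epochs:
        preferred = qc.analysis_eye
        if ep.missing_fraction(preferred) <= qc.max_missing_fraction:
            ep.analysis_eye = preferred
            kept.append(ep)
        elif ep.missing_fraction(other[preferred]) <= qc.max_missing_fraction:
            ep.analysis_eye = other[preferred]
            kept.append(ep)
        else:
            rejected.append(
                (
                    ep,
                    f"missing fraction {ep.missing_fraction(preferred):.2f} "
                    f"({preferred} eye) exceeds {qc.max_missing_fraction:.2f}",
                )
            )
    return kept, rejected


def interpolate_missing(ep: Epoch) -> Epoch:
    """Fill missing pupil samples with a monotone piecewise-cubic (PCHIP).

    Valid samples are left untouched; interpolated spans cannot overshoot
    their anchoring neighbours (shape preservation). Missing runs at the
    epoch edges are held at the nearest valid value.
    """
    for eye in ("left", "right"):
        p = ep.pupil(eye)
        valid = np.isfinite(p)
        if valid.all():
            continue
        if valid.sum() < 2:
            raise ValueError(
                f"epoch at {ep.event_time:.3f} s: fewer than two valid "
                f"{eye}-eye samples, cannot interpolate"
            )
        filled = interpolate_trace(p)
        if eye == "left":
            ep.lp = filled
        else:
            ep.rp = filled
    return ep


def interpolate_trace(p: np.ndarray) -> np.ndarray:
    """PCHIP gap filling for a 1-D trace with NaNs; edges held constant."""
    p = np.asarray(p, dtype=float)
    valid = np.isfinite(p)
    if valid.all():
        return p.copy()
    if valid.sum() < 2:
        raise ValueError("fewer than two valid samples")
    idx = np.arange(len(p))
    interp = PchipInterpolator(idx[valid], p[valid], extrapolate=False)
    out = p.copy()
    out[~valid] = interp(idx[~valid])
    # edge gaps: hold the nearest valid value
    first, last = idx[valid][0], idx[valid][-1]
    out[:first] = p[first]
    out[last + 1 :] = p[last]
    return out
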