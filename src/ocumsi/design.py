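"""Session designs for the dichotic tone-pip attention experiment.

A session presents two concurrent streams of 50 ms tone pips (one per ear,
temporally interleaved, 50 ms inter-tone interval) for 7 s per trial. The
listener monitors the cued ("to-be-attended") stream for a behavioral target
(a 0.15 s gap in Experiment 1, a frequency step in Experiment 2) while the
other event type is embedded task-irrelevantly in either, both, or neither
stream. This module generates the full 128-trial, 4-block schedule, the
per-ear tone grids, and the frequency assignments under the >= 8 pool-step
ear-separation constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARS = ("left", "right")

#: tone-slot period per ear (50 ms pip + 50 ms inter-tone interval)
SLOT = 0.1
TONE_DURATION = 0.05
ITI = 0.05
#: phase of each ear's tone grid relative to its stream onset; the right
#: ear is offset half a slot so tones interleave with the left ear's ITIs
EAR_PHASE = {"left": 0.0, "right": 0.05}
STREAM_DURATION = 7.0
N_SLOTS = 70
IGNORED_ONSET_DELAY = 1.0
EVENT_WINDOW = (2.0, 5.0)
MIN_EVENT_SEPARATION = 2.0
MIN_POOL_STEP_SEPARATION = 8

#: trial-condition labels. "target" trials carry the behaviorally relevant
#: event type; "event" trials carry the task-irrelevant type.
CONDITIONS = (
    "target_attended",
    "target_ignored",
    "event_attended",
    "event_ignored",
    "event_both",
    "event_neither",
)
#: per-block trial composition (sums to 32)
BLOCK_COMPOSITION = {
    "target_attended": 4,
    "target_ignored": 4,
    "event_attended": 6,
    "event_ignored": 6,
    "event_both": 6,
    "event_neither": 6,
}
N_BLOCKS = 4
TRIALS_PER_BLOCK = 32


@dataclass(frozen=True)
class FrequencyPool:
    """Fixed pool of 14 log-spaced tone frequencies, 445-2000 Hz (12% steps)."""

    values: np.ndarray

    @property
    def ratio(self) -> float:
        return float(self.values[1] / self.values[0])

    def __len__(self) -> int:
        return len(self.values)


def build_frequency_pool() -> FrequencyPool:
    """Return the 14-frequency pool: log-spaced, endpoints 445 and 2000 Hz."""
    values = np.geomspace(445.0, 2000.0, 14)
    # pin the endpoints exactly (geomspace is exact up to rounding anyway)
    values[0], values[-1] = 445.0, 2000.0
    return FrequencyPool(values=values)


@dataclass(frozen=True)
class FrequencyAssignment:
    """Per-ear (pre-step, post-step) pool indices for one trial.

    ``post`` indices are None for CONT streams. Every simultaneous
    left/right combination is at least 8 pool steps apart.
    """

    left_pre: int
    right_pre: int
    left_post: int | None = None
    right_post: int | None = None

    def indices(self, ear: str) -> tuple[int, ...]:
        pre = self.left_pre if ear == "left" else self.right_pre
        post = self.left_post if ear == "left" else self.right_post
        return (pre,) if post is None else (pre, post)


def sample_ear_frequencies(
    pool: FrequencyPool,
    rng: np.random.Generator,
    left_step: bool = False,
    right_step: bool = False,
) -> FrequencyAssignment:
    """Draw per-ear frequencies under the >= 8 pool-step separation rule.

    All pre/post combinations across ears are required to satisfy the
    separation (the streams' step times are free to interleave either way,
    so every combination can be simultaneous at some point). Draws that
    violate the constraint are resampled internally.
    """
    n = len(pool)
    while True:
        lp = int(rng.integers(n))
        rp = int(rng.integers(n))
        lpost = int(rng.integers(n)) if left_step else None
        rpost = int(rng.integers(n)) if right_step else None
        left = (lp,) if lpost is None else (lp, lpost)
        right = (rp,) if rpost is None else (rp, rpost)
        if left_step and lpost == lp:
            continue
        if right_step and rpost == rp:
            continue
        if all(abs(li - ri) >= MIN_POOL_STEP_SEPARATION for li in left for ri in right):
            return FrequencyAssignment(
                left_pre=lp, right_pre=rp, left_post=lpost, right_post=rpost
            )


@dataclass
class TrialSpec:
    """One trial: ear assignment, condition, and event times.

    Event times are stored relative to the onset of the stream that contains
    them and lie on that ear's tone grid within [2, 5] s. The attended
    stream starts at trial time 0; the ignored stream 1 s later.
    """

    trial_index: int
    block_index: int
    attended_ear: str
    condition: str
    #: per-ear frequency-step onset time (s, relative to stream onset)
    step_times: dict = field(default_factory=dict)
    #: per-ear gap onset time (s, relative to stream onset)
    gap_times: dict = field(default_factory=dict)
    #: per-ear dummy event times for control ("event_neither") trials
    dummy_times: dict = field(default_factory=dict)
    target_type: str = "gap"
    trial_duration: float = STREAM_DURATION
    iti_min: float = 6.5
    feedback_duration: float = 1.5

    @property
    def ignored_ear(self) -> str:
        return "right" if self.attended_ear == "left" else "left"

    def stream_onset(self, ear: str) -> float:
        return 0.0 if ear == self.attended_ear else IGNORED_ONSET_DELAY

    def ear_role(self, ear: str) -> str:
        return "attended" if ear == self.attended_ear else "ignored"

    @property
    def event_type(self) -> str:
        """The task-irrelevant event type (the attention probe)."""
        return "step" if self.target_type == "gap" else "gap"

    def events_abs(self, event_type: str) -> list[tuple[str, float]]:
        """(ear, trial-absolute onset) of every event of the given type."""
        times = self.step_times if event_type == "step" else self.gap_times
        return [
            (ear, self.stream_onset(ear) + t)
            for ear, t in sorted(times.items())
            if t is not None
        ]

    def probe_events_abs(self) -> list[tuple[str, str, float]]:
        """Task-irrelevant events as (role, ear, trial-absolute onset).

        For control trials the stored dummy times are returned with the
        same role labelling, so control epochs mirror the event epochs.
        """
        out = []
        if self.condition == "event_neither":
            for ear, t in sorted(self.dummy_times.items()):
                out.append((self.ear_role(ear), ear, self.stream_onset(ear) + t))
        else:
            for ear, t in self.events_abs(self.event_type):
                out.append((self.ear_role(ear), ear, t))
        return out

    def stream_pattern(self, ear: str) -> str:
        return "STEP" if self.step_times.get(ear) is not None else "CONT"


@dataclass
class SessionDesign:
    """A complete 128-trial session schedule."""

    trials: list
    experiment: int
    rng_seed: int
    blocks: int = N_BLOCKS
    trials_per_block: int = TRIALS_PER_BLOCK

    def __iter__(self):
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def block_trials(self, block: int) -> list:
        return [t for t in self.trials if t.block_index == block]

    def condition_counts(self) -> dict:
        counts: dict = {}
        for t in self.trials:
            counts[t.condition] = counts.get(t.condition, 0) + 1
        return counts


def _event_slots(ear: str) -> np.ndarray:
    """Tone-grid times (s, relative to stream onset) eligible for events."""
    phase = EAR_PHASE[ear]
    rel = phase + SLOT * np.arange(N_SLOTS)
    lo, hi = EVENT_WINDOW
    # a gap needs a following slot; the last slot is never eligible anyway
    return rel[(rel >= lo) & (rel <= hi) & (rel + SLOT < STREAM_DURATION)]


def _draw_event_time(ear: str, rng: np.random.Generator) -> float:
    slots = _event_slots(ear)
    # times live on the 0.05 s grid; round to the canonical two-decimal
    # representation so schedules serialize exactly
    return float(round(rng.choice(slots), 2))


def _draw_pair_times(trial: TrialSpec, rng: np.random.Generator) -> dict:
    """Event time in each ear, trial-absolute onsets >= 2 s apart."""
    while True:
        t = {ear: _draw_event_time(ear, rng) for ear in EARS}
        abs_times = [trial.stream_onset(ear) + t[ear] for ear in EARS]
        if abs(abs_times[0] - abs_times[1]) >= MIN_EVENT_SEPARATION:
            return t


def build_session(experiment: int, rng_seed: int) -> SessionDesign:
    """Generate the full session design for Experiment 1 or 2.

    128 trials in 4 blocks of 32. Per block: 8 trials carry the behavioral
    target event type (4 attended / 4 ignored) and the remaining 24 carry
    the task-irrelevant event type in the attended stream only, the ignored
    stream only, both streams, or neither (6 each, i.e. 24 each per
    session). Attended-ear assignment is balanced 16/16 within each block.
    Experiment 2 swaps the task significance of gaps and steps.
    """
    if experiment not in (1, 2):
        raise ValueError(f"experiment must be 1 or 2, got {experiment!r}")
    target_type = "gap" if experiment == 1 else "step"
    rng = np.random.default_rng(rng_seed)

    trials: list[TrialSpec] = []
    index = 0
    for block in range(N_BLOCKS):
        conditions = [
            c for c, n in BLOCK_COMPOSITION.items() for _ in range(n)
        ]
        rng.shuffle(conditions)
        ears = ["left"] * (TRIALS_PER_BLOCK // 2) + ["right"] * (TRIALS_PER_BLOCK // 2)
        rng.shuffle(ears)
        for condition, ear in zip(conditions, ears):
            trial = TrialSpec(
                trial_index=index,
                block_index=block,
                attended_ear=ear,
                condition=condition,
                target_type=target_type,
            )
            _assign_event_times(trial, rng)
            trials.append(trial)
            index += 1
    return SessionDesign(trials=trials, experiment=experiment, rng_seed=rng_seed)


def _assign_event_times(trial: TrialSpec, rng: np.random.Generator) -> None:
    probe = trial.event_type            # task-irrelevant type
    target = trial.target_type
    times_of = {"step": trial.step_times, "gap": trial.gap_times}
    cond = trial.condition
    if cond == "target_attended":
        ear = trial.attended_ear
        times_of[target][ear] = _draw_event_time(ear, rng)
    elif cond == "target_ignored":
        ear = trial.ignored_ear
        times_of[target][ear] = _draw_event_time(ear, rng)
    elif cond == "event_attended":
        ear = trial.attended_ear
        times_of[probe][ear] = _draw_event_time(ear, rng)
    elif cond == "event_ignored":
        ear = trial.ignored_ear
        times_of[probe][ear] = _draw_event_time(ear, rng)
    elif cond == "event_both":
        for ear, t in _draw_pair_times(trial, rng).items():
            times_of[probe][ear] = t
    elif cond == "event_neither":
        trial.dummy_times = _draw_pair_times(trial, rng)
    else:  # pragma: no cover - conditions are generated internally
        raise ValueError(f"unknown condition {cond!r}")


@dataclass
class ToneSchedule:
    """One ear's rendered tone-pip sequence for a trial.

    Onsets are trial-absolute seconds on the ear's 0.1 s grid; the two
    ears' grids are offset by 0.05 s so tones interleave. A gap omits two
    consecutive slots (0.15 s silence from the first omitted tone's nominal
    onset to the second's nominal offset).
    """

    ear: str
    stream_onset: float
    tone_onsets: np.ndarray
    frequencies: np.ndarray
    omitted: np.ndarray
    tone_duration: float = TONE_DURATION
    iti: float = ITI


def render_tone_schedule(
    trial: TrialSpec,
    pool: FrequencyPool,
    rng: np.random.Generator,
) -> tuple[ToneSchedule, ToneSchedule]:
    """Render (left, right) tone schedules for a trial.

    Frequencies are drawn fresh (per participant, per trial) under the
    ear-separation constraint; STEP streams switch from the pre- to the
    post-step frequency at the step slot; gaps omit two consecutive slots.
    """
    assignment = sample_ear_frequencies(
        pool,
        rng,
        left_step=trial.step_times.get("left") is not None,
        right_step=trial.step_times.get("right") is not None,
    )
    out = []
    for ear in EARS:
        onset = trial.stream_onset(ear)
        rel = EAR_PHASE[ear] + SLOT * np.arange(N_SLOTS)
        tone_onsets = onset + rel
        idx = assignment.indices(ear)
        freqs = np.full(N_SLOTS, pool.values[idx[0]])
        step_t = trial.step_times.get(ear)
        if step_t is not None:
            _check_event_time(step_t, ear, trial)
            freqs[rel >= step_t - 1e-9] = pool.values[idx[1]]
        omitted = np.zeros(N_SLOTS, dtype=bool)
        gap_t = trial.gap_times.get(ear)
        if gap_t is not None:
            _check_event_time(gap_t, ear, trial)
            k = int(np.argmin(np.abs(rel - gap_t)))
            omitted[k : k + 2] = True
        out.append(
            ToneSchedule(
                ear=ear,
                stream_onset=onset,
                tone_onsets=tone_onsets,
                frequencies=freqs,
                omitted=omitted,
            )
        )
    return out[0], out[1]


def _check_event_time(t: float, ear: str, trial: TrialSpec) -> None:
    lo, hi = EVENT_WINDOW
    if not (lo - 1e-9 <= t <= hi + 1e-9):
        raise ValueError(
            f"trial {trial.trial_index}: event at {t:.3f} s ({ear}) outside "
            f"the [{lo}, {hi}] s window"
        )


# ---------------------------------------------------------------------------
# serialization

_DESIGN_COLUMNS = [
    "trial_index", "block_index", "attended_ear", "condition",
    "step_time_left", "step_time_right", "gap_time_left", "gap_time_right",
    "dummy_time_left", "dummy_time_right",
]


def design_to_frame(design: SessionDesign) -> pd.DataFrame:
    rows = []
    for t in design.trials:
        rows.append(
            {
                "trial_index": t.trial_index,
                "block_index": t.block_index,
                "attended_ear": t.attended_ear,
                "condition": t.condition,
                "step_time_left": t.step_times.get("left"),
                "step_time_right": t.step_times.get("right"),
                "gap_time_left": t.gap_times.get("left"),
                "gap_time_right": t.gap_times.get("right"),
                "dummy_time_left": t.dummy_times.get("left"),
                "dummy_time_right": t.dummy_times.get("right"),
            }
        )
    return pd.DataFrame(rows, columns=_DESIGN_COLUMNS)


def write_design(design: SessionDesign, path) -> None:
    """Write the trial table as TSV plus a sidecar ``<path>.meta`` file."""
    frame = design_to_frame(design)
    frame.to_csv(path, sep="\t", index=False, float_format="%.2f")
    with open(f"{path}.meta", "w") as fh:
        fh.write(f"experiment={design.experiment}\n")
        fh.write(f"rng_seed={design.rng_seed}\n")


def read_design(path) -> SessionDesign:
    frame = pd.read_csv(path, sep="\t")
    meta = {}
    with open(f"{path}.meta") as fh:
        for line in fh:
            key, _, value = line.strip().partition("=")
            meta[key] = int(value)
    experiment = meta["experiment"]
    target_type = "gap" if experiment == 1 else "step"
    trials = []
    for _, row in frame.iterrows():
        def _times(prefix):
            return {
                ear: float(row[f"{prefix}_{ear}"])
                for ear in EARS
                if pd.notna(row[f"{prefix}_{ear}"])
            }
        trials.append(
            TrialSpec(
                trial_index=int(row.trial_index),
                block_index=int(row.block_index),
                attended_ear=str(row.attended_ear),
                condition=str(row.condition),
                step_times=_times("step_time"),
                gap_times=_times("gap_time"),
                dummy_times=_times("dummy_time"),
                target_type=target_type,
            )
        )
    return SessionDesign(
        trials=trials, experiment=experiment, rng_seed=meta["rng_seed"]
    )
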