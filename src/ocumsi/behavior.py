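"""Behavioral scoring: hits, false-alarm categories, d-prime, exclusions.

A button press within 2 s after a target onset is a hit. Other presses are
false alarms of three kinds: (a) within 2 s of a nontarget event in the
ignored stream, (b) within 2 s of the nontarget event type in the attended
stream, (c) anything else. Participants are excluded when the hit rate
falls below 70%, the category-(a) false-alarm rate reaches 30% (the pair of
criteria is equivalent to d' = 1.05), or the baseline microsaccade
incidence is below 0.25 events/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm


@dataclass(frozen=True)
class BehaviorParams:
    response_window: float = 2.0
    hit_criterion: float = 0.70
    fa_criterion: float = 0.30
    min_baseline_ms_rate: float = 0.25

    def __post_init__(self):
        if not (0 < self.hit_criterion < 1 and 0 < self.fa_criterion < 1):
            raise ValueError("criteria must lie in (0, 1)")


@dataclass
class BehavioralSummary:
    n_targets: int
    n_hits: int
    hit_rate: float
    mean_rt: float
    n_fa_events_a: int                  # ignored-stream nontarget events
    fa_count_a: int                     # such events responded to
    fa_rate_category_a: float
    fa_count_b: int
    fa_count_c: int
    d_prime: float


@dataclass
class TrialEvents:
    """Scoreable events of one trial (trial-relative onset seconds)."""

    trial_index: int
    target_times: list = field(default_factory=list)
    nontarget_ignored_times: list = field(default_factory=list)
    nontarget_attended_times: list = field(default_factory=list)


def _in_window(press: float, onset: float, window: float) -> bool:
    return 0.0 < press - onset <= window


def score_responses(
    presses,
    schedule,
    params: BehaviorParams = BehaviorParams(),
) -> BehavioralSummary:
    """Score presses against a session's event schedule.

    ``presses`` is a sequence of (trial_index, press_time) with press times
    relative to trial onset; ``schedule`` a sequence of :class:`TrialEvents`.
    Each press is assigned to exactly one category with precedence
    hit > (a) > (b) > (c), earliest eligible event first; each event absorbs
    at most one press. Hit reaction time is press minus target onset.
    """
    by_trial: dict = {ev.trial_index: ev for ev in schedule}
    hit_targets: dict = {}
    responded_a: set = set()
    fa_b = fa_c = 0
    rts = []
    n_targets = sum(len(ev.target_times) for ev in schedule)
    n_fa_events_a = sum(len(ev.nontarget_ignored_times) for ev in schedule)
    for trial_index, press in sorted(presses):
        ev = by_trial.get(trial_index)
        assigned = False
        if ev is not None:
            for k, onset in enumerate(sorted(ev.target_times)):
                key = (trial_index, k)
                if key not in hit_targets and _in_window(press, onset, params.response_window):
                    hit_targets[key] = press
                    rts.append(press - onset)
                    assigned = True
                    break
            if not assigned:
                for k, onset in enumerate(sorted(ev.nontarget_ignored_times)):
                    key = (trial_index, k)
                    if key not in responded_a and _in_window(press, onset, params.response_window):
                        responded_a.add(key)
                        assigned = True
                        break
            if not assigned:
                if any(
                    _in_window(press, onset, params.response_window)
                    for onset in ev.nontarget_attended_times
                ):
                    fa_b += 1
                    assigned = True
        if not assigned:
            fa_c += 1
    n_hits = len(hit_targets)
    hit_rate = n_hits / n_targets if n_targets else np.nan
    fa_rate = len(responded_a) / n_fa_events_a if n_fa_events_a else np.nan
    return BehavioralSummary(
        n_targets=n_targets,
        n_hits=n_hits,
        hit_rate=hit_rate,
        mean_rt=float(np.mean(rts)) if rts else np.nan,
        n_fa_events_a=n_fa_events_a,
        fa_count_a=len(responded_a),
        fa_rate_category_a=fa_rate,
        fa_count_b=fa_b,
        fa_count_c=fa_c,
        d_prime=d_prime(hit_rate, fa_rate, n_targets or 1, n_fa_events_a or 1),
    )


def d_prime(
    hit_rate: float,
    fa_rate: float,
    n_targets: int = 16,
    n_nontargets: int = 16,
) -> float:
    """Signal-detection sensitivity d' = Phi^-1(hit) - Phi^-1(fa).

    Extreme rates (0 or 1) are clamped to 1/(2N) and 1 - 1/(2N) with the
    respective trial counts, the standard log-linear-free correction.
    """
    def clamp(rate, n):
        lo = 1.0 / (2 * n)
        return min(max(rate, lo), 1.0 - lo)

    if np.isnan(hit_rate) or np.isnan(fa_rate):
        return np.nan
    return float(
        norm.ppf(clamp(hit_rate, n_targets)) - norm.ppf(clamp(fa_rate, n_nontargets))
    )


def apply_exclusions(
    summaries: dict,
    baseline_ms_rates: dict,
    params: BehaviorParams = BehaviorParams(),
):
    """Partition participants into (included, excluded-with-reasons).

    A participant is excluded when the hit rate is below 70%, the
    category-(a) false-alarm rate is at or above 30%, or the baseline
    microsaccade rate is below 0.25 events/s.
    """
    included, excluded = [], []
    for pid, summary in summaries.items():
        reasons = []
        if summary.hit_rate < params.hit_criterion:
            reasons.append(
                f"hit rate {summary.hit_rate:.2f} below {params.hit_criterion:.2f}"
            )
        if summary.fa_rate_category_a >= params.fa_criterion:
            reasons.append(
                f"false-alarm rate {summary.fa_rate_category_a:.2f} not below "
                f"{params.fa_criterion:.2f}"
            )
        base = baseline_ms_rates.get(pid, np.nan)
        if base < params.min_baseline_ms_rate:
            reasons.append(
                f"baseline microsaccade rate {base:.2f} events/s below "
                f"{params.min_baseline_ms_rate:.2f}"
            )
        if reasons:
            excluded.append((pid, reasons))
        else:
            included.append(pid)
    return included, excluded


def ocular_exclusion_flags(design, presses) -> dict:
    """Per-trial flag: exclude from ocular analysis.

    Trials containing the behavioral target event type, or any button
    press, are excluded from the microsaccade/pupillometry analysis.
    """
    pressed = {trial for trial, _ in presses}
    flags = {}
    for trial in design.trials:
        has_target = len(trial.events_abs(trial.target_type)) > 0
        flags[trial.trial_index] = has_target or trial.trial_index in pressed
    return flags
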