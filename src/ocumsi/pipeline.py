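"""End-to-end orchestration: design -> simulate -> QC -> rates -> statistics.

``run_pipeline`` reproduces the full analysis on synthetic data: it builds a
session design, simulates every participant, scores behavior, applies the
participant- and trial-exclusion rules, epochs the recordings around the
task-irrelevant events (and matched dummy times in no-event trials),
computes microsaccade-rate, evoked-pupil and pupil-event-rate time series
per condition, and runs the bootstrap cluster statistic on every condition
pair. All outputs are plain-text tables plus a machine-readable metrics
file; figures are optional artifacts.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import design as dsg
from . import microsaccade as ms
from . import pupil as pup
from . import recording as rio
from . import simulate as sim
from . import stats as tstats

CONDITIONS = ("attended", "ignored", "control")
MEASURES = ("ms_rate", "pdr", "dilation_rate", "constriction_rate")
COMPARISONS = (
    ("attended", "control"),
    ("ignored", "control"),
    ("attended", "ignored"),
)
#: search window for the MSI trough, relative to event onset (s)
MSI_WINDOW = (0.1, 0.5)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Fully resolved run configuration; defaults are the study's values."""

    experiment: int = 1
    seed: int = 0
    sim: sim.SimParams = field(default_factory=sim.SimParams)
    qc: rio.QCParams = field(default_factory=rio.QCParams)
    detection: ms.DetectionParams = field(default_factory=ms.DetectionParams)
    kernel: ms.KernelParams = field(default_factory=ms.KernelParams)
    preproc: pup.PupilPreprocParams = field(default_factory=pup.PupilPreprocParams)
    pupil_events: pup.PupilEventParams = field(default_factory=pup.PupilEventParams)
    behavior: beh.BehaviorParams = field(default_factory=beh.BehaviorParams)
    bootstrap: tstats.BootstrapParams = field(default_factory=tstats.BootstrapParams)
    #: event-locked window used for the statistical time series; it covers
    #: the 2 s pre-onset control interval the cluster threshold needs
    stats_window: tuple = (-2.0, 2.0)
    make_figures: bool = False


_SECTIONS = {
    "sim": sim.SimParams,
    "qc": rio.QCParams,
    "detection": ms.DetectionParams,
    "kernel": ms.KernelParams,
    "preproc": pup.PupilPreprocParams,
    "pupil_events": pup.PupilEventParams,
    "behavior": beh.BehaviorParams,
    "bootstrap": tstats.BootstrapParams,
}
_ALIASES = {("detection", "lambda"): "lam"}


def validate_config(mapping: dict | None) -> RunConfig:
    """Build a resolved RunConfig from a (possibly nested) plain mapping.

    Unknown keys and out-of-range values are reported together, with
    nearest-name suggestions for likely typos. An empty mapping resolves to
    all defaults.
    """
    mapping = dict(mapping or {})
    errors: list[str] = []
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    kwargs: dict = {}
    for key, value in mapping.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            names = {f.name for f in dataclasses.fields(cls)}
            section_kwargs = {}
            for k, v in dict(value or {}).items():
                k = _ALIASES.get((key, k), k)
                if k not in names:
                    hint = difflib.get_close_matches(k, names, n=1)
                    suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
                    errors.append(f"{key}.{k}: unknown field{suggestion}")
                else:
                    if isinstance(v, list):
                        v = tuple(v)
                    section_kwargs[k] = v
            try:
                kwargs[key] = cls(**section_kwargs)
            except (TypeError, ValueError) as err:
                errors.append(f"{key}: {err}")
        elif key in top_fields:
            kwargs[key] = tuple(value) if isinstance(value, list) else value
        else:
            hint = difflib.get_close_matches(key, top_fields | set(_SECTIONS), n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            errors.append(f"{key}: unknown field{suggestion}")
    if not errors and kwargs.get("experiment", 1) not in (1, 2):
        errors.append(f"experiment: must be 1 or 2, got {kwargs['experiment']!r}")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(**kwargs)


def config_to_dict(config: RunConfig) -> dict:
    out: dict = {}
    for f in dataclasses.fields(RunConfig):
        value = getattr(config, f.name)
        if dataclasses.is_dataclass(value):
            out[f.name] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(value).items()
            }
        elif isinstance(value, tuple):
            out[f.name] = list(value)
        else:
            out[f.name] = value
    return out


# ---------------------------------------------------------------------------
# per-participant analysis


def behavior_schedule(design: dsg.SessionDesign) -> list:
    """Scoreable events per trial for the behavior module."""
    schedule = []
    for trial in design.trials:
        targets, ignored_nontargets, attended_other = [], [], []
        for ear, time in trial.events_abs(trial.target_type):
            if ear == trial.attended_ear:
                targets.append(time)
            else:
                ignored_nontargets.append(time)
        for ear, time in trial.events_abs(trial.event_type):
            if ear == trial.attended_ear:
                attended_other.append(time)
        schedule.append(
            beh.TrialEvents(
                trial_index=trial.trial_index,
                target_times=targets,
                nontarget_ignored_times=ignored_nontargets,
                nontarget_attended_times=attended_other,
            )
        )
    return schedule


@dataclass
class ParticipantAnalysis:
    participant: int
    summary: beh.BehavioralSummary
    baseline_ms_rate: float
    #: condition -> list of per-epoch arrays of MS onsets (s rel. event)
    ms_events: dict
    #: condition -> 2-D (n_epochs, n_time) interpolated z-scored pupil
    pupil_epochs: dict
    #: condition -> per-epoch (dilation_times, constriction_times)
    pupil_events: dict
    n_epochs_kept: dict
    n_epochs_rejected: int
    rate_multiplier: float


def analyze_participant(
    design: dsg.SessionDesign,
    pdata: sim.ParticipantData,
    config: RunConfig,
) -> ParticipantAnalysis:
    """QC, detection, epoching and behavioral scoring for one participant."""
    fs = config.sim.sampling_rate
    window = config.stats_window
    summary = beh.score_responses(
        pdata.presses, behavior_schedule(design), config.behavior
    )
    flags = beh.ocular_exclusion_flags(design, pdata.presses)

    ms_events: dict = {c: [] for c in CONDITIONS}
    pupil_epochs: dict = {c: [] for c in CONDITIONS}
    pupil_events: dict = {c: [] for c in CONDITIONS}
    n_rejected = 0
    total_events = 0
    valid_time = 0.0
    kernel_pad = 30.0 / config.kernel.alpha   # causal support before window

    for rec in pdata.recordings:
        b = int(rec.block[0])
        rec = rio.mark_invalid(rec, config.qc)
        detected = ms.detect(rec, config.detection)
        onsets = np.asarray([ev.onset for ev in detected])
        total_events += len(detected)
        valid_time += float((rec.lvalid & rec.rvalid).sum()) / fs
        # z-score the block's pupil in place (valid samples only)
        rec.lp = pup.zscore_block(rec.lp, rec.lvalid)
        rec.rp = pup.zscore_block(rec.rp, rec.rvalid)

        events = []
        for trial in design.block_trials(b):
            if flags[trial.trial_index]:
                continue
            onset = pdata.trial_onsets[b][trial.trial_index]
            for role, _, time in trial.probe_events_abs():
                condition = "control" if trial.condition == "event_neither" else role
                events.append((onset + time, condition))
        if not events:
            continue
        qc_epochs = rio.epoch_recording(rec, events)
        kept, rejected = rio.reject_epochs(qc_epochs, config.qc)
        n_rejected += len(rejected)
        kept_events = [(ep.event_time, ep.condition) for ep in kept]
        eyes = [ep.analysis_eye for ep in kept]
        wide = rio.epoch_recording(rec, kept_events, window=window)
        for ep, eye in zip(wide, eyes):
            ep.analysis_eye = eye
            rio.interpolate_missing(ep)
            trace = ep.pupil()
            pupil_epochs[ep.condition].append(trace)
            smoothed = pup.smooth(
                trace, config.pupil_events.event_smoothing, fs
            )
            dil, con = pup.detect_pupil_events(
                smoothed, fs, config.pupil_events
            )
            pupil_events[ep.condition].append((ep.t[dil], ep.t[con]))
            if onsets.size:
                near = onsets[
                    (onsets >= ep.event_time + window[0] - kernel_pad)
                    & (onsets <= ep.event_time + window[1])
                ]
            else:
                near = onsets
            ms_events[ep.condition].append(near - ep.event_time)

    baseline_rate = total_events / valid_time if valid_time > 0 else np.nan
    return ParticipantAnalysis(
        participant=pdata.participant,
        summary=summary,
        baseline_ms_rate=baseline_rate,
        ms_events=ms_events,
        pupil_epochs={
            c: np.asarray(v) if v else np.empty((0, 0)) for c, v in pupil_epochs.items()
        },
        pupil_events=pupil_events,
        n_epochs_kept={c: len(ms_events[c]) for c in CONDITIONS},
        n_epochs_rejected=n_rejected,
        rate_multiplier=pdata.rate_multiplier,
    )


# ---------------------------------------------------------------------------
# group level


def trough(series: ms.RateSeries, window: tuple = MSI_WINDOW) -> tuple[float, float]:
    """(depth, latency) of the rate minimum in the MSI search window."""
    mask = (series.t >= window[0]) & (series.t <= window[1])
    i = int(np.argmin(series.rate[mask]))
    return float(-series.rate[mask][i]), float(series.t[mask][i])


def _cluster_rows(measure: str, pair: tuple, result: tstats.ClusterResult) -> list:
    rows = []
    if not result.clusters:
        rows.append(
            {
                "measure": measure,
                "comparison": f"{pair[0]}_vs_{pair[1]}",
                "start": np.nan,
                "end": np.nan,
                "direction": 0,
                "threshold_samples": result.threshold_samples,
            }
        )
    for cl in result.clusters:
        rows.append(
            {
                "measure": measure,
                "comparison": f"{pair[0]}_vs_{pair[1]}",
                "start": cl.start,
                "end": cl.end,
                "direction": cl.direction,
                "threshold_samples": result.threshold_samples,
            }
        )
    return rows


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full synthetic experiment and analysis; write all outputs.

    Returns the metrics dictionary that is also written to
    ``<out_dir>/metrics.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    design = dsg.build_session(config.experiment, config.seed)
    dsg.write_design(design, out / "design.tsv")
    with open(out / "config_resolved.json", "w") as fh:
        json.dump(config_to_dict(config), fh, indent=1, sort_keys=True)

    fs = config.sim.sampling_rate
    children = np.random.SeedSequence(config.seed).spawn(config.sim.n_participants)
    analyses: list[ParticipantAnalysis] = []
    for pid, child in enumerate(children):
        pdata = sim.generate_participant(design, config.sim, pid, child)
        analysis = analyze_participant(design, pdata, config)
        analyses.append(analysis)
        log(
            f"participant {pid}: hit={analysis.summary.hit_rate:.3f} "
            f"fa={analysis.summary.fa_rate_category_a:.3f} "
            f"baseline={analysis.baseline_ms_rate:.2f} ev/s, "
            f"{analysis.n_epochs_rejected} epochs rejected"
        )

    summaries = {a.participant: a.summary for a in analyses}
    baselines = {a.participant: a.baseline_ms_rate for a in analyses}
    included, excluded = beh.apply_exclusions(summaries, baselines, config.behavior)
    for pid, reasons in excluded:
        log(f"participant {pid} excluded: " + "; ".join(reasons))
    if len(included) < 2:
        raise RuntimeError("fewer than two participants survive exclusion")
    kept = [a for a in analyses if a.participant in set(included)]

    behavior_frame = pd.DataFrame(
        {
            "participant": [a.participant for a in analyses],
            "hit_rate": [a.summary.hit_rate for a in analyses],
            "mean_rt": [a.summary.mean_rt for a in analyses],
            "fa_rate": [a.summary.fa_rate_category_a for a in analyses],
            "d_prime": [a.summary.d_prime for a in analyses],
            "baseline_ms_rate": [a.baseline_ms_rate for a in analyses],
            "included": [a.participant in set(included) for a in analyses],
        }
    )
    behavior_frame.to_csv(out / "behavior.tsv", sep="\t", index=False)

    # --- condition time series -------------------------------------------
    series: dict = {m: {} for m in MEASURES}
    for cond in CONDITIONS:
        series["ms_rate"][cond] = ms.ms_rate(
            [a.ms_events[cond] for a in kept],
            window=config.stats_window,
            kernel=config.kernel,
            sampling_rate=fs,
        )
        for measure, which in (("dilation_rate", 0), ("constriction_rate", 1)):
            series[measure][cond] = pup.pupil_event_rate(
                [[ep[which] for ep in a.pupil_events[cond]] for a in kept],
                window=config.stats_window,
                kernel=config.kernel,
                sampling_rate=fs,
            )
    t_grid = series["ms_rate"]["attended"].t
    pdr_group: dict = {}
    pdr_per: dict = {}
    for cond in CONDITIONS:
        group, per = pup.evoked_pdr(
            [a.pupil_epochs[cond] for a in kept],
            t_grid,
            config.preproc,
            sampling_rate=fs,
        )
        pdr_group[cond], pdr_per[cond] = group, per

    for measure in MEASURES:
        frame = pd.DataFrame({"t": t_grid})
        for cond in CONDITIONS:
            frame[cond] = (
                pdr_group[cond] if measure == "pdr" else series[measure][cond].rate
            )
        frame.to_csv(out / f"{measure}.tsv", sep="\t", index=False, float_format="%.6g")

    # --- cluster statistics ----------------------------------------------
    rng = np.random.default_rng(config.bootstrap.rng_seed + config.seed)
    cluster_rows: list = []
    cluster_results: dict = {}
    for measure in MEASURES:
        for pair in COMPARISONS:
            if measure == "pdr":
                a_mat, b_mat = pdr_per[pair[0]], pdr_per[pair[1]]
            else:
                a_mat = series[measure][pair[0]].per_participant
                b_mat = series[measure][pair[1]].per_participant
            result = tstats.compare_conditions(
                a_mat, b_mat, t_grid, config.bootstrap, rng
            )
            cluster_results[(measure, pair)] = result
            cluster_rows.extend(_cluster_rows(measure, pair, result))
    pd.DataFrame(cluster_rows).to_csv(out / "clusters.tsv", sep="\t", index=False)

    # --- metrics -----------------------------------------------------------
    inc = behavior_frame[behavior_frame.included]
    depth_att, lat_att = trough(series["ms_rate"]["attended"])
    depth_ign, lat_ign = trough(series["ms_rate"]["ignored"])
    att_vs_ign = cluster_results[("ms_rate", ("attended", "ignored"))]
    metrics = {
        "experiment": config.experiment,
        "seed": config.seed,
        "n_participants": len(analyses),
        "n_included": len(included),
        "hit_rate": float(inc.hit_rate.mean()),
        "mean_rt": float(inc.mean_rt.mean()),
        "fa_rate": float(inc.fa_rate.mean()),
        "d_prime": float(inc.d_prime.mean()),
        "baseline_ms_rate": float(inc.baseline_ms_rate.mean()),
        "msi_depth_attended": depth_att,
        "msi_depth_ignored": depth_ign,
        "msi_latency_attended": lat_att,
        "msi_latency_ignored": lat_ign,
        "valid_epochs": {
            cond: float(np.mean([a.n_epochs_kept[cond] for a in kept]))
            for cond in CONDITIONS
        },
        "ms_attended_vs_ignored_clusters": [
            [cl.start, cl.end, cl.direction] for cl in att_vs_ign.clusters
        ],
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1, sort_keys=True)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    if config.make_figures:
        try:
            _make_figures(out, t_grid, series, pdr_group)
        except Exception as err:  # plotting failures never fail the run
            log(f"figure generation failed: {err}")
            (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return metrics


def _make_figures(out: Path, t, series, pdr_group) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    panels = [
        ("ms_rate", "microsaccade rate (events/s)"),
        ("pdr", "pupil diameter (z)"),
        ("dilation_rate", "dilation rate (events/s)"),
        ("constriction_rate", "constriction rate (events/s)"),
    ]
    colors = {"attended": "#5b2a86", "ignored": "#b491c8", "control": "0.5"}
    for ax, (measure, label) in zip(axes.ravel(), panels):
        for cond in CONDITIONS:
            y = pdr_group[cond] if measure == "pdr" else series[measure][cond].rate
            ax.plot(t, y, label=cond, color=colors[cond])
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_ylabel(label)
        ax.set_xlabel("time from event (s)")
    axes[0, 0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "figures.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# focused simulation-recovery harness


def msi_recovery_experiment(
    params: sim.SimParams,
    n_participants: int = 24,
    n_epochs: int = 48,
    seed: int = 0,
    conditions: tuple = ("attended", "ignored"),
    detection: ms.DetectionParams = ms.DetectionParams(),
    kernel: ms.KernelParams = ms.KernelParams(),
    window: tuple = (-0.2, 1.2),
    baseline_corrected: bool = True,
) -> dict:
    """Epoch-level simulation + detection + rate estimation, per condition.

    A lean harness for parameter-recovery checks: each participant
    contributes ``n_epochs`` event-locked segments per condition ("control"
    means no event), simulated as one continuous trace so the detection
    threshold has block-level scope, then detected and converted to
    baseline-corrected rate series.

    Returns a dict with the per-condition :class:`RateSeries` (participant
    matrices attached), the per-participant rate multipliers, and the
    ground-truth event counts.
    """
    fs = params.sampling_rate
    seg_pre, seg_post = 1.6, 1.3        # s around each segment's event
    seg_len = seg_pre + seg_post
    seg_n = int(round(seg_len * fs))
    n_seg = n_epochs * len(conditions)
    n_samples = seg_n * n_seg
    t = np.arange(n_samples) / fs
    children = np.random.SeedSequence(seed).spawn(n_participants)
    events_by_participant: dict = {c: [] for c in conditions}
    multipliers = []
    injected = 0
    detected_total = 0
    for child in children:
        rng = np.random.default_rng(child)
        mult = sim._lognormal_multiplier(params.between_subject_cv_rate, rng)
        multipliers.append(mult)
        events = []
        event_times = []
        for ci, cond in enumerate(conditions):
            for k in range(n_epochs):
                e_time = (ci * n_epochs + k) * seg_len + seg_pre
                event_times.append((cond, e_time))
                if cond != "control":
                    events.append((e_time, cond))
        profile = sim.ms_rate_profile(t, events, params, rate_multiplier=mult)
        times = sim.simulate_ms_times(t, profile, rng, refractory=params.ms_refractory)
        injected += len(times)
        xl, xr, _ = sim.inject_saccade_waveforms(times, n_samples, params, rng)
        det = ms.detect_binocular(xl, xr, fs, detection)
        onsets = np.asarray([ev.onset for ev in det])
        detected_total += len(det)
        per_cond: dict = {c: [] for c in conditions}
        for cond, e_time in event_times:
            near = onsets[
                (onsets >= e_time - seg_pre) & (onsets <= e_time + seg_post)
            ]
            per_cond[cond].append(near - e_time)
        for cond in conditions:
            events_by_participant[cond].append(per_cond[cond])
    rates = {
        cond: ms.ms_rate(
            events_by_participant[cond],
            window=window,
            kernel=kernel,
            sampling_rate=fs,
            baseline_corrected=baseline_corrected and cond != "control",
        )
        for cond in conditions
    }
    return {
        "rates": rates,
        "rate_multipliers": np.asarray(multipliers),
        "n_injected": injected,
        "n_detected": detected_total,
        "duration_per_participant": n_samples / fs,
    }
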