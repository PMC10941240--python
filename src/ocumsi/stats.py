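"""Bootstrap pointwise test with a pre-onset-derived cluster threshold.

For a pair of condition time series, the per-participant difference series
are resampled across participants with replacement (1000 iterations; one
participant resampling per iteration, applied to all time points so
temporal dependence is preserved). A time point is significant when more
than 95% of iteration means fall on one side of zero. The longest run of
significant samples in a 2 s pre-onset control interval — attributable to
noise by construction — sets the minimum run length a post-onset cluster
must strictly exceed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BootstrapParams:
    n_iterations: int = 1000
    criterion: float = 0.95
    control_window: float = 2.0         # s before onset
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.5 < self.criterion < 1.0):
            raise ValueError("criterion must lie in (0.5, 1)")
        if self.n_iterations < 1:
            raise ValueError("need at least one bootstrap iteration")


@dataclass
class Cluster:
    start: float
    end: float
    direction: int                      # +1 (A > B) or -1 (A < B)
    n_samples: int


@dataclass
class ClusterResult:
    t: np.ndarray
    sig_mask: np.ndarray                # int8 per sample: -1, 0, +1
    threshold_samples: int
    clusters: list


def participant_differences(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise per-participant difference A - B (same grids required)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] < 2:
        raise ValueError("need at least two participants")
    return a - b


def pointwise_bootstrap(
    differences: np.ndarray,
    params: BootstrapParams = BootstrapParams(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Signed pointwise significance mask from participant resampling.

    Returns int8 per time point: +1 where more than ``criterion`` of
    bootstrap means are above zero, -1 where more than ``criterion`` are
    below, else 0. Zero-valued means count as neither.
    """
    differences = np.atleast_2d(np.asarray(differences, dtype=float))
    n_p = differences.shape[0]
    if n_p < 2:
        raise ValueError("need at least two participants")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    idx = rng.integers(n_p, size=(params.n_iterations, n_p))
    # one resampling per iteration across all time points: counts @ data
    counts = np.zeros((params.n_iterations, n_p))
    np.add.at(counts, (np.repeat(np.arange(params.n_iterations), n_p), idx.ravel()), 1.0)
    means = counts @ differences / n_p
    prop_pos = (means > 0).mean(axis=0)
    prop_neg = (means < 0).mean(axis=0)
    mask = np.zeros(differences.shape[1], dtype=np.int8)
    mask[prop_pos > params.criterion] = 1
    mask[prop_neg > params.criterion] = -1
    return mask


def _run_lengths(mask: np.ndarray):
    """(start, length, value) of maximal constant-value runs."""
    if len(mask) == 0:
        return []
    change = np.flatnonzero(mask[1:] != mask[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(mask)]))
    return [(int(a), int(b - a), int(mask[a])) for a, b in zip(starts, stops)]


def derive_cluster_threshold(control_mask: np.ndarray) -> int:
    """Longest run of significant samples (either direction) pre-onset."""
    best = 0
    for _, length, value in _run_lengths(np.asarray(control_mask) != 0):
        if value:
            best = max(best, length)
    return best


def significant_clusters(
    post_mask: np.ndarray,
    threshold_samples: int,
    t_post: np.ndarray,
) -> list:
    """Same-direction runs strictly longer than the control threshold."""
    clusters = []
    for start, length, value in _run_lengths(np.asarray(post_mask)):
        if value != 0 and length > threshold_samples:
            clusters.append(
                Cluster(
                    start=float(t_post[start]),
                    end=float(t_post[start + length - 1]),
                    direction=int(value),
                    n_samples=int(length),
                )
            )
    return clusters


def compare_conditions(
    a: np.ndarray,
    b: np.ndarray,
    t: np.ndarray,
    params: BootstrapParams = BootstrapParams(),
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Full cluster statistic for two condition series on an event grid.

    ``a`` and ``b`` are (n_participants, n_time) on the grid ``t`` whose
    origin is the event onset; the grid must include the pre-onset control
    interval. The pointwise mask is computed over the whole grid, the
    cluster threshold over [-control_window, 0), and clusters over t >= 0.
    """
    t = np.asarray(t, dtype=float)
    diffs = participant_differences(a, b)
    if diffs.shape[1] != len(t):
        raise ValueError("time grid does not match the series")
    mask = pointwise_bootstrap(diffs, params, rng)
    control = (t >= -params.control_window) & (t < 0)
    post = t >= 0
    if not control.any():
        raise ValueError("grid does not cover a pre-onset control interval")
    threshold = derive_cluster_threshold(mask[control])
    clusters = significant_clusters(mask[post], threshold, t[post])
    return ClusterResult(
        t=t, sig_mask=mask, threshold_samples=threshold, clusters=clusters
    )
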