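"""Velocity estimation, detection criteria, and the rate kernel."""

import numpy as np
import pytest

from helpers import oracle_detect
from ocumsi import microsaccade as ms
from ocumsi import simulate as sim

FS = 1000.0


class TestVelocity:
    def test_constant_trace_has_zero_velocity(self):
        v = ms.compute_velocity(np.full(100, 3.7), FS)
        np.testing.assert_allclose(v, 0.0)

    def test_linear_trace_exact(self):
        t = np.arange(100) / FS
        v = ms.compute_velocity(10.0 * t, FS)
        np.testing.assert_allclose(v[2:-2], 10.0, atol=1e-9)
        np.testing.assert_allclose(v[:2], 0.0)
        np.testing.assert_allclose(v[-2:], 0.0)

    def test_matches_bruteforce_stencil(self, rng):
        from helpers import oracle_velocity

        x = np.cumsum(rng.standard_normal(500)) * 0.01
        np.testing.assert_allclose(
            ms.compute_velocity(x, FS), oracle_velocity(x, FS), atol=1e-9
        )

    def test_step_displacement_peak_velocity(self):
        # 0.5 deg over 10 samples at 1000 Hz ~ 50 deg/s plateau
        x = np.concatenate([np.zeros(50), np.linspace(0, 0.5, 11), np.full(50, 0.5)])
        v = ms.compute_velocity(x, FS)
        assert np.max(np.abs(v)) == pytest.approx(50.0, rel=0.05)

    def test_too_short_trace_errors(self):
        with pytest.raises(ValueError):
            ms.compute_velocity(np.zeros(4), FS)


class TestMedianBasedSD:
    def test_symmetric_integers(self):
        assert ms.median_based_sd(np.array([-2.0, -1, 0, 1, 2])) == pytest.approx(1.0)

    def test_single_outlier_is_ignored(self):
        # both medians are zero, so the spread floors at epsilon
        assert ms.median_based_sd(np.array([0.0, 0, 0, 100, 0])) == ms.VELOCITY_SD_FLOOR

    def test_constant_floors(self):
        assert ms.median_based_sd(np.full(10, 3.0)) == ms.VELOCITY_SD_FLOOR


class TestMonocularDetection:
    def _velocity_with_run(self, n_run, amplitude=100.0, n=400, at=100):
        v = np.zeros(n)
        v[at : at + n_run] = amplitude
        return v

    def test_20_sample_run_is_one_candidate(self):
        v = self._velocity_with_run(20)
        cands = ms.detect_monocular(v, ms.DetectionParams(), 1.0, FS)
        assert len(cands) == 1
        assert cands[0].offset - cands[0].onset == pytest.approx(0.019)
        assert (cands[0].offset_idx - cands[0].onset_idx + 1) / FS == pytest.approx(0.02)

    @pytest.mark.parametrize("n_run", [4, 5])
    def test_short_runs_rejected(self, n_run):
        v = self._velocity_with_run(n_run)
        assert ms.detect_monocular(v, ms.DetectionParams(), 1.0, FS) == []

    def test_long_run_rejected(self):
        v = self._velocity_with_run(150)
        assert ms.detect_monocular(v, ms.DetectionParams(), 1.0, FS) == []


class TestBinocularMatch:
    def _cand(self, onset, offset=None):
        offset = onset + 0.02 if offset is None else offset
        return ms.Candidate(
            onset_idx=int(onset * FS),
            offset_idx=int((offset) * FS),
            onset=onset,
            offset=offset,
            peak_velocity=50.0,
        )

    def test_small_disparity_matched(self):
        events = ms.binocular_match(
            [self._cand(1.000)], [self._cand(1.008)], ms.DetectionParams()
        )
        assert len(events) == 1
        assert events[0].onset == pytest.approx(1.000)
        assert events[0].disparity == pytest.approx(0.008)

    def test_disparity_at_or_beyond_10ms_unmatched(self):
        events = ms.binocular_match(
            [self._cand(1.000)], [self._cand(1.012)], ms.DetectionParams()
        )
        assert events == []

    def test_refractory_drops_later_event(self):
        left = [self._cand(2.000), self._cand(2.030)]
        right = [self._cand(2.001), self._cand(2.031)]
        events = ms.binocular_match(left, right, ms.DetectionParams())
        assert len(events) == 1
        assert events[0].onset == pytest.approx(2.000)

    def test_each_candidate_used_once(self):
        left = [self._cand(1.000)]
        right = [self._cand(1.002), self._cand(1.006)]
        events = ms.binocular_match(left, right, ms.DetectionParams())
        assert len(events) == 1


class TestDetection:
    def test_equivalent_to_bruteforce_oracle(self):
        params = ms.DetectionParams()
        sp = sim.SimParams()
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 4000
            times = np.sort(rng.uniform(0.1, n / FS - 0.1, size=rng.integers(0, 8)))
            xl, xr, _ = sim.inject_saccade_waveforms(times, n, sp, rng)
            got = ms.detect_binocular(xl, xr, FS, params)
            expected = oracle_detect(xl, xr, FS, params)
            assert len(got) == len(expected)
            for ev, (onset, offset) in zip(got, expected):
                assert ev.onset == pytest.approx(onset, abs=1e-9)
                assert ev.offset == pytest.approx(offset, abs=1e-9)

    def test_injected_events_recovered_with_accurate_onsets(self):
        sp = sim.SimParams(gaze_noise_sd=0.002)
        rng = np.random.default_rng(5)
        times = np.arange(12) * 0.5 + 0.3
        xl, xr, _ = sim.inject_saccade_waveforms(times, 7000, sp, rng)
        events = ms.detect_binocular(xl, xr, FS, ms.DetectionParams())
        assert len(events) == 12
        np.testing.assert_allclose(
            [ev.onset for ev in events], times, atol=0.005
        )

    def test_pure_noise_false_positive_rate_low(self):
        sp = sim.SimParams()
        fp = 0
        duration = 0.0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            xl, xr, _ = sim.inject_saccade_waveforms(np.empty(0), 10_000, sp, rng)
            fp += len(ms.detect_binocular(xl, xr, FS, ms.DetectionParams()))
            duration += 10.0
        assert fp / duration < 0.1

    def test_quiet_trials_have_no_supra_threshold_runs(self):
        # noise-floor calibration: without injected events the velocity
        # almost never exceeds 6 robust SDs for more than 5 ms
        sp = sim.SimParams()
        quiet = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            xl, xr, _ = sim.inject_saccade_waveforms(np.empty(0), 2000, sp, rng)
            v = ms.compute_velocity(xl, FS)
            cands = ms.detect_monocular(
                v, ms.DetectionParams(), ms.median_based_sd(v), FS
            )
            quiet += not cands
        assert quiet >= 99

    def test_empty_recording_detects_nothing(self):
        x = np.zeros(100)
        assert ms.detect_binocular(x, x, FS, ms.DetectionParams()) == []

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        sp = sim.SimParams()
        times = np.sort(rng.uniform(0.2, 9.8, size=12))
        xl, xr, _ = sim.inject_saccade_waveforms(times, 10_000, sp, rng)
        counts = [
            len(ms.detect_binocular(xl, xr, FS, ms.DetectionParams(lam=lam)))
            for lam in (3.0, 4.5, 6.0, 8.0, 12.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestRateKernel:
    def test_unit_integral(self):
        for alpha in (1 / 0.01, 1 / 0.05, 1 / 0.1):
            w = ms.rate_kernel(alpha, FS)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unshifted_impulse_response_peaks_at_one_over_alpha(self):
        kernel = ms.KernelParams(shift=0.0)
        series = ms.ms_rate(
            [[np.array([0.0])]], window=(-0.2, 1.0), kernel=kernel,
            baseline_corrected=False,
        )
        assert series.t[np.argmax(series.rate)] == pytest.approx(0.05)

    def test_default_shift_centres_peak_on_event(self):
        series = ms.ms_rate(
            [[np.array([0.0])]], window=(-0.2, 1.0), baseline_corrected=False
        )
        assert series.t[np.argmax(series.rate)] == pytest.approx(0.0, abs=1e-9)

    def test_mass_conservation(self):
        # integral of the mean uncorrected rate = events per epoch
        rng = np.random.default_rng(11)
        epochs = [np.sort(rng.uniform(0.3, 1.2, size=3)) for _ in range(10)]
        series = ms.ms_rate(
            [epochs], window=(-0.2, 3.0), baseline_corrected=False
        )
        integral = np.trapezoid(series.rate, series.t)
        assert integral == pytest.approx(3.0, rel=1e-3)

    def test_homogeneous_rate_recovered(self):
        rng = np.random.default_rng(13)
        rate = 1.27
        epochs = []
        for _ in range(500):
            n = rng.poisson(rate * 4.0)
            epochs.append(np.sort(rng.uniform(-2.0, 2.0, size=n)))
        series = ms.ms_rate(
            [epochs], window=(-0.2, 1.8), baseline_corrected=False
        )
        assert series.rate.mean() == pytest.approx(rate, rel=0.1)

    def test_no_events_gives_zero_rate(self):
        series = ms.ms_rate([[np.empty(0)] * 5], window=(-0.2, 2.0))
        np.testing.assert_allclose(series.rate, 0.0)

    def test_zero_epochs_errors(self):
        with pytest.raises(ValueError):
            ms.ms_rate([[]])

    def test_trough_rank_order_robust_to_kernel_choice(self):
        # attended vs ignored inhibition depth ordering survives the
        # alternate smoothing parameters (rate-level simulation)
        sp = sim.SimParams()
        rng = np.random.default_rng(21)
        n_epochs, seg = 2000, 3.0
        t = np.arange(int(n_epochs * seg * FS)) / FS
        epochs = {"attended": [], "ignored": []}
        for role in epochs:
            onsets = 1.5 + seg * np.arange(n_epochs)
            profile = sim.ms_rate_profile(t, [(e, role) for e in onsets], sp)
            times = sim.simulate_ms_times(t, profile, rng)
            for e in onsets:
                sel = (times >= e - 1.5) & (times < e + 1.5)
                epochs[role].append(times[sel] - e)
        for alpha in (1 / 0.01, 1 / 0.05, 1 / 0.1):
            kernel = ms.KernelParams(alpha=alpha)
            depth = {}
            for role, eps in epochs.items():
                series = ms.ms_rate([eps], window=(-0.2, 1.2), kernel=kernel)
                mask = (series.t >= 0.1) & (series.t <= 0.5)
                depth[role] = series.rate[mask].mean()
            assert depth["attended"] < depth["ignored"]
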