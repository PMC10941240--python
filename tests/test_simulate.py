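"""Ground-truth fidelity of the synthetic ocular-data generator."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from ocumsi import microsaccade as ms
from ocumsi import recording as rio
from ocumsi import simulate as sim

FS = 1000.0


class TestRateProfile:
    def test_no_events_gives_constant_baseline(self, default_params):
        t = np.arange(0, 7, 1 / FS)
        profile = sim.ms_rate_profile(t, [], default_params)
        np.testing.assert_allclose(profile, default_params.baseline_ms_rate)

    def test_attended_dip_depth_and_latency(self, default_params):
        t = np.arange(0, 7, 1 / FS)
        profile = sim.ms_rate_profile(t, [(3.0, "attended")], default_params)
        trough = profile.min()
        assert trough == pytest.approx(
            default_params.baseline_ms_rate - default_params.msi_depth_attended,
            abs=1e-6,
        )
        assert t[np.argmin(profile)] == pytest.approx(
            3.0 + default_params.msi_trough_latency, abs=0.002
        )
        assert (profile >= 0).all()

    def test_deeper_dip_removes_more_mass(self, default_params):
        t = np.arange(0, 7, 1 / FS)
        base = default_params.baseline_ms_rate
        removed = {}
        for role in ("attended", "ignored"):
            profile = sim.ms_rate_profile(t, [(3.0, role)], default_params)
            removed[role] = np.trapezoid(base - profile, t)
        assert removed["attended"] > removed["ignored"]

    def test_depth_exceeding_baseline_rejected(self):
        with pytest.raises(ValueError):
            sim.SimParams(baseline_ms_rate=0.5, msi_depth_attended=0.68)


class TestPoissonThinning:
    def test_zero_profile_no_events(self, rng):
        t = np.arange(0, 5, 1 / FS)
        assert len(sim.simulate_ms_times(t, np.zeros_like(t), rng)) == 0

    def test_homogeneous_mean_count(self, rng):
        # 1.27 events/s over 7 s -> 8.89 events per trial once the
        # refractory deletion is compensated
        t = np.arange(0, 7, 1 / FS)
        profile = np.full_like(t, 1.27)
        counts = [len(sim.simulate_ms_times(t, profile, rng)) for _ in range(1500)]
        assert np.mean(counts) == pytest.approx(1.27 * 7.0, rel=0.02)

    def test_refractory_interval_enforced(self, rng):
        t = np.arange(0, 60, 1 / FS)
        times = sim.simulate_ms_times(t, np.full_like(t, 5.0), rng, refractory=0.05)
        assert np.all(np.diff(times) > 0.05)

    def test_thinning_matches_time_rescaling_oracle(self, rng):
        # independent simulator oracle: inverse-CDF time rescaling
        t = np.arange(0, 2000, 1 / 100.0)
        profile = 1.0 + 0.5 * np.sin(2 * np.pi * t / 7.0)
        ours = sim.simulate_ms_times(t, profile, rng, refractory=0.0, compensate=False)
        cum = np.concatenate(([0.0], np.cumsum(profile[:-1] * np.diff(t))))
        total = cum[-1]
        arrivals = []
        s = 0.0
        while True:
            s += rng.exponential(1.0)
            if s >= total:
                break
            arrivals.append(np.interp(s, cum, t))
        oracle = np.asarray(arrivals)
        stat = ks_2samp(np.diff(ours), np.diff(oracle))
        assert stat.pvalue > 0.01


class TestSaccadeWaveforms:
    def test_single_event_exceeds_detection_threshold_in_both_eyes(self, default_params):
        rng = np.random.default_rng(3)
        xl, xr, truth = sim.inject_saccade_waveforms(
            np.array([1.0]), 2000, default_params, rng
        )
        assert len(truth) == 1
        for x in (xl, xr):
            v = ms.compute_velocity(x, FS)
            sd = ms.median_based_sd(v)
            runs = ms.detect_monocular(v, ms.DetectionParams(), sd, FS)
            assert len(runs) == 1
            assert runs[0].offset_idx - runs[0].onset_idx + 1 >= 6

    def test_rendered_disparity_below_10_ms(self, default_params):
        rng = np.random.default_rng(4)
        times = np.arange(50) * 0.4 + 0.2
        _, _, truth = sim.inject_saccade_waveforms(times, 21_000, default_params, rng)
        assert len(truth) == 50
        assert all(w["disparity"] < 0.01 for w in truth)

    def test_gaze_stays_near_fixation(self, default_params):
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0.2, 59.8, 80))
        xl, _, _ = sim.inject_saccade_waveforms(times, 60_000, default_params, rng)
        assert np.abs(xl).max() < 2.56


class TestPupilSimulation:
    def test_zero_amplitude_leaves_background_only(self, default_params):
        params = sim.SimParams(pdr_amplitude_attended=0.0, pdr_amplitude_ignored=0.0)
        with_events, _ = sim.simulate_pupil(
            5000, [(1.0, "attended")], params, np.random.default_rng(6)
        )
        without, _ = sim.simulate_pupil(5000, [], params, np.random.default_rng(6))
        np.testing.assert_array_equal(with_events, without)

    def test_evoked_peak_latency_matches_analytic_value(self, default_params):
        tau = np.arange(0, 5, 1 / FS)
        kernel = sim.evoked_pupil_kernel(tau, 1.0, 1.5, default_params)
        peak = tau[np.argmax(kernel)]
        assert abs(peak - sim.evoked_peak_latency(default_params)) <= 1 / FS

    def test_trace_contains_evoked_dilation(self, default_params):
        rng = np.random.default_rng(7)
        trace, truth = sim.simulate_pupil(6000, [(1.0, "attended")], default_params, rng)
        quiet, _ = sim.simulate_pupil(6000, [], default_params, np.random.default_rng(7))
        diff = trace - quiet
        peak_idx = np.argmax(diff)
        assert peak_idx / FS == pytest.approx(truth[0]["peak_time"], abs=0.005)


class TestMissingData:
    def _recording(self, n=10_000, seed=8):
        rng = np.random.default_rng(seed)
        return rio.OcularRecording(
            t=np.arange(n) / FS,
            lx=rng.standard_normal(n) * 0.1,
            ly=rng.standard_normal(n) * 0.1,
            rx=rng.standard_normal(n) * 0.1,
            ry=rng.standard_normal(n) * 0.1,
            lp=1500 + rng.standard_normal(n),
            rp=1500 + rng.standard_normal(n),
            lvalid=np.ones(n, dtype=bool),
            rvalid=np.ones(n, dtype=bool),
            block=np.zeros(n, dtype=int),
        )

    def test_zero_rates_leave_recording_unchanged(self, default_params):
        params = sim.SimParams(blink_rate=0.0, closure_rate=0.0, excursion_rate=0.0)
        rec = self._recording()
        before = rec.lp.copy()
        out, intervals = sim.inject_blinks_and_excursions(
            rec, params, np.random.default_rng(9)
        )
        assert not intervals
        np.testing.assert_array_equal(out.lp, before)
        assert out.lvalid.all()

    def test_single_blink_fraction_below_rejection_rule(self):
        # one 0.3 s blink in a 2.2 s epoch: 13.6% missing, epoch retained
        rec = self._recording(n=2201)
        rec.rvalid[1000:1300] = False
        rec.rp[1000:1300] = np.nan
        (ep,) = rio.epoch_recording(rec, [(0.2, "c")], window=(-0.2, 2.0))
        assert ep.missing_fraction("right") == pytest.approx(0.3 / 2.201, abs=0.01)
        kept, _ = rio.reject_epochs([ep])
        assert len(kept) == 1

    def test_blinks_marked_missing(self, default_params):
        rec = self._recording(n=100_000)
        out, intervals = sim.inject_blinks_and_excursions(
            rec, default_params, np.random.default_rng(10)
        )
        assert intervals
        start, stop = intervals[0]
        i = int((start + stop) / 2 * FS)
        assert not out.lvalid[i] and np.isnan(out.lp[i])


class TestDataset:
    def test_regenerates_identically_from_seed(self, session_exp1, default_params):
        child = np.random.SeedSequence(55).spawn(1)[0]
        a = sim.generate_participant(session_exp1, default_params, 0, child)
        b = sim.generate_participant(
            session_exp1, default_params, 0, np.random.SeedSequence(55).spawn(1)[0]
        )
        np.testing.assert_array_equal(a.recordings[0].lx, b.recordings[0].lx)
        np.testing.assert_array_equal(a.recordings[2].rp, b.recordings[2].rp)
        assert a.presses == b.presses

    def test_ground_truth_consistent_with_recording(self, session_exp1, default_params):
        child = np.random.SeedSequence(56).spawn(1)[0]
        pdata = sim.generate_participant(session_exp1, default_params, 0, child)
        for rec in pdata.recordings:
            b = int(rec.block[0])
            times = pdata.ground_truth["ms_times"][b]
            assert np.all(times >= rec.t[0]) and np.all(times <= rec.t[-1])
            assert len(times) > 0
        assert pdata.rate_multiplier > 0
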