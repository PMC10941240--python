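"""Session-design invariants: pool, composition, timing, rendering."""

import numpy as np
import pytest

from ocumsi import design as dsg


class TestFrequencyPool:
    def test_endpoints_and_spacing(self, pool):
        assert len(pool.values) == 14
        assert pool.values[0] == pytest.approx(445.0)
        assert pool.values[13] == pytest.approx(2000.0)
        assert np.all(np.diff(pool.values) > 0)
        ratios = pool.values[1:] / pool.values[:-1]
        # log spacing: constant ratio, ~12% steps
        assert np.allclose(ratios, ratios[0])
        assert ratios[0] == pytest.approx((2000.0 / 445.0) ** (1 / 13))
        assert ratios[0] == pytest.approx(1.12, abs=0.005)

    def test_eight_steps_above_bottom_is_1122(self, pool):
        assert pool.values[8] == pytest.approx(1122.0, abs=0.5)


class TestEarFrequencies:
    def test_separation_holds_over_many_draws(self, pool, rng):
        for _ in range(10_000):
            a = dsg.sample_ear_frequencies(
                pool, rng, left_step=bool(rng.integers(2)), right_step=bool(rng.integers(2))
            )
            left = a.indices("left")
            right = a.indices("right")
            assert all(abs(l - r) >= 8 for l in left for r in right)

    def test_low_left_forces_high_right(self, pool, rng):
        # when the left ear sits at the pool bottom (445 Hz), the right ear
        # must land at least eight steps up, i.e. above 1122 Hz
        seen = 0
        while seen < 50:
            a = dsg.sample_ear_frequencies(pool, rng)
            if a.left_pre == 0:
                assert a.right_pre >= 8
                assert pool.values[a.right_pre] >= 1122.0
                seen += 1

    def test_top_left_forces_low_right(self, pool, rng):
        seen = 0
        while seen < 50:
            a = dsg.sample_ear_frequencies(pool, rng)
            if a.left_pre == 13:
                assert a.right_pre <= 5
                seen += 1


class TestSessionComposition:
    def test_trial_and_block_counts(self, session_exp1):
        assert len(session_exp1) == 128
        for b in range(4):
            assert len(session_exp1.block_trials(b)) == 32

    def test_target_trials_per_block(self, session_exp1):
        for b in range(4):
            trials = session_exp1.block_trials(b)
            att = [t for t in trials if t.condition == "target_attended"]
            ign = [t for t in trials if t.condition == "target_ignored"]
            assert len(att) == 4 and len(ign) == 4
            # 8 trials (25%) per block carry the behavioral target event
            assert sum(len(t.events_abs(t.target_type)) > 0 for t in trials) == 8

    @pytest.mark.parametrize("fixture", ["session_exp1", "session_exp2"])
    def test_probe_composition_24_each(self, fixture, request):
        session = request.getfixturevalue(fixture)
        counts = session.condition_counts()
        for cond in ("event_attended", "event_ignored", "event_both", "event_neither"):
            assert counts[cond] == 24
        # balanced within blocks as well
        for b in range(4):
            trials = session.block_trials(b)
            for cond in ("event_attended", "event_ignored", "event_both", "event_neither"):
                assert sum(t.condition == cond for t in trials) == 6

    def test_attended_ear_balanced_within_block(self, session_exp1):
        for b in range(4):
            ears = [t.attended_ear for t in session_exp1.block_trials(b)]
            assert ears.count("left") == 16

    def test_event_times_in_window_and_separated(self, session_exp1, session_exp2):
        for session in (session_exp1, session_exp2):
            for trial in session:
                times = {**trial.step_times, **trial.gap_times}
                for t in times.values():
                    assert 2.0 - 1e-9 <= t <= 5.0 + 1e-9
                both = trial.events_abs(trial.event_type)
                if len(both) == 2:
                    assert abs(both[0][1] - both[1][1]) >= 2.0 - 1e-9

    def test_experiment_2_swaps_target_type(self, session_exp1, session_exp2):
        assert all(t.target_type == "gap" for t in session_exp1)
        assert all(t.target_type == "step" for t in session_exp2)
        # in Exp 2 target trials carry a step, probe trials carry gaps
        tgt = next(t for t in session_exp2 if t.condition == "target_attended")
        assert tgt.step_times and not tgt.gap_times

    def test_same_seed_reproduces_identical_design(self):
        a = dsg.design_to_frame(dsg.build_session(1, 42))
        b = dsg.design_to_frame(dsg.build_session(1, 42))
        assert a.equals(b)

    def test_invalid_experiment_rejected(self):
        with pytest.raises(ValueError):
            dsg.build_session(3, 0)

    def test_control_trials_carry_two_dummy_times(self, session_exp1):
        for trial in session_exp1:
            if trial.condition == "event_neither":
                assert set(trial.dummy_times) == {"left", "right"}
                probes = trial.probe_events_abs()
                assert {role for role, _, _ in probes} == {"attended", "ignored"}


class TestToneSchedules:
    def test_gap_omits_150_ms(self, pool, rng, session_exp1):
        trial = next(t for t in session_exp1 if t.gap_times)
        left, right = dsg.render_tone_schedule(trial, pool, rng)
        sched = left if trial.gap_times.get("left") is not None else right
        omitted = np.flatnonzero(sched.omitted)
        assert len(omitted) == 2 and omitted[1] == omitted[0] + 1
        span = (
            sched.tone_onsets[omitted[1]] + sched.tone_duration
            - sched.tone_onsets[omitted[0]]
        )
        assert span == pytest.approx(0.15)

    def test_cont_cont_trial_is_eventless_single_frequency(self, pool, rng, session_exp1):
        trial = next(t for t in session_exp1 if t.condition == "event_neither")
        for sched in dsg.render_tone_schedule(trial, pool, rng):
            assert not sched.omitted.any()
            assert len(np.unique(sched.frequencies)) == 1

    def test_attended_stream_leads_by_one_second(self, pool, rng, session_exp1):
        trial = session_exp1.trials[0]
        left, right = dsg.render_tone_schedule(trial, pool, rng)
        attended = left if trial.attended_ear == "left" else right
        ignored = right if trial.attended_ear == "left" else left
        assert ignored.stream_onset - attended.stream_onset == pytest.approx(1.0)

    def test_tones_interleave(self, pool, rng, session_exp1):
        left, right = dsg.render_tone_schedule(session_exp1.trials[0], pool, rng)
        # a tone in one ear always falls in the other ear's inter-tone gap
        for onset in right.tone_onsets:
            rel = (onset - left.tone_onsets[0]) % 0.1
            assert rel == pytest.approx(0.05)

    def test_step_changes_frequency_with_separation(self, pool, rng, session_exp1):
        trial = next(t for t in session_exp1 if t.condition == "event_both")
        for _ in range(20):
            left, right = dsg.render_tone_schedule(trial, pool, rng)
            for sched in (left, right):
                assert len(np.unique(sched.frequencies)) == 2
            # exhaustive separation scan over every co-occurring pair
            li = np.searchsorted(pool.values, left.frequencies)
            ri = np.searchsorted(pool.values, right.frequencies)
            for l in np.unique(li):
                for r in np.unique(ri):
                    assert abs(int(l) - int(r)) >= 8

    def test_out_of_window_event_rejected(self, pool, rng, session_exp1):
        trial = next(t for t in session_exp1 if t.condition == "event_attended")
        bad = dsg.TrialSpec(
            trial_index=0,
            block_index=0,
            attended_ear=trial.attended_ear,
            condition=trial.condition,
            step_times={trial.attended_ear: 5.6},
            target_type="gap",
        )
        with pytest.raises(ValueError, match="outside"):
            dsg.render_tone_schedule(bad, pool, rng)


def test_design_round_trip(tmp_path, session_exp1):
    path = tmp_path / "design.tsv"
    dsg.write_design(session_exp1, path)
    loaded = dsg.read_design(path)
    assert dsg.design_to_frame(loaded).equals(dsg.design_to_frame(session_exp1))
    assert loaded.experiment == 1 and loaded.rng_seed == 0
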