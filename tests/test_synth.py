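"""Generator invariants: determinism, rates, trial labeling, planted content."""

import numpy as np
import pandas as pd
import pytest

from placeseq.preprocess import estimate_speed
from placeseq.session import PositionSeries, TaskGeometry
from placeseq.synth import (
    SimulationSpec,
    build_session,
    build_trial_schedule,
    expected_mean_rates,
    simulate_lfp,
    simulate_rest_replay,
    simulate_run_spikes,
    simulate_trajectory,
)
from tests.conftest import small_spec

TWO_PI = 2 * np.pi


class TestGeometry:
    def test_default_matches_task_layout(self, geometry):
        assert geometry.track_radius == 50.0  # 100-cm diameter
        assert geometry.n_sites == 19
        assert geometry.site_spacing == pytest.approx(0.199)
        assert len(geometry.candidate_sites) == 10

    def test_candidates_are_farthest_from_restbox(self, geometry):
        from placeseq.circstats import circular_distance

        cand = set(geometry.candidate_sites.tolist())
        d = circular_distance(geometry.site_angles, geometry.restbox_angle)
        worst_candidate = min(d[s] for s in cand)
        best_excluded = max(d[s] for s in range(19) if s not in cand)
        assert worst_candidate >= best_excluded

    def test_overlapping_sites_rejected(self):
        with pytest.raises(ValueError):
            TaskGeometry(n_sites=40, site_spacing=0.199)

    def test_goal_outside_candidates_rejected(self):
        with pytest.raises(ValueError):
            TaskGeometry(goal_site=0)


class TestDeterminism:
    def test_same_seed_identical_sessions(self, geometry):
        s1, t1 = build_session(geometry, small_spec(seed=3), with_lfp=False)
        s2, t2 = build_session(geometry, small_spec(seed=3), with_lfp=False)
        assert np.array_equal(s1.position.angles, s2.position.angles)
        for u in s1.spikes.unit_ids:
            assert np.array_equal(s1.spikes.trains[u], s2.spikes.trains[u])
        assert t1.planted_swr_intervals == t2.planted_swr_intervals
        pd.testing.assert_frame_equal(s1.trials, s2.trials)

    def test_different_seed_differs(self, geometry):
        s1, _ = build_session(geometry, small_spec(seed=3), with_lfp=False)
        s2, _ = build_session(geometry, small_spec(seed=4), with_lfp=False)
        assert not np.array_equal(
            s1.spikes.merged_times(), s2.spikes.merged_times()
        )


class TestTrajectory:
    def test_zero_noise_lap_duration_matches_kinematics(self, geometry):
        spec = SimulationSpec(run_speed_sd=0.0, n_pre_laps=2, seed=0)
        schedule = build_trial_schedule(geometry, spec).iloc[:1]
        pos, trials = simulate_trajectory(geometry, spec, schedule)
        lap_time = geometry.circumference / spec.run_speed_mean
        measured = trials.iloc[0]["t_stop_s"] - trials.iloc[0]["t_start_s"]
        assert measured == pytest.approx(2 * lap_time, abs=0.1)

    def test_angle_monotone_during_runs(self, small_session):
        session, _ = small_session
        for _, tr in session.trials.iterrows():
            sel = (session.position.times >= tr["t_start_s"]) & (
                session.position.times < tr["t_stop_s"]
            )
            assert (np.diff(session.position.unwrapped[sel]) >= -1e-12).all()

    def test_rest_windows_pinned_at_restbox(self, small_session, geometry):
        from placeseq.circstats import circular_distance

        session, _ = small_session
        for a, b in session.rest_windows():
            sel = (session.position.times > a + 0.1) & (session.position.times < b - 0.1)
            d = circular_distance(session.position.angles[sel], geometry.restbox_angle)
            assert d.max() < 1e-9

    def test_stop_outside_candidates_rejected(self, geometry):
        spec = SimulationSpec(seed=0)
        schedule = pd.DataFrame(
            [{"stage": "sample-test", "phase": "test", "stop_site": 0, "laps": 0}]
        )
        with pytest.raises(ValueError):
            simulate_trajectory(geometry, spec, schedule)

    def test_outcome_labels_follow_stop_sites(self, small_session, geometry):
        session, truth = small_session
        st = session.trials[session.trials["phase"].isin(["test", "post-test"])]
        for _, tr in st.iterrows():
            expected = "correct" if tr["stop_site"] == geometry.goal_site else "error"
            assert tr["outcome"] == expected
        # sample trials inherit their pair's test outcome
        pairs = session.trials[session.trials["stage"] == "sample-test"]
        samples = pairs[pairs["phase"] == "sample"].reset_index()
        tests = pairs[pairs["phase"] == "test"].reset_index()
        assert (samples["outcome"] == tests["outcome"]).all()


class TestRunSpikes:
    def test_empty_ensemble_valid(self, geometry):
        spec = small_spec(n_units=0)
        session, _ = build_session(geometry, spec, with_lfp=False)
        assert session.spikes.n_spikes == 0
        assert session.position.times.size > 0

    def test_zero_peak_rate_nearly_silent(self, geometry):
        spec = small_spec(peak_rate=0.0, baseline_rate=0.0, n_pairs=1, n_post_trials=0)
        session, truth = build_session(geometry, spec, with_lfp=False)
        run_total = sum(
            ((session.spikes.trains[u] >= r["t_start_s"]) &
             (session.spikes.trains[u] < r["t_stop_s"])).sum()
            for u in session.spikes.unit_ids
            for _, r in session.trials.iterrows()
        )
        assert run_total == 0  # only planted replay spikes remain

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(peak_rate=-1.0)

    def test_mean_rates_match_programmed_intensity(self, geometry):
        # Poisson counts within 3 SE of the intensity integral per unit
        spec = small_spec(n_pairs=2, n_post_trials=0, seed=9)
        schedule = build_trial_schedule(geometry, spec)
        pos, _ = simulate_trajectory(geometry, spec, schedule)
        spikes = simulate_run_spikes(pos, spec)
        expected = expected_mean_rates(pos, spec)
        dur = pos.times[-1] - pos.times[0]
        outside = 0
        for u, exp_rate in zip(spikes.unit_ids, expected):
            n = spikes.trains[u].size
            mu = exp_rate * dur
            se = np.sqrt(max(mu, 1.0))
            outside += abs(n - mu) > 3 * se
        assert outside <= max(2, int(0.05 * len(expected)))

    def test_no_precession_spike_phase_position_independent(self, geometry):
        # precession_slope ~ 0: theta phase of spikes unrelated to position
        spec = small_spec(precession_slope=1e-9, n_pairs=4, n_post_trials=0,
                          gate_depth=0.0, seed=13)
        schedule = build_trial_schedule(geometry, spec)
        pos, _ = simulate_trajectory(geometry, spec, schedule)
        spikes = simulate_run_spikes(pos, spec)
        # circular-mean spike phase identical in the early and late field
        # half, averaged over units (single units carry lap-sampling noise)
        from placeseq.circstats import circular_distance

        diffs = []
        for unit in range(15, 36):
            st = spikes.trains[unit]
            if st.size < 20:
                continue
            phases = (TWO_PI * spec.theta_freq * st) % TWO_PI
            d = (pos.angle_at(st) - spec.centers()[unit]) % TWO_PI
            d = np.where(d > np.pi, d - TWO_PI, d)
            mean_early = np.angle(np.exp(1j * phases[d < 0]).mean())
            mean_late = np.angle(np.exp(1j * phases[d >= 0]).mean())
            diffs.append(circular_distance(mean_early, mean_late))
        assert len(diffs) >= 10
        assert np.mean(diffs) < 0.35


class TestRestReplay:
    def test_replay_spikes_confined_to_swr_intervals(self, small_session):
        # rest-period spikes outside planted SWRs only at the baseline rate
        session, truth = small_session
        rest = session.rest_windows()
        merged = session.spikes.merged_times()
        stray = 0
        rest_dur = 0.0
        for a, b in rest:
            rest_dur += (b - a) - 1.0
            in_rest = merged[(merged >= a + 0.5) & (merged < b - 0.5)]
            stray += sum(
                not any(s <= t < e for s, e in truth.planted_swr_intervals)
                for t in in_rest
            )
        expected = 0.1 * session.spikes.n_units * rest_dur  # baseline-rate spikes
        assert stray <= expected + 3 * np.sqrt(expected + 1)

    def test_end_bias_one_all_events_end_at_goal(self, geometry):
        spec = SimulationSpec(seed=4, replay_end_bias=1.0)
        intervals = [(i * 1.0, i * 1.0 + 0.08) for i in range(10)]
        _, truth = simulate_rest_replay(intervals, spec, geometry)
        assert all(ev["end_site"] == geometry.goal_site for ev in truth)

    def test_zero_replay_speed_rejected(self, geometry):
        with pytest.raises(ValueError):
            simulate_rest_replay([(0.0, 0.08)], SimulationSpec(replay_speed=0.0), geometry)

    def test_every_replay_inside_its_swr(self, small_session):
        _, truth = small_session
        for ev in truth.planted_replays:
            s, e = ev["swr_interval"]
            assert s <= ev["t_start"] and ev["t_end"] <= e


class TestLFP:
    def test_ripple_outside_rest_rejected(self, geometry):
        t = np.arange(0, 20, 1 / 30)
        pos = PositionSeries(times=t, angles=(0.8 * t) % TWO_PI)
        estimate_speed(pos)
        with pytest.raises(ValueError):
            simulate_lfp(pos, SimulationSpec(seed=0), [(5.0, 5.08)], [(10.0, 20.0)])

    def test_noiseless_theta_envelope_constant(self, geometry):
        from placeseq.lfp import band_analytic

        t = np.arange(0, 20, 1 / 30)
        pos = PositionSeries(times=t, angles=(0.8 * t) % TWO_PI)
        estimate_speed(pos)
        spec = SimulationSpec(seed=0, noise_sd=0.0)
        lfp = simulate_lfp(pos, spec, [], [(0.0, 0.0)])
        bs = band_analytic(lfp.traces[:, 0], lfp.fs, "theta", times=lfp.times)
        mid = slice(4000, -4000)
        env = bs.envelope[mid]
        assert env.std() / env.mean() < 0.1
        dphi = np.diff(np.unwrap(bs.phase[mid])).mean() * lfp.fs
        assert dphi == pytest.approx(TWO_PI * 8.0, rel=0.02)
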