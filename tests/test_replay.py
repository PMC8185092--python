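"""SWR detection, replay qualification, bias test, end-stop correlation."""

import numpy as np
import pytest

from placeseq.circstats import CircLinearFit
from placeseq.decoder import PosteriorMatrix
from placeseq.preprocess import estimate_speed
from placeseq.replay import (
    ReplayEvent,
    SWREvent,
    detect_swr,
    end_vs_stop_correlation,
    qualify_replay,
    termination_bias,
)
from placeseq.session import PositionSeries, SpikeSet, TaskGeometry
from placeseq.synth import (
    SimulationSpec,
    analytic_rate_map,
    plant_swr_intervals,
    planted_replay_events,
    simulate_lfp,
)

TWO_PI = 2 * np.pi
BIN_CENTERS = (np.arange(90) + 0.5) * TWO_PI / 90


def rest_lfp(seed, duration=40.0, n_ripples=5):
    """Rest-box LFP with planted ripples; returns (lfp, intervals, rest)."""
    times = np.arange(0, duration, 1 / 30.0)
    pos = PositionSeries(times=times, angles=np.zeros_like(times))
    estimate_speed(pos)
    rest = [(0.0, duration)]
    spec = SimulationSpec(seed=seed)
    intervals = plant_swr_intervals(
        rest, SimulationSpec(seed=seed, replays_per_rest=n_ripples)
    )
    return simulate_lfp(pos, spec, intervals, rest), intervals, rest


class TestDetectSWR:
    def test_planted_ripples_recovered_one_to_one(self):
        lfp, intervals, rest = rest_lfp(seed=0)
        events = detect_swr(lfp, rest)
        for a, b in intervals:
            overlapping = [e for e in events if e.t_start < b and e.t_end > a]
            assert len(overlapping) == 1

    def test_no_events_on_ripple_free_noise(self):
        lfp, _, rest = rest_lfp(seed=1, n_ripples=0)
        assert detect_swr(lfp, rest) == []

    def test_core_duration_at_least_50_ms(self):
        lfp, _, rest = rest_lfp(seed=2)
        for e in detect_swr(lfp, rest):
            assert e.core_end - e.core_start >= 0.050 - 1e-9
            assert e.t_start <= e.core_start and e.t_end >= e.core_end

    def test_empty_rest_mask_rejected(self):
        lfp, _, _ = rest_lfp(seed=3, n_ripples=0)
        with pytest.raises(ValueError):
            detect_swr(lfp, [])


class TestQualifyReplay:
    def test_planted_forward_event_accepted_with_high_r2(self, geometry):
        spec = SimulationSpec(seed=5, replay_p_forward=1.0, replay_end_bias=1.0)
        events, truth = planted_replay_events(geometry, spec, 6)
        assert len(events) == 6
        for ev, tr in zip(events, truth):
            assert ev.direction == "forward" == tr["direction"]
            assert ev.r2 > 0.5
            assert ev.end_site == geometry.goal_site

    def test_planted_reverse_event_classified_reverse(self, geometry):
        spec = SimulationSpec(seed=6, replay_p_forward=0.0)
        events, truth = planted_replay_events(geometry, spec, 6)
        assert all(e.direction == "reverse" for e in events)
        assert all(e.fit.slope < 0 for e in events)

    def test_no_spikes_rejected(self, geometry):
        spec = SimulationSpec(seed=7)
        maps = analytic_rate_map(spec)
        swr = SWREvent(0.0, 0.1, 0.0, 0.1, 8.0)
        spikes = SpikeSet({u: np.empty(0) for u in range(spec.n_units)},
                          t_start=0, t_stop=1)
        assert qualify_replay(swr, spikes, maps, geometry) is None

    def test_short_trimmed_duration_rejected(self, geometry):
        spec = SimulationSpec(seed=8)
        maps = analytic_rate_map(spec)
        # all spikes inside 30 ms -> trimmed duration ~< 50 ms
        spikes = SpikeSet(
            {u: np.array([0.05 + 0.001 * u]) for u in range(20)}
            | {u: np.empty(0) for u in range(20, spec.n_units)},
            t_start=0, t_stop=1,
        )
        swr = SWREvent(0.04, 0.09, 0.04, 0.09, 8.0)
        assert qualify_replay(swr, spikes, maps, geometry) is None

    def test_too_many_empty_windows_rejected(self, geometry):
        spec = SimulationSpec(seed=9)
        maps = analytic_rate_map(spec)
        # spikes only at the edges of a 200-ms event: middle windows empty
        trains = {u: np.empty(0) for u in range(spec.n_units)}
        trains[10] = np.array([0.01, 0.012, 0.015])
        trains[11] = np.array([0.19, 0.192, 0.195])
        spikes = SpikeSet(trains, t_start=0, t_stop=1)
        swr = SWREvent(0.0, 0.2, 0.0, 0.2, 8.0)
        assert qualify_replay(swr, spikes, maps, geometry) is None


def _manual_event(end_site, geometry, stop_site=None, block="trials 1-4"):
    """ReplayEvent whose terminal posterior is a delta at one site."""
    probs = np.zeros((3, 90))
    site_angle = geometry.site_angles[end_site]
    bin_idx = int(site_angle / (TWO_PI / 90))
    probs[:, bin_idx] = 1.0
    post = PosteriorMatrix(np.array([0.02, 0.03, 0.04]), BIN_CENTERS, probs)
    return ReplayEvent(
        swr=SWREvent(0, 0.1, 0, 0.1, 8.0), t_start=0.0, t_end=0.1,
        fit=CircLinearFit(10.0, 0.0, 0.9, 0.9), direction="forward",
        empty_fraction=0.0, posterior=post, end_site=end_site, start_site=0,
        block=block, stop_site=stop_site if stop_site is not None else end_site,
    )


class TestTerminationBias:
    def test_all_events_at_goal_only_goal_significant(self, geometry):
        events = [_manual_event(geometry.goal_site, geometry) for _ in range(30)]
        res = termination_bias(events, geometry, n_shuffles=1000, seed=0)
        assert res.significant_locations().tolist() == [0]

    def test_shuffles_conserve_mass(self, geometry, rng):
        events, _ = planted_replay_events(
            geometry, SimulationSpec(seed=11, replay_end_bias=0.5), 10
        )
        res = termination_bias(events, geometry, n_shuffles=200, seed=1)
        total = sum(ev.posterior.probabilities[-1].sum() for ev in events)
        assert res.observed.sum() == pytest.approx(total, abs=1e-9)
        # null bounds profile from mass-conserving shuffles
        assert res.null_hi.sum() >= res.null_lo.sum()

    def test_rotation_equivariance_on_compatible_grid(self):
        # geometry whose sites tile the bin grid exactly (90 bins / 18 sites)
        geo = TaskGeometry(n_sites=18, site_spacing=TWO_PI / 18, site_start=0.0,
                          goal_site=9)
        k_sites = 4
        shift_bins = (90 // 18) * k_sites
        events = [_manual_event(9, geo) for _ in range(12)]
        rotated = []
        for ev in events:
            probs = np.roll(ev.posterior.probabilities, shift_bins, axis=1)
            post = PosteriorMatrix(ev.posterior.centers, BIN_CENTERS, probs)
            rotated.append(
                ReplayEvent(swr=ev.swr, t_start=ev.t_start, t_end=ev.t_end,
                            fit=ev.fit, direction=ev.direction,
                            empty_fraction=0.0, posterior=post,
                            end_site=(9 + k_sites) % 18, start_site=0)
            )
        a = termination_bias(events, geo, goal_site=9, n_shuffles=300, seed=5)
        b = termination_bias(rotated, geo, goal_site=(9 + k_sites) % 18,
                             n_shuffles=300, seed=5)
        assert np.allclose(a.observed, b.observed)
        assert np.allclose(a.null_hi, b.null_hi)

    def test_initiation_variant_uses_first_window(self, geometry):
        probs = np.zeros((3, 90))
        site_a = geometry.site_angles[5]
        site_b = geometry.site_angles[12]
        probs[0, int(site_a / (TWO_PI / 90))] = 1.0
        probs[1:, int(site_b / (TWO_PI / 90))] = 1.0
        post = PosteriorMatrix(np.array([0.02, 0.03, 0.04]), BIN_CENTERS, probs)
        ev = ReplayEvent(swr=SWREvent(0, 0.1, 0, 0.1, 8.0), t_start=0, t_end=0.1,
                         fit=CircLinearFit(10, 0, 0.9, 0.9), direction="forward",
                         empty_fraction=0.0, posterior=post, end_site=12, start_site=5)
        first = termination_bias([ev] * 20, geometry, end="first",
                                 n_shuffles=300, seed=2)
        off_a = (5 - geometry.goal_site)
        assert first.observed[first.locations == off_a][0] == pytest.approx(20.0, abs=1e-9)

    def test_empty_event_list_rejected(self, geometry):
        with pytest.raises(ValueError):
            termination_bias([], geometry)


class TestEndVsStop:
    def test_perfect_coupling_gives_mcc_one(self, geometry):
        goal = geometry.goal_site
        events = []
        for off in (-2, -1, 0, 1, 2) * 4:
            events.append(_manual_event(goal + off, geometry, stop_site=goal + off))
        df = end_vs_stop_correlation(events, geometry, n_resamples=100)
        row = df[df["block"] == "trials 1-4"].iloc[0]
        assert row["mcc"] == pytest.approx(1.0)

    def test_independent_labels_near_zero(self, geometry, rng):
        goal = geometry.goal_site
        events = [
            _manual_event(goal + int(rng.integers(-3, 4)), geometry,
                          stop_site=goal + int(rng.integers(-3, 4)))
            for _ in range(300)
        ]
        df = end_vs_stop_correlation(events, geometry, n_resamples=100)
        assert abs(df[df["block"] == "trials 1-4"].iloc[0]["mcc"]) < 0.15

    def test_planted_partial_coupling_recovered(self, geometry, rng):
        # end site equals stop site on 80% of events, uniform otherwise
        goal = geometry.goal_site
        events = []
        pairs = []
        for _ in range(400):
            stop = goal + int(rng.integers(-3, 4))
            end = stop if rng.random() < 0.8 else goal + int(rng.integers(-3, 4))
            pairs.append((end, stop))
            events.append(_manual_event(end, geometry, stop_site=stop))
        df = end_vs_stop_correlation(events, geometry, n_resamples=200, seed=4)
        row = df[df["block"] == "trials 1-4"].iloc[0]
        # oracle: MCC computed directly on the generating table
        from placeseq.circstats import matthews_multiclass

        cm = np.zeros((7, 7))
        for end, stop in pairs:
            cm[end - goal + 3, stop - goal + 3] += 1
        direct = matthews_multiclass(cm)
        assert row["mcc"] == pytest.approx(direct, abs=1e-9)
        assert row["ci_lo"] <= direct <= row["ci_hi"]

    def test_block_without_error_trials_flagged(self, geometry):
        events = [_manual_event(geometry.goal_site, geometry, block="post-test")
                  for _ in range(10)]
        df = end_vs_stop_correlation(events, geometry, n_resamples=50)
        assert np.isnan(df[df["block"] == "post-test"].iloc[0]["mcc"])
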