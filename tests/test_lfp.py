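"""Band filtering, phase conventions, theta cycles, gamma cycle numbering."""

import numpy as np
import pytest

from placeseq.lfp import (
    BANDS,
    band_analytic,
    gamma_cycle_analysis,
    segment_theta_cycles,
    select_theta_channel,
    spike_phase_by_location,
)
from placeseq.session import LFPSet, PositionSeries, SpikeSet

TWO_PI = 2 * np.pi
FS = 2000.0


def sinusoid(freq, dur=10.0, amp=1.0, fs=FS):
    t = np.arange(0, dur, 1 / fs)
    return t, amp * np.cos(TWO_PI * freq * t)


class TestBandAnalytic:
    def test_band_definitions(self):
        assert BANDS["theta"] == (6.0, 10.0)
        assert BANDS["slow_gamma"] == (25.0, 55.0)
        assert BANDS["fast_gamma"] == (60.0, 100.0)
        assert BANDS["ripple"] == (150.0, 250.0)

    def test_pure_theta_envelope_and_phase_rate(self):
        t, x = sinusoid(8.0, amp=3.0)
        bs = band_analytic(x, FS, "theta", times=t)
        mid = slice(2000, -2000)  # avoid filter edges
        assert np.allclose(bs.envelope[mid], 3.0, rtol=0.02)
        # phase advances 2*pi per 125 ms
        dphi = np.diff(np.unwrap(bs.phase[mid]))
        assert dphi.mean() * FS == pytest.approx(TWO_PI * 8.0, rel=0.01)

    def test_phase_zero_at_oscillation_peak(self):
        t, x = sinusoid(8.0)
        bs = band_analytic(x, FS, "theta", times=t)
        peaks = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1
        peaks = peaks[(peaks > 2000) & (peaks < x.size - 2000)]
        wrapped = (bs.phase[peaks] + np.pi) % TWO_PI - np.pi
        assert np.abs(wrapped).max() < 0.05

    def test_zero_phase_filtering_no_lag(self):
        t, x = sinusoid(8.0)
        bs = band_analytic(x, FS, "theta", times=t)
        mid = slice(2000, -2000)
        lag = np.argmax(np.correlate(bs.filtered[mid][:4000], x[mid][:4000], "full")) - 3999
        assert lag == 0

    def test_znormalized_power_over_mask(self, rng):
        x = rng.normal(0, 1, int(20 * FS))
        mask = np.zeros(x.size, dtype=bool)
        mask[: x.size // 2] = True
        bs = band_analytic(x, FS, "slow_gamma", mask=mask)
        assert bs.power_z[mask].mean() == pytest.approx(0.0, abs=1e-9)
        assert bs.power_z[mask].std() == pytest.approx(1.0, abs=1e-9)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_analytic(np.zeros(1000), 300.0, "ripple")


class TestSelectThetaChannel:
    def test_single_channel_returned(self):
        t, x = sinusoid(8.0)
        lfp = LFPSet(times=t, traces=x[:, None], fs=FS, channel_ids=[3])
        assert select_theta_channel(lfp, np.ones(t.size, dtype=bool)) == 3

    def test_doubled_theta_amplitude_wins(self, rng):
        t, x = sinusoid(8.0)
        noise = rng.normal(0, 0.3, (t.size, 3))
        traces = np.stack([x, 2 * x, x], axis=1) + noise
        lfp = LFPSet(times=t, traces=traces, fs=FS)
        assert select_theta_channel(lfp, np.ones(t.size, dtype=bool)) == 1


class TestThetaCycles:
    def test_pure_theta_cycle_durations(self, rng):
        t, x = sinusoid(8.0, dur=20.0)
        bs = band_analytic(x, FS, "theta", times=t)
        spikes = SpikeSet({0: np.sort(rng.uniform(1, 19, 400))})
        cyc = segment_theta_cycles(bs, spikes)
        inner = (cyc.boundaries[:-1] > 1.0) & (cyc.boundaries[1:] < 19.0)
        assert np.allclose(cyc.durations()[inner], 0.125, atol=1e-3)

    def test_cut_phase_opposite_planted_spike_phase(self, rng):
        # spikes concentrated at the trough (phase pi) -> cut near the peak (0)
        t, x = sinusoid(8.0, dur=30.0)
        trough_times = (np.arange(8, 200) + 0.5) * 0.125  # cos trough at phase pi
        spikes = SpikeSet({0: trough_times + rng.normal(0, 0.004, trough_times.size)})
        bs = band_analytic(x, FS, "theta", times=t)
        cyc = segment_theta_cycles(bs, spikes)
        wrapped = (cyc.cut_phase + np.pi) % TWO_PI - np.pi
        assert abs(wrapped) < np.pi / 4

    def test_cycles_partition_the_epoch(self, rng):
        t, x = sinusoid(8.0, dur=20.0)
        bs = band_analytic(x, FS, "theta", times=t)
        spikes = SpikeSet({0: np.sort(rng.uniform(1, 19, 300))})
        cyc = segment_theta_cycles(bs, spikes)
        assert (np.diff(cyc.boundaries) > 0).all()

    def test_no_spikes_rejected(self):
        t, x = sinusoid(8.0)
        bs = band_analytic(x, FS, "theta", times=t)
        with pytest.raises(ValueError):
            segment_theta_cycles(bs, SpikeSet({0: np.empty(0)}))


class _Event:
    def __init__(self, t_start, t_end, location_to_stop=-7.0):
        self.t_start = t_start
        self.t_end = t_end
        self.location_to_stop = location_to_stop


class TestGammaCycles:
    def test_single_complete_cycle_is_cycle_zero(self, rng):
        t, x = sinusoid(40.0, dur=2.0)
        bs = band_analytic(x, FS, "slow_gamma", times=t)
        ev = _Event(1.0, 1.03)  # ~1.2 gamma cycles at 40 Hz
        spikes = SpikeSet({0: np.array([1.004, 1.010, 1.016])})
        out = gamma_cycle_analysis(ev, spikes, bs)
        assert out is None or out["n_complete_cycles"] == 1

    def test_planted_per_cycle_phase_advance_detected(self):
        t, x = sinusoid(40.0, dur=10.0)
        bs = band_analytic(x, FS, "slow_gamma", times=t)
        # spikes drifting +0.8 rad of gamma phase per cycle around cycle 0
        period = 1 / 40.0
        base = 5.0
        times = []
        for k in (-1, 0, 0, 0, 1):  # cycle 0 has maximal spiking
            phase = (0.8 * k) % TWO_PI + 0.3
            times.append(base + (k + 2) * period + phase / TWO_PI * period)
        spikes = SpikeSet({0: np.sort(np.array(times))})
        ev = _Event(base, base + 5 * period + 0.002)
        out = gamma_cycle_analysis(ev, spikes, bs)
        assert out is not None
        assert out["circ_linear_corr"] > 0.9

    def test_cycle_independent_phase_jitter_no_correlation(self, rng):
        # same mean phase in every cycle, jitter independent of cycle number
        t, x = sinusoid(40.0, dur=10.0)
        bs = band_analytic(x, FS, "slow_gamma", times=t)
        period = 1 / 40.0
        times = []
        for k, n in zip((0, 1, 2, 3, 4), (6, 6, 10, 6, 6)):  # max at cycle 2
            ph = (0.3 + rng.uniform(-0.5, 0.5, n)) % TWO_PI
            times.extend(5.0 + k * period + ph / TWO_PI * period)
        spikes = SpikeSet({0: np.sort(np.array(times))})
        ev = _Event(5.0, 5.0 + 5 * period + 0.002)
        out = gamma_cycle_analysis(ev, spikes, bs)
        assert out is not None
        assert out["circ_linear_corr"] < 0.35


class TestSpikePhaseByLocation:
    def test_categories_and_planted_shift(self, geometry, rng):
        from placeseq.preprocess import RateMap

        # three units peaking early/middle/late on the start->goal segment
        goal = geometry.goal_angle
        span = goal % TWO_PI
        peaks = [span / 6, span / 2, 5 * span / 6]
        edges = np.linspace(0, TWO_PI, 91)
        centers = (edges[:-1] + edges[1:]) / 2
        rates = np.zeros((3, 90))
        for i, p in enumerate(peaks):
            rates[i, np.argmin(np.abs(centers - p))] = 5.0
        maps = RateMap(edges, [0, 1, 2], rates, np.ones(90), np.ones(90),
                       np.zeros((3, 90)))
        t, x = sinusoid(8.0, dur=20.0)
        bs = band_analytic(x, FS, "theta", times=t)
        # each unit spikes at a fixed theta phase inside one sequence window
        period = 0.125
        def at_phase(ph, n=40):
            k = np.arange(10, 10 + n)
            return k * period + ph / TWO_PI * period
        spikes = SpikeSet({0: at_phase(0.5), 1: at_phase(2.0), 2: at_phase(3.5)})
        events = [_Event(1.0, 9.0, location_to_stop=-7.0)]
        out = spike_phase_by_location(events, spikes, maps, bs, geometry)
        assert out["Early"]["n_spikes"] > 0
        assert out["Early"]["circular_mean"] == pytest.approx(0.5, abs=0.2)
        assert out["Middle"]["circular_mean"] == pytest.approx(2.0, abs=0.2)
        assert out["Late"]["circular_mean"] == pytest.approx(3.5, abs=0.2)

    def test_sequences_outside_window_excluded(self, geometry):
        from placeseq.preprocess import RateMap

        edges = np.linspace(0, TWO_PI, 91)
        rates = np.zeros((1, 90)); rates[0, 5] = 5.0
        maps = RateMap(edges, [0], rates, np.ones(90), np.ones(90), np.zeros((1, 90)))
        t, x = sinusoid(8.0, dur=5.0)
        bs = band_analytic(x, FS, "theta", times=t)
        spikes = SpikeSet({0: np.array([1.0, 2.0])})
        events = [_Event(0.5, 4.0, location_to_stop=-2.0)]  # outside -10..-5
        out = spike_phase_by_location(events, spikes, maps, bs, geometry)
        assert all(v["n_spikes"] == 0 for v in out.values())
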