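"""LFP band analysis: filtering, Hilbert power/phase, theta cycles, gamma shifts.

Frequency bands: theta 6-10 Hz, slow gamma 25-55 Hz, fast gamma 60-100 Hz,
ripple 150-250 Hz. Band power is the squared Hilbert envelope of the
zero-phase bandpass-filtered trace, z-normalized over the movement mask
(speed >= 5 cm/s outside the rest box). Phase is the analytic-signal
angle wrapped to [0, 2*pi), 0 at the oscillation peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .circstats import circ_linear_corr, circular_distance, resultant_length
from .preprocess import RateMap
from .session import TWO_PI, LFPSet, PositionSeries, SpikeSet, TaskGeometry

BANDS = {
    "theta": (6.0, 10.0),
    "slow_gamma": (25.0, 55.0),
    "fast_gamma": (60.0, 100.0),
    "ripple": (150.0, 250.0),
}

PHASE_BIN_DEG = 30.0


@dataclass
class BandSeries:
    """One channel filtered to one band: envelope, phase, normalized power."""

    band: str
    times: np.ndarray
    fs: float
    filtered: np.ndarray
    envelope: np.ndarray
    phase: np.ndarray  # [0, 2*pi), 0 at oscillation peak
    power_z: np.ndarray | None = None

    def phase_at(self, t) -> np.ndarray:
        """Phase at arbitrary times (nearest-sample lookup)."""
        idx = np.clip(
            np.round((np.asarray(t, dtype=float) - self.times[0]) * self.fs).astype(int),
            0,
            self.times.size - 1,
        )
        return self.phase[idx]

    def envelope_at(self, t) -> np.ndarray:
        idx = np.clip(
            np.round((np.asarray(t, dtype=float) - self.times[0]) * self.fs).astype(int),
            0,
            self.times.size - 1,
        )
        return self.envelope[idx]


def movement_mask(
    lfp_times: np.ndarray,
    position: PositionSeries,
    geometry: TaskGeometry | None = None,
    speed_min: float = 5.0,
) -> np.ndarray:
    """Samples where the rat moves >= speed_min cm/s outside the rest box."""
    speed = np.interp(lfp_times, position.times, position.speeds)
    mask = speed >= speed_min
    if geometry is not None:
        ang = position.angle_at(lfp_times)
        mask &= circular_distance(ang, geometry.restbox_angle) > geometry.site_spacing / 2
    return mask


def band_analytic(
    trace: np.ndarray,
    fs: float,
    band: str | tuple[float, float],
    times: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    order: int = 4,
) -> BandSeries:
    """Zero-phase bandpass + analytic signal for one channel.

    The filter is a Butterworth bandpass applied forward and backward
    (``sosfiltfilt``), so there is no group delay: the phase at a local
    maximum of the filtered trace is ~0. Power z-normalization uses
    ``mask`` (the movement mask) when given.
    """
    name, (lo, hi) = (band, BANDS[band]) if isinstance(band, str) else ("custom", band)
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz exceeds Nyquist ({fs / 2} Hz)")
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filt = sosfiltfilt(sos, np.asarray(trace, dtype=float))
    analytic = hilbert(filt)
    env = np.abs(analytic)
    phase = np.angle(analytic) % TWO_PI
    power = env**2
    power_z = None
    if mask is not None and mask.any():
        mu, sd = power[mask].mean(), power[mask].std()
        power_z = (power - mu) / sd if sd > 0 else np.zeros_like(power)
    if times is None:
        times = np.arange(filt.size) / fs
    return BandSeries(
        band=name, times=times, fs=fs, filtered=filt, envelope=env, phase=phase,
        power_z=power_z,
    )


def select_theta_channel(lfp: LFPSet, mask: np.ndarray, eligible=None) -> int:
    """Channel with the highest mean raw theta power over the movement mask.

    ``eligible`` restricts to channels (tetrodes) with place cells; ties
    break deterministically toward the lowest channel id.
    """
    ids = list(lfp.channel_ids) if eligible is None else list(eligible)
    if not ids:
        raise ValueError("no eligible channels")
    best, best_power = ids[0], -np.inf
    for ch in ids:
        col = lfp.channel_ids.index(ch)
        bs = band_analytic(lfp.traces[:, col], lfp.fs, "theta", times=lfp.times)
        p = float((bs.envelope[mask] ** 2).mean())
        if p > best_power + 1e-12:
            best, best_power = ch, p
    return best


@dataclass
class ThetaCycles:
    """Theta cycle segmentation: boundaries at the minimum-spiking phase."""

    boundaries: np.ndarray  # cycle edge times, strictly increasing
    cut_phase: float  # radians
    spike_counts: np.ndarray | None = None
    mean_speeds: np.ndarray | None = None

    @property
    def n_cycles(self) -> int:
        return max(self.boundaries.size - 1, 0)

    def durations(self) -> np.ndarray:
        return np.diff(self.boundaries)


def segment_theta_cycles(
    theta: BandSeries,
    spikes: SpikeSet,
    position: PositionSeries | None = None,
    run_epochs: list[tuple[float, float]] | None = None,
    phase_bin_deg: float = PHASE_BIN_DEG,
) -> ThetaCycles:
    """Cut theta cycles at the phase with the fewest spikes.

    All cells' run-period spikes are histogrammed by theta phase (30-deg
    bins); the cut phase is the center of the minimum-count bin (typically
    at or near the theta peak), and cycle boundaries are the successive
    crossings of that phase.
    """
    st = spikes.merged_times()
    if run_epochs is not None:
        keep = np.zeros(st.size, dtype=bool)
        for a, b in run_epochs:
            keep |= (st >= a) & (st < b)
        st = st[keep]
    if st.size == 0:
        raise ValueError("no spikes to locate the low-spiking theta phase")
    phases = theta.phase_at(st)
    n_bins = int(round(360.0 / phase_bin_deg))
    hist, edges = np.histogram(phases, bins=n_bins, range=(0.0, TWO_PI))
    k = int(np.argmin(hist))
    cut = float((edges[k] + edges[k + 1]) / 2.0)

    # boundary times: crossings of the cut phase in the unwrapped phase
    unwrapped = np.unwrap(theta.phase)
    targets = np.arange(
        np.ceil((unwrapped[0] - cut) / TWO_PI), np.floor((unwrapped[-1] - cut) / TWO_PI) + 1
    ) * TWO_PI + cut
    idx = np.searchsorted(unwrapped, targets)
    keep = (idx > 0) & (idx < unwrapped.size)
    idx, tgt = idx[keep], targets[keep]
    # linear interpolation between the bracketing samples
    x0, x1 = unwrapped[idx - 1], unwrapped[idx]
    t0, t1 = theta.times[idx - 1], theta.times[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(x1 > x0, (tgt - x0) / (x1 - x0), 0.0)
    boundaries = np.sort(t0 + f * (t1 - t0))

    counts = None
    speeds = None
    if boundaries.size > 1:
        counts = np.histogram(st, bins=boundaries)[0]
        if position is not None and position.speeds is not None:
            mids = (boundaries[:-1] + boundaries[1:]) / 2.0
            speeds = position.speed_at(mids)
    return ThetaCycles(
        boundaries=boundaries, cut_phase=cut, spike_counts=counts, mean_speeds=speeds
    )


def spike_phase_by_location(
    events,
    spikes: SpikeSet,
    maps: RateMap,
    theta: BandSeries,
    geometry: TaskGeometry,
    window_sites: tuple[float, float] = (-10.0, -5.0),
    phase_bin_deg: float = PHASE_BIN_DEG,
) -> dict:
    """Theta-phase histograms for Early/Middle/Late place cells.

    The track from the rest-box exit to the goal is split into three equal
    segments; each unit is assigned Early/Middle/Late by its peak-rate
    position. Only spikes inside sequences whose midpoint location lies in
    ``window_sites`` (10 to 5 sites before the goal by default) contribute.
    Returns per-category phase probability histograms (30-deg bins) and
    circular means.
    """
    start = geometry.restbox_angle
    goal = geometry.goal_angle
    span = (goal - start) % TWO_PI
    if span <= 0:
        raise ValueError("goal at the track start: location segments are empty")
    seg_edges = start + span * np.array([0.0, 1 / 3, 2 / 3, 1.0])

    peak_angles = maps.bin_centers[maps.peak_bins()]
    categories = {}
    for uid, pa in zip(maps.unit_ids, peak_angles):
        d = (pa - start) % TWO_PI
        if d >= span:
            categories[uid] = None  # beyond the goal; not part of the trajectory
        else:
            categories[uid] = ("Early", "Middle", "Late")[min(int(3 * d / span), 2)]

    lo, hi = window_sites
    n_bins = int(round(360.0 / phase_bin_deg))
    out = {cat: [] for cat in ("Early", "Middle", "Late")}
    for ev in events:
        if not (lo <= ev.location_to_stop <= hi):
            continue
        for uid in maps.unit_ids:
            cat = categories.get(uid)
            if cat is None:
                continue
            st = spikes.trains.get(uid, np.empty(0))
            st = st[(st >= ev.t_start) & (st < ev.t_end)]
            if st.size:
                out[cat].extend(theta.phase_at(st).tolist())
    result = {}
    for cat, phases in out.items():
        phases = np.asarray(phases)
        hist = np.histogram(phases, bins=n_bins, range=(0.0, TWO_PI))[0].astype(float)
        total = hist.sum()
        result[cat] = {
            "hist": hist / total if total > 0 else hist,
            "n_spikes": int(phases.size),
            "circular_mean": float(np.angle(np.exp(1j * phases).sum()) % TWO_PI)
            if phases.size
            else float("nan"),
        }
    return result


def gamma_cycle_analysis(
    event,
    spikes: SpikeSet,
    gamma: BandSeries,
    theta: BandSeries | None = None,
    band: str = "slow_gamma",
    phase_bin_deg: float = PHASE_BIN_DEG,
) -> dict | None:
    """Gamma phase shift across successive gamma cycles within one sequence.

    Gamma cycles inside the sequence are numbered relative to the cycle
    with maximal ensemble spiking (cycle 0); incomplete edge cycles are
    dropped, and the retained range is cycles -1..1 for slow gamma and
    -2..2 for fast gamma. Returns the (cycle number, gamma phase) spike
    samples, their circular-linear correlation and resultant length, and a
    5x5-box-smoothed theta-by-gamma phase histogram (30-deg bins).
    Returns None when the event contains no complete gamma cycle.
    """
    max_cycles = 3 if band == "slow_gamma" else 5
    half = max_cycles // 2
    i0 = np.searchsorted(gamma.times, event.t_start)
    i1 = np.searchsorted(gamma.times, event.t_end)
    if i1 - i0 < 2:
        return None
    unwrapped = np.unwrap(gamma.phase[i0:i1])
    tloc = gamma.times[i0:i1]
    # complete cycles: consecutive multiples of 2*pi fully inside the event
    k0 = int(np.ceil(unwrapped[0] / TWO_PI))
    k1 = int(np.floor(unwrapped[-1] / TWO_PI))
    if k1 - k0 < 1:
        return None
    edge_targets = np.arange(k0, k1 + 1) * TWO_PI
    edge_times = np.interp(edge_targets, unwrapped, tloc)

    st = spikes.merged_times()
    st = st[(st >= edge_times[0]) & (st < edge_times[-1])]
    if st.size == 0:
        return None
    cyc = np.searchsorted(edge_times, st, side="right") - 1
    counts = np.bincount(cyc, minlength=edge_times.size - 1)
    cycle0 = int(np.argmax(counts))
    rel = cyc - cycle0
    keep = np.abs(rel) <= half
    if keep.sum() < 3 or np.ptp(rel[keep]) == 0:
        return None
    g_phase = gamma.phase_at(st[keep])
    corr = circ_linear_corr(g_phase, rel[keep].astype(float))
    rlen = resultant_length(g_phase)
    hist2d = None
    if theta is not None:
        t_phase = theta.phase_at(st[keep])
        n_bins = int(round(360.0 / phase_bin_deg))
        h = np.histogram2d(
            t_phase, g_phase, bins=n_bins, range=[[0, TWO_PI], [0, TWO_PI]]
        )[0]
        # 5x5 box smoothing with wrap-around on both phase axes
        from scipy.ndimage import uniform_filter

        hist2d = uniform_filter(h, size=5, mode="wrap")
    return {
        "cycle_numbers": rel[keep],
        "gamma_phases": g_phase,
        "circ_linear_corr": corr,
        "resultant_length": rlen,
        "hist2d": hist2d,
        "cycle0_index": cycle0,
        "n_complete_cycles": int(edge_times.size - 1),
    }
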