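"""Sharp wave-ripple detection, replay qualification, and goal-bias statistics.

SWRs are detected in rest-box periods from the 150-250 Hz Hilbert envelope
smoothed with a 25-ms Gaussian: events are stretches exceeding the mean by
5 SDs for at least 50 ms, with boundaries widened to the first crossings
of the mean, merged across channels. A SWR qualifies as a replay event if
the circular-linear fit to its decoded posterior has r^2 > 0.5, fewer than
20% of its time bins are spike-free, and its spike-trimmed duration
exceeds 50 ms; the slope sign classifies it as forward or reverse.

The termination-bias test asks whether replay preferentially ends at the
learned goal: the last time bin's posterior of every event, aligned so the
goal is location 0 and aggregated onto the reward-site grid, is summed
across events, and compared with a null built by circularly rotating each
event's entire posterior by an independent random angle (5,000 shuffles by
default). A location is significant where the observed sum exceeds the
97.5th percentile of its null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .circstats import CircLinearFit, bootstrap_ci, circ_linear_fit, matthews_multiclass
from .decoder import PosteriorMatrix, bin_spikes, decode_posterior
from .lfp import band_analytic
from .preprocess import RateMap
from .session import TWO_PI, LFPSet, SpikeSet, TaskGeometry

SWR_THRESHOLD_SD = 5.0
SWR_MIN_DURATION = 0.050  # s
SWR_SMOOTH_SD = 0.025  # s
REPLAY_R2_MIN = 0.5
REPLAY_EMPTY_MAX = 0.20
REPLAY_MIN_DURATION = 0.050  # s
SLOPE_RANGE_REPLAY = (-60.0, 60.0)  # rad/s
N_SHUFFLES_DEFAULT = 5000


@dataclass
class SWREvent:
    """One detected sharp wave-ripple."""

    t_start: float  # mean-crossing-adjusted boundaries
    t_end: float
    core_start: float  # supra-threshold core
    core_end: float
    peak_z: float
    channels: list[int] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ReplayEvent:
    """A qualified replay event inside a SWR."""

    swr: SWREvent
    t_start: float  # trimmed to first/last occupied windows
    t_end: float
    fit: CircLinearFit
    direction: str  # 'forward' | 'reverse'
    empty_fraction: float
    posterior: PosteriorMatrix  # trimmed clip
    end_site: int
    start_site: int
    rest_id: int = -1
    block: str = ""
    outcome: str = ""
    stop_site: int = -1

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def r2(self) -> float:
        return self.fit.r2


@dataclass
class BiasResult:
    """Goal-aligned terminal posterior sums against a circular-shift null."""

    locations: np.ndarray  # site offsets from the goal
    observed: np.ndarray
    null_lo: np.ndarray  # 2.5th percentile per location
    null_hi: np.ndarray  # 97.5th percentile per location
    significant: np.ndarray  # observed > null_hi
    n_events: int
    n_shuffles: int
    seed: int
    end: str = "last"

    def significant_locations(self) -> np.ndarray:
        return self.locations[self.significant]


def _detect_on_envelope(env_z, times, mean_level, rest_mask, fs):
    """Supra-threshold stretches >= 50 ms widened to mean crossings."""
    above = (env_z > SWR_THRESHOLD_SD) & rest_mask
    idx = np.flatnonzero(above)
    events = []
    if idx.size == 0:
        return events
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    min_samples = int(round(SWR_MIN_DURATION * fs))
    below_mean = env_z <= mean_level
    for s, e in zip(starts, ends):
        if e - s + 1 < min_samples:
            continue
        a = s
        while a > 0 and not below_mean[a - 1] and rest_mask[a - 1]:
            a -= 1
        b = e
        while b < env_z.size - 1 and not below_mean[b + 1] and rest_mask[b + 1]:
            b += 1
        events.append(
            SWREvent(
                t_start=float(times[a]),
                t_end=float(times[b]),
                core_start=float(times[s]),
                core_end=float(times[e]),
                peak_z=float(env_z[s : e + 1].max()),
            )
        )
    return events


def detect_swr(
    lfp: LFPSet,
    rest_windows: list[tuple[float, float]],
    channels=None,
) -> list[SWREvent]:
    """Detect SWRs during rest on each eligible channel, merging overlaps.

    The ripple-band (150-250 Hz) Hilbert envelope is smoothed with a
    Gaussian kernel (SD 25 ms); the mean and SD defining the 5-SD
    threshold are estimated over the rest mask. Events overlapping in time
    across channels are merged (union of intervals).
    """
    if not rest_windows:
        raise ValueError("rest mask is empty")
    total_rest = sum(e - s for s, e in rest_windows)
    if total_rest < 10.0:
        import warnings

        warnings.warn("rest mask shorter than 10 s; envelope SD estimate is unstable")
    rest_mask = np.zeros(lfp.times.size, dtype=bool)
    for s, e in rest_windows:
        rest_mask |= (lfp.times >= s) & (lfp.times < e)

    channels = channels if channels is not None else lfp.channel_ids
    per_channel: list[SWREvent] = []
    for ch in channels:
        col = lfp.channel_ids.index(ch)
        bs = band_analytic(lfp.traces[:, col], lfp.fs, "ripple", times=lfp.times)
        env = gaussian_filter1d(bs.envelope, SWR_SMOOTH_SD * lfp.fs)
        mu = env[rest_mask].mean()
        sd = env[rest_mask].std()
        env_z = (env - mu) / sd
        mean_level = 0.0  # mean amplitude in z units
        for ev in _detect_on_envelope(env_z, lfp.times, mean_level, rest_mask, lfp.fs):
            ev.channels = [ch]
            per_channel.append(ev)

    # merge time-overlapping events across channels
    per_channel.sort(key=lambda ev: ev.t_start)
    merged: list[SWREvent] = []
    for ev in per_channel:
        if merged and ev.t_start <= merged[-1].t_end:
            last = merged[-1]
            last.t_end = max(last.t_end, ev.t_end)
            last.core_start = min(last.core_start, ev.core_start)
            last.core_end = max(last.core_end, ev.core_end)
            last.peak_z = max(last.peak_z, ev.peak_z)
            last.channels = sorted(set(last.channels) | set(ev.channels))
        else:
            merged.append(ev)
    return merged


def qualify_replay(
    swr: SWREvent,
    spikes: SpikeSet,
    maps: RateMap,
    geometry: TaskGeometry,
    tau: float = 0.040,
    step: float = 0.010,
    slope_range=SLOPE_RANGE_REPLAY,
) -> ReplayEvent | None:
    """Decode a SWR's spiking and apply the replay qualification rules.

    Windows are clipped to the SWR, trimmed to the first/last occupied
    windows, and a circular-linear line is fitted to the posterior.
    Accepts iff r^2 > 0.5, < 20% empty windows, trimmed duration > 50 ms.
    The end (start) site is the last (first) occupied window's posterior
    argmax snapped to the reward-site grid.
    """
    counts = bin_spikes(spikes, (swr.t_start, swr.t_end), tau=tau, step=step)
    if counts.n_windows == 0:
        return None
    occupied = counts.total_per_window() > 0
    if not occupied.any():
        return None
    first, last = np.flatnonzero(occupied)[[0, -1]]
    counts.centers = counts.centers[first : last + 1]
    counts.counts = counts.counts[first : last + 1]
    occupied = occupied[first : last + 1]
    duration = (counts.n_windows - 1) * step + tau
    if duration <= REPLAY_MIN_DURATION:
        return None
    empty_fraction = float(1.0 - occupied.mean())
    if empty_fraction >= REPLAY_EMPTY_MAX:
        return None
    posterior = decode_posterior(counts, maps)
    t = posterior.centers - posterior.centers[0]
    n_bins = posterior.bin_centers.size
    tt = np.repeat(t, n_bins)
    th = np.tile(posterior.bin_centers, counts.n_windows)
    w = posterior.probabilities.ravel()
    fit = circ_linear_fit(tt, th, weights=w, slope_range=slope_range)
    if fit.r2 <= REPLAY_R2_MIN:
        return None
    end_angle = posterior.bin_centers[int(np.argmax(posterior.probabilities[-1]))]
    start_angle = posterior.bin_centers[int(np.argmax(posterior.probabilities[0]))]
    return ReplayEvent(
        swr=swr,
        t_start=float(posterior.centers[0] - tau / 2),
        t_end=float(posterior.centers[-1] + tau / 2),
        fit=fit,
        direction="forward" if fit.slope >= 0 else "reverse",
        empty_fraction=empty_fraction,
        posterior=posterior,
        end_site=int(geometry.nearest_site(end_angle)),
        start_site=int(geometry.nearest_site(start_angle)),
    )


def _site_aggregation_matrix(bin_centers: np.ndarray, geometry: TaskGeometry) -> np.ndarray:
    """(n_bins, n_sites) 0/1 matrix assigning each decoding bin to its nearest site."""
    sites = geometry.nearest_site(bin_centers)
    mat = np.zeros((bin_centers.size, geometry.n_sites))
    mat[np.arange(bin_centers.size), sites] = 1.0
    return mat


def termination_bias(
    replays: list[ReplayEvent],
    geometry: TaskGeometry,
    goal_site: int | None = None,
    end: str = "last",
    n_shuffles: int = N_SHUFFLES_DEFAULT,
    seed: int = 0,
) -> BiasResult:
    """Goal-aligned terminal posterior sums vs a circular-shift null.

    Each event's time axis is normalized to [0, 1]; the terminal window's
    posterior (``end='last'`` for termination, ``'first'`` for initiation)
    is aggregated onto the site grid, rotated so the goal is location 0,
    and summed across events. The null rotates each event's entire
    (site-aggregated) posterior by an independent uniform circular shift
    on the site grid — site-step granularity makes the permutation
    distribution exchangeable with location-unbiased replay and conserves
    each event's mass exactly. Significance is upper-tail at the 97.5th
    percentile per location.
    """
    if not replays:
        raise ValueError("termination_bias requires at least one replay event")
    if n_shuffles < 100:
        import warnings

        warnings.warn("fewer than 100 shuffles: confidence bounds are unstable")
    goal = goal_site if goal_site is not None else geometry.goal_site
    n_sites = geometry.n_sites
    rng = np.random.default_rng(seed)

    terminal = np.stack(
        [
            ev.posterior.probabilities[0 if end == "first" else -1]
            for ev in replays
        ]
    )  # (E, n_bins)
    agg = _site_aggregation_matrix(replays[0].posterior.bin_centers, geometry)
    site_mass = terminal @ agg  # (E, n_sites)

    # all site-step rotations of each event's terminal site profile
    # rot_tables[e, r, s]: event e rotated forward by r sites, mass at site s
    rot_tables = np.stack(
        [np.roll(site_mass, r, axis=1) for r in range(n_sites)], axis=1
    )  # (E, n_sites, n_sites)

    def align(profile_sites):
        """Rotate the site profile so the goal sits at offset 0."""
        return np.roll(profile_sites, -goal, axis=-1)

    observed = align(site_mass.sum(axis=0))
    shifts = rng.integers(0, n_sites, size=(n_shuffles, len(replays)))
    shuffled = rot_tables[np.arange(len(replays))[None, :], shifts, :].sum(axis=1)
    shuffled = align(shuffled)
    null_lo, null_hi = np.percentile(shuffled, [2.5, 97.5], axis=0)
    # offsets centered on the goal: 0, 1, ..., then wrapped negatives
    offsets = np.arange(n_sites)
    offsets = np.where(offsets > n_sites // 2, offsets - n_sites, offsets)
    order = np.argsort(offsets)
    return BiasResult(
        locations=offsets[order],
        observed=observed[order],
        null_lo=null_lo[order],
        null_hi=null_hi[order],
        significant=(observed > null_hi)[order],
        n_events=len(replays),
        n_shuffles=n_shuffles,
        seed=seed,
        end=end,
    )


def end_vs_stop_correlation(
    replays: list[ReplayEvent],
    geometry: TaskGeometry,
    offset_range: int = 3,
    n_resamples: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Matthews correlation between replay end locations and actual stops.

    Events must carry ``block`` ('trials 1-4', 'trials 5-8', 'post-test')
    and the trial's actual ``stop_site``. Builds, per block, a confusion
    matrix of (replay end offset x actual stop offset) over offsets
    -offset_range..offset_range from the goal, and reports the multiclass
    MCC with a percentile bootstrap CI. Blocks whose MCC is undefined
    (degenerate marginals, e.g. no error trials) are flagged NaN.
    """
    goal = geometry.goal_site
    n_off = 2 * offset_range + 1

    def offset_of(site):
        d = (site - goal) % geometry.n_sites
        if d > geometry.n_sites // 2:
            d -= geometry.n_sites
        return int(np.clip(d, -offset_range, offset_range))

    rows = []
    for block in ("trials 1-4", "trials 5-8", "post-test"):
        evs = [e for e in replays if e.block == block and e.stop_site >= 0]
        if not evs:
            rows.append({"block": block, "mcc": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan, "n_events": 0})
            continue
        pairs = np.array(
            [(offset_of(e.end_site) + offset_range, offset_of(e.stop_site) + offset_range)
             for e in evs]
        )
        cm = np.zeros((n_off, n_off))
        np.add.at(cm, (pairs[:, 0], pairs[:, 1]), 1.0)
        mcc = matthews_multiclass(cm)
        if np.isnan(mcc) or len(evs) < 2:
            ci_lo = ci_hi = np.nan
        else:
            def stat(idx_vals):
                idx = idx_vals.astype(int)
                sub = np.zeros((n_off, n_off))
                np.add.at(sub, (pairs[idx, 0], pairs[idx, 1]), 1.0)
                m = matthews_multiclass(sub)
                return 0.0 if np.isnan(m) else m

            ci_lo, ci_hi = bootstrap_ci(
                np.arange(len(evs)), stat, n_resamples=n_resamples, seed=seed
            )
        rows.append({"block": block, "mcc": mcc, "ci_lo": ci_lo, "ci_hi": ci_hi,
                     "n_events": len(evs)})
    return pd.DataFrame(rows)


def replays_to_frame(replays: list[ReplayEvent]) -> pd.DataFrame:
    rows = []
    for e in replays:
        rows.append(
            {
                "t_start": e.t_start, "t_end": e.t_end, "duration": e.duration,
                "slope": e.fit.slope, "direction": e.direction, "r2": e.r2,
                "empty_fraction": e.empty_fraction, "end_site": e.end_site,
                "start_site": e.start_site, "peak_z": e.swr.peak_z,
                "rest_id": e.rest_id, "block": e.block, "outcome": e.outcome,
                "stop_site": e.stop_site,
            }
        )
    return pd.DataFrame(rows)
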