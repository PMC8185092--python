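"""Speed estimation, position tuning (rate maps), and unit selection.

The rate map is the decoder's encoding model f_i(x): occupancy-normalized,
circularly smoothed firing rate of each unit over uniform angular bins.
Defaults follow the analysis conventions: 0.07-rad bins (realized as the
nearest uniform circular partition, 90 bins of width 2*pi/90 ~ 0.0698 rad),
Gaussian smoothing with SD 0.14 rad applied on the circle, and a 5 cm/s
movement threshold for both occupancy and spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d

from .session import TWO_PI, PositionSeries, SpikeSet, TaskGeometry

N_BINS_DEFAULT = int(np.ceil(TWO_PI / 0.07))  # 90
SPEED_MIN_DEFAULT = 5.0  # cm/s
KERNEL_SD_DEFAULT = 0.14  # rad
INTERNEURON_RATE_MAX = 5.0  # Hz; mean rate above this = putative interneuron
GOAL_ACTIVE_PEAK_MIN = 0.5  # Hz


def estimate_speed(position: PositionSeries, track_radius: float = 50.0) -> np.ndarray:
    """Running speed (cm/s) by central differences of the unwrapped angle.

    Speed at sample n uses (X_{n+1} - X_{n-1}) / (t_{n+1} - t_{n-1});
    endpoints use one-sided differences. Fills ``position.speeds`` in place
    and returns the array.
    """
    t = position.times
    if t.size < 3:
        raise ValueError("need at least 3 position samples")
    x = position.unwrapped * track_radius  # cm along the track
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) / (t[2:] - t[:-2])
    v[0] = (x[1] - x[0]) / (t[1] - t[0])
    v[-1] = (x[-1] - x[-2]) / (t[-1] - t[-2])
    v = np.abs(v)
    position.speeds = v
    return v


def circular_gaussian_kernel(sd_bins: float, n_bins: int) -> np.ndarray:
    """Unit-mass Gaussian kernel sampled on the circular bin grid."""
    half = n_bins // 2
    offs = np.arange(-half, n_bins - half)
    k = np.exp(-0.5 * (offs / sd_bins) ** 2)
    return k / k.sum()


def smooth_circular(values: np.ndarray, sd_bins: float) -> np.ndarray:
    """Circular (wrap-around) Gaussian smoothing along the last axis."""
    values = np.asarray(values, dtype=float)
    kernel = circular_gaussian_kernel(sd_bins, values.shape[-1])
    return convolve1d(values, kernel, axis=-1, mode="wrap")


@dataclass
class RateMap:
    """Smoothed position tuning f_i(x) per unit on a uniform circular grid.

    rates : (n_units, n_bins) Hz, NaN where occupancy is undefined.
    occupancy : smoothed seconds per bin (what the rates were divided by).
    occupancy_raw : unsmoothed seconds per bin.
    """

    bin_edges: np.ndarray
    unit_ids: list[int]
    rates: np.ndarray
    occupancy: np.ndarray
    occupancy_raw: np.ndarray
    spike_counts: np.ndarray = field(default=None)

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def peak_rates(self) -> np.ndarray:
        return np.nanmax(self.rates, axis=1)

    def peak_bins(self) -> np.ndarray:
        return np.nanargmax(self.rates, axis=1)

    def unit_index(self, unit_ids) -> np.ndarray:
        lookup = {u: i for i, u in enumerate(self.unit_ids)}
        return np.array([lookup[u] for u in unit_ids], dtype=int)

    def subset(self, unit_ids) -> "RateMap":
        idx = self.unit_index(unit_ids)
        return RateMap(
            bin_edges=self.bin_edges,
            unit_ids=list(unit_ids),
            rates=self.rates[idx],
            occupancy=self.occupancy,
            occupancy_raw=self.occupancy_raw,
            spike_counts=self.spike_counts[idx] if self.spike_counts is not None else None,
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.rates.T, index=self.bin_centers, columns=self.unit_ids
        ).rename_axis("angle_rad")


def compute_rate_map(
    spikes: SpikeSet,
    position: PositionSeries,
    speed_min: float = SPEED_MIN_DEFAULT,
    epoch: tuple[float, float] | None = None,
    n_bins: int = N_BINS_DEFAULT,
    kernel_sd: float = KERNEL_SD_DEFAULT,
    restbox_angle: float | None = None,
    restbox_halfwidth: float = 0.0995,
    smooth_ratio: bool = False,
) -> RateMap:
    """Occupancy-normalized, circularly smoothed rate map per unit.

    Spikes and occupancy are restricted to times with speed > ``speed_min``
    inside ``epoch``; samples within ``restbox_halfwidth`` of
    ``restbox_angle`` are masked out (the rest box is not part of the track
    tuning). Spike counts and occupancy are smoothed separately with a
    wrap-around Gaussian kernel (SD ``kernel_sd`` rad) before division; set
    ``smooth_ratio`` to smooth the unsmoothed ratio instead. Bins with zero
    (smoothed) occupancy carry NaN rates.
    """
    if position.speeds is None:
        raise ValueError("position.speeds not set; run estimate_speed first")
    t = position.times
    if epoch is None:
        epoch = (t[0], t[-1] + 1e-9)
    in_epoch = (t >= epoch[0]) & (t < epoch[1])
    moving = position.speeds > speed_min
    mask = in_epoch & moving
    if restbox_angle is not None:
        from .circstats import circular_distance

        mask &= circular_distance(position.angles, restbox_angle) > restbox_halfwidth

    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    dt = np.empty_like(t)
    dt[:-1] = np.diff(t)
    dt[-1] = dt[-2] if t.size > 1 else 0.0
    occ, _ = np.histogram(position.angles[mask], bins=edges, weights=dt[mask])
    if occ.sum() <= 0:
        raise ValueError("zero total occupancy under the speed/epoch filter")

    unit_ids = spikes.unit_ids
    counts = np.zeros((len(unit_ids), n_bins))
    # a spike is kept if the nearest position sample passes the mask
    for i, uid in enumerate(unit_ids):
        st = spikes.trains[uid]
        st = st[(st >= epoch[0]) & (st < epoch[1])]
        if st.size == 0:
            continue
        idx = np.clip(np.searchsorted(t, st), 0, t.size - 1)
        keep = mask[idx]
        ang = position.angle_at(st[keep])
        counts[i], _ = np.histogram(ang, bins=edges)

    sd_bins = kernel_sd / (TWO_PI / n_bins)
    if smooth_ratio:
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(occ > 0, counts / occ, np.nan)
        rates = smooth_circular(np.nan_to_num(raw), sd_bins)
        occ_s = occ
    else:
        counts_s = smooth_circular(counts, sd_bins)
        occ_s = smooth_circular(occ, sd_bins)
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = np.where(occ_s > 0, counts_s / occ_s, np.nan)
    return RateMap(
        bin_edges=edges,
        unit_ids=unit_ids,
        rates=rates,
        occupancy=occ_s,
        occupancy_raw=occ,
        spike_counts=counts,
    )


def select_units(
    maps_post: RateMap,
    spikes: SpikeSet,
    geometry: TaskGeometry,
    seed: int = 0,
) -> dict:
    """Retain the decodable unit set: drop interneurons, equalize goal over-representation.

    Units with session mean rate > 5 Hz are excluded as putative fast-spiking
    interneurons. Among the rest, "goal-active" units (peak rate > 0.5 Hz
    within half a site spacing of the goal, on the post-pre-running map) are
    randomly downsampled (seeded) to match the count of units active
    elsewhere on the track (excluding the rest box), so that goal
    over-representation cannot bias decoding.

    Returns dict with keys: retained, interneurons, downsampled.
    """
    from .circstats import circular_distance

    mean_rates = spikes.mean_rates()
    ids = [u for u in maps_post.unit_ids if u in mean_rates]
    interneurons = [u for u in ids if mean_rates[u] > INTERNEURON_RATE_MAX]
    kept = [u for u in ids if u not in set(interneurons)]

    centers = maps_post.bin_centers
    half = geometry.site_spacing / 2.0
    goal_bins = circular_distance(centers, geometry.goal_angle) <= half
    restbox_bins = circular_distance(centers, geometry.restbox_angle) <= half
    elsewhere_bins = ~goal_bins & ~restbox_bins

    idx = maps_post.unit_index(kept)
    rates = np.nan_to_num(maps_post.rates[idx])
    goal_peak = rates[:, goal_bins].max(axis=1) if goal_bins.any() else np.zeros(len(kept))
    else_peak = rates[:, elsewhere_bins].max(axis=1)
    goal_active = [u for u, g in zip(kept, goal_peak) if g > GOAL_ACTIVE_PEAK_MIN]
    else_active = [u for u, e in zip(kept, else_peak) if e > GOAL_ACTIVE_PEAK_MIN]

    dropped: list[int] = []
    n_goal, n_else = len(goal_active), len(else_active)
    if n_goal > n_else:
        rng = np.random.default_rng(seed)
        dropped = sorted(rng.choice(goal_active, size=n_goal - n_else, replace=False).tolist())
    retained = [u for u in kept if u not in set(dropped)]
    if not retained:
        import warnings

        warnings.warn("unit selection retained no units; decoding will be refused")
    return {
        "retained": retained,
        "interneurons": interneurons,
        "downsampled": dropped,
        "n_goal_active": n_goal,
        "n_elsewhere_active": n_else,
    }
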