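"""Sliding-window Bayesian decoding of position from ensemble spike counts.

Position is decoded from windowed spike counts with a memoryless Poisson
model: assuming units are conditionally independent given position x with
rates f_i(x) (the rate map), the log likelihood of the count vector n in a
window of length tau is

    log P(n | x) = sum_i [ n_i * log(tau * f_i(x)) - tau * f_i(x) ]  + const

With a flat prior, the posterior P(x | n) is the normalized likelihood over
the circular bin grid. Default windows: 40 ms, stepped by 10 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .circstats import circular_distance
from .preprocess import RateMap
from .session import PositionSeries, SpikeSet

TAU_DEFAULT = 0.040  # s
STEP_DEFAULT = 0.010  # s
RATE_FLOOR = 0.01  # Hz, floor before taking logs


@dataclass
class CountMatrix:
    """Spike counts per sliding window: (n_windows, n_units)."""

    centers: np.ndarray
    tau: float
    step: float
    unit_ids: list[int]
    counts: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.centers.size

    def total_per_window(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def units_per_window(self) -> np.ndarray:
        return (self.counts > 0).sum(axis=1)


@dataclass
class PosteriorMatrix:
    """Decoded posterior P(x | n): (n_windows, n_bins), rows sum to 1."""

    centers: np.ndarray
    bin_centers: np.ndarray
    probabilities: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.centers.size

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    def argmax_bins(self) -> np.ndarray:
        # ties broken toward the lowest bin index (np.argmax convention)
        return np.argmax(self.probabilities, axis=1)

    def map_angles(self) -> np.ndarray:
        """Maximum-likelihood decoded angle per window."""
        return self.bin_centers[self.argmax_bins()]

    def clip(self, t0: float, t1: float) -> "PosteriorMatrix":
        keep = (self.centers >= t0) & (self.centers < t1)
        return PosteriorMatrix(self.centers[keep], self.bin_centers, self.probabilities[keep])


def bin_spikes(
    spikes: SpikeSet,
    epoch: tuple[float, float],
    tau: float = TAU_DEFAULT,
    step: float = STEP_DEFAULT,
) -> CountMatrix:
    """Count each unit's spikes in sliding windows [c - tau/2, c + tau/2).

    Windows tile the epoch at ``step`` spacing; the first window starts at
    the epoch start. An empty epoch yields a valid empty matrix.
    """
    if not (tau >= step > 0):
        raise ValueError("require tau >= step > 0")
    t0, t1 = epoch
    span = t1 - t0
    if span < tau:
        centers = np.empty(0)
    else:
        n_win = int(np.floor((span - tau) / step)) + 1
        centers = t0 + tau / 2.0 + step * np.arange(n_win)
    unit_ids = spikes.unit_ids
    counts = np.zeros((centers.size, len(unit_ids)), dtype=np.int64)
    starts = centers - tau / 2.0
    ends = centers + tau / 2.0
    for j, uid in enumerate(unit_ids):
        st = spikes.trains[uid]
        counts[:, j] = np.searchsorted(st, ends, side="left") - np.searchsorted(
            st, starts, side="left"
        )
    return CountMatrix(centers=centers, tau=tau, step=step, unit_ids=unit_ids, counts=counts)


def decode_posterior(counts: CountMatrix, maps: RateMap) -> PosteriorMatrix:
    """Poisson-likelihood posterior over position bins, flat prior.

    Rates are floored at 0.01 Hz before the log; bins whose rate is
    undefined for all units (zero occupancy) are excluded from the support.
    Windows with zero total spikes still produce a (broad) posterior from
    the zero-count Poisson likelihood.
    """
    if counts.unit_ids != maps.unit_ids:
        maps = maps.subset(counts.unit_ids)
    rates = maps.rates
    defined = ~np.all(np.isnan(rates), axis=0)
    if not defined.any():
        raise ValueError("no position bins with defined rates")
    f = np.nan_to_num(rates, nan=0.0)
    f = np.maximum(f, RATE_FLOOR)
    tau = counts.tau
    log_f = np.log(tau * f)  # (units, bins)
    sum_f = tau * f.sum(axis=0)  # (bins,)
    loglik = counts.counts @ log_f - sum_f[None, :]
    loglik[:, ~defined] = -np.inf
    log_post = loglik - logsumexp(loglik, axis=1, keepdims=True)
    return PosteriorMatrix(
        centers=counts.centers,
        bin_centers=maps.bin_centers,
        probabilities=np.exp(log_post),
    )


def evaluate_decoder(posterior: PosteriorMatrix, position: PositionSeries) -> dict:
    """Decoding error diagnostics against the tracked trajectory.

    Error per window = circular distance (rad, in [0, pi]) between the
    maximum-likelihood decoded bin center and the interpolated true angle.
    Also returns the cumulative error curve (sorted errors vs cumulative
    fraction) and a confusion matrix accumulating posterior mass by the
    true-position bin.
    """
    true_angles = position.angle_at(posterior.centers)
    errors = circular_distance(posterior.map_angles(), true_angles)
    order = np.sort(errors)
    cumfrac = np.arange(1, order.size + 1) / max(order.size, 1)
    n_bins = posterior.bin_centers.size
    width = posterior.bin_width
    true_bins = np.floor(true_angles / width).astype(int) % n_bins
    confusion = np.zeros((n_bins, n_bins))
    np.add.at(confusion, true_bins, posterior.probabilities)
    row_mass = confusion.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = np.where(row_mass > 0, confusion / row_mass, 0.0)
    return {
        "errors": errors,
        "median_error": float(np.median(errors)) if errors.size else float("nan"),
        "cumulative_curve": (order, cumfrac),
        "confusion": confusion,
    }
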