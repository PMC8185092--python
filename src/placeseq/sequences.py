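"""Detection and quantification of place-cell sequences during running.

A candidate sequence is a maximal run of consecutive decoding windows that
each contain at least one spike, with: run length >= 6 windows (90 ms at
40/10-ms windows), circular jumps between adjacent maximum-likelihood
positions <= 1.4 rad, first-to-last decoded displacement >= 0.07 rad, and
at least 3 distinct units and 5 spikes in the run. A candidate qualifies
as a sequence if a weighted circular-linear line fitted to its posterior
satisfies two rules: at least 60% of the total posterior mass lies within
0.35 rad of the line, and the line passes within 0.35 rad of the animal's
true position at some window. The fitted slope (rad/s) measures the
temporal compression of the represented trajectory.

Also provides the theta-cycle-restricted detection variant, the
ahead/behind/trajectory posterior sums, and the slope-by-location profile
with bootstrap CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circstats import CircLinearFit, bootstrap_ci, circ_linear_fit, circular_distance
from .decoder import CountMatrix, PosteriorMatrix
from .session import TWO_PI, PositionSeries, TaskGeometry

# detection thresholds
MIN_WINDOWS = 6
MAX_JUMP = 1.4  # rad between adjacent windows
MIN_SPAN = 0.07  # rad first-to-last
MIN_CELLS = 3
MIN_SPIKES = 5
# qualification thresholds
NEAR_LINE_RAD = 0.35
NEAR_LINE_FRACTION = 0.60
SLOPE_RANGE_RUN = (-20.0, 20.0)  # rad/s


@dataclass
class SequenceEvent:
    """One qualified place-cell sequence."""

    start_index: int
    end_index: int  # inclusive
    t_start: float
    t_end: float
    n_cells: int
    n_spikes: int
    fit: CircLinearFit
    near_line_fraction: float
    min_line_to_position: float
    location_to_stop: float  # site units, negative before the stop
    mode: str = "continuous"
    trial_id: int = -1
    phase: str = ""
    outcome: str = ""

    @property
    def slope(self) -> float:
        return self.fit.slope

    @property
    def slope_sign(self) -> str:
        return self.fit.sign

    @property
    def t_span(self) -> float:
        return self.t_end - self.t_start

    @property
    def x_span(self) -> float:
        """Trajectory length of the fitted line, |slope| * t_span (rad)."""
        return abs(self.fit.slope) * self.t_span

    def relative_x_span(self, stop_distance: float) -> float:
        """x_span normalized by the remaining distance to the stop (rad)."""
        return self.x_span / max(stop_distance, 1e-9)


def _candidate_runs(posterior: PosteriorMatrix, counts: CountMatrix):
    occupied = counts.total_per_window() > 0
    # maximal runs of consecutive occupied windows
    idx = np.flatnonzero(occupied)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts, ends))


def detect_candidates(posterior: PosteriorMatrix, counts: CountMatrix) -> list[tuple[int, int]]:
    """Candidate windows (start, end inclusive) passing all five detection rules."""
    if posterior.n_windows != counts.n_windows:
        raise ValueError("posterior and counts must share the window grid")
    out = []
    map_angles = posterior.map_angles()
    for s, e in _candidate_runs(posterior, counts):
        if e - s + 1 < MIN_WINDOWS:
            continue
        ang = map_angles[s : e + 1]
        if np.any(circular_distance(ang[1:], ang[:-1]) > MAX_JUMP):
            continue
        if circular_distance(ang[0], ang[-1]) < MIN_SPAN:
            continue
        block = counts.counts[s : e + 1]
        if (block.sum(axis=0) > 0).sum() < MIN_CELLS or block.sum() < MIN_SPIKES:
            continue
        out.append((int(s), int(e)))
    return out


def qualify_sequence(
    candidate: tuple[int, int],
    posterior: PosteriorMatrix,
    counts: CountMatrix,
    position: PositionSeries,
    stop_angle: float,
    geometry: TaskGeometry | None = None,
    slope_range=SLOPE_RANGE_RUN,
) -> SequenceEvent | None:
    """Fit a trajectory line to the candidate's posterior and apply both rules.

    The fit weighs every (window time, bin angle) pair by its posterior
    mass. Windows whose fitted position passes the stop location are kept.
    Returns the qualified SequenceEvent, or None with no event if either
    the 60%-near-line rule or the true-position proximity rule fails.
    """
    s, e = candidate
    sub = posterior.probabilities[s : e + 1]
    t = posterior.centers[s : e + 1]
    n_win, n_bins = sub.shape
    tt = np.repeat(t - t[0], n_bins)
    th = np.tile(posterior.bin_centers, n_win)
    w = sub.ravel()
    fit = circ_linear_fit(tt, th, weights=w, slope_range=slope_range)

    line = fit.predict(t - t[0])
    dist = circular_distance(th, np.repeat(line, n_bins))
    near_frac = float(w[dist <= NEAR_LINE_RAD].sum() / w.sum())
    true_angles = position.angle_at(t)
    min_d = float(np.min(circular_distance(line, true_angles)))
    if near_frac < NEAR_LINE_FRACTION or min_d > NEAR_LINE_RAD:
        return None

    block = counts.counts[s : e + 1]
    t_mid = 0.5 * (t[0] + t[-1])
    mid_angle = float(position.angle_at(t_mid))
    # signed site distance to the stop: negative while approaching (the rat
    # is before the stop in the running direction), positive once past it
    fd = (stop_angle - mid_angle) % TWO_PI  # forward distance to the stop
    spacing = geometry.site_spacing if geometry is not None else 0.199
    location_to_stop = -fd / spacing if fd <= 1.5 * np.pi else (TWO_PI - fd) / spacing
    # event times are the outer window edges (6 windows at 40/10 ms = 90 ms)
    return SequenceEvent(
        start_index=int(s),
        end_index=int(e),
        t_start=float(t[0] - counts.tau / 2),
        t_end=float(t[-1] + counts.tau / 2),
        n_cells=int((block.sum(axis=0) > 0).sum()),
        n_spikes=int(block.sum()),
        fit=fit,
        near_line_fraction=near_frac,
        min_line_to_position=min_d,
        location_to_stop=float(location_to_stop),
        mode="continuous",
    )


def detect_sequences(
    posterior: PosteriorMatrix,
    counts: CountMatrix,
    position: PositionSeries,
    stop_angle: float,
    geometry: TaskGeometry | None = None,
    mode: str = "continuous",
) -> list[SequenceEvent]:
    """Detect + qualify all sequences on a window grid (one approach period)."""
    events = []
    for cand in detect_candidates(posterior, counts):
        ev = qualify_sequence(cand, posterior, counts, position, stop_angle, geometry)
        if ev is not None:
            ev.mode = mode
            events.append(ev)
    return events


def detect_cycle_sequences(
    posterior: PosteriorMatrix,
    counts: CountMatrix,
    cycles,
    position: PositionSeries,
    stop_angle: float,
    geometry: TaskGeometry | None = None,
    speed_min: float = 5.0,
) -> list[SequenceEvent]:
    """Theta-cycle-restricted variant: clip windows to each eligible cycle.

    A cycle is eligible if it contains spikes from >= 3 units and >= 5
    spikes and the mean running speed over the cycle exceeds ``speed_min``
    cm/s; the continuous detection + qualification rules are then applied
    to the windows inside the cycle.

    ``cycles`` is a ThetaCycles (see placeseq.lfp) or any object with a
    ``boundaries`` array of cycle edge times.
    """
    events = []
    bounds = np.asarray(cycles.boundaries, dtype=float)
    for c0, c1 in zip(bounds[:-1], bounds[1:]):
        keep = (posterior.centers >= c0) & (posterior.centers < c1)
        if keep.sum() < MIN_WINDOWS:
            continue
        sl = np.flatnonzero(keep)
        s, e = sl[0], sl[-1] + 1
        block = counts.counts[s:e]
        if (block.sum(axis=0) > 0).sum() < MIN_CELLS or block.sum() < MIN_SPIKES:
            continue
        mean_speed = float(np.mean(position.speed_at(np.linspace(c0, c1, 9))))
        if mean_speed <= speed_min:
            continue
        sub_post = PosteriorMatrix(posterior.centers[s:e], posterior.bin_centers,
                                   posterior.probabilities[s:e])
        sub_counts = CountMatrix(counts.centers[s:e], counts.tau, counts.step,
                                 counts.unit_ids, counts.counts[s:e])
        for ev in detect_sequences(sub_post, sub_counts, position, stop_angle,
                                   geometry, mode="theta-cycle"):
            ev.start_index += int(s)
            ev.end_index += int(s)
            events.append(ev)
    return events


def posterior_sums(
    posterior: PosteriorMatrix,
    position: PositionSeries,
    stop_angle: float,
    top_k: int = 5,
    ahead_offset_bins: int = 2,
    aggregate: str = "mean",
) -> dict:
    """Ahead/behind/trajectory regional posterior scores over an approach.

    Per window: the ahead region runs from 2 bins ahead of the current bin
    to the stop bin (in the running direction), the behind region from the
    track start (rest-box exit) to the current bin, and the trajectory
    region from the track start to the stop bin. Each regional score is
    the sum of that region's ``top_k`` largest posterior values. The lap
    value aggregates per-window scores (mean by default; 'sum' available).
    """
    n_bins = posterior.bin_centers.size
    width = TWO_PI / n_bins
    cur_bins = (np.floor(position.angle_at(posterior.centers) / width)).astype(int) % n_bins
    stop_bin = int(np.floor((stop_angle % TWO_PI) / width)) % n_bins

    def top_sum(row, lo, n):
        """Sum of top_k of the n bins starting at lo (circular)."""
        if n <= 0:
            return 0.0
        sel = (lo + np.arange(n)) % n_bins
        vals = row[sel]
        if vals.size > top_k:
            vals = np.partition(vals, vals.size - top_k)[-top_k:]
        return float(vals.sum())

    ahead, behind, traj = [], [], []
    for i in range(posterior.n_windows):
        row = posterior.probabilities[i]
        cb = cur_bins[i]
        fd = (stop_bin - cb) % n_bins  # forward bins to the stop
        if ahead_offset_bins <= fd <= 3 * n_bins // 4:
            n_ahead = fd - ahead_offset_bins + 1
        else:
            n_ahead = 0  # stop already passed (or at hand): ahead region empty
        ahead.append(top_sum(row, (cb + ahead_offset_bins) % n_bins, n_ahead))
        behind.append(top_sum(row, 0, cb % n_bins + 1))
        traj.append(top_sum(row, 0, stop_bin + 1))
    agg = np.sum if aggregate == "sum" else np.mean
    return {
        "ahead": float(agg(ahead)) if ahead else float("nan"),
        "behind": float(agg(behind)) if behind else float("nan"),
        "trajectory": float(agg(traj)) if traj else float("nan"),
        "per_window": {
            "ahead": np.asarray(ahead),
            "behind": np.asarray(behind),
            "trajectory": np.asarray(traj),
        },
    }


def slope_profile(
    events: list[SequenceEvent],
    bin_width_sites: float = 2.0,
    location_range: tuple[float, float] = (-12.0, 0.0),
    sign: str = "positive",
    n_resamples: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean sequence slope vs location-to-stop, with percentile bootstrap CIs.

    Groups events (by default positive-slope only) into ``bin_width_sites``
    location bins over ``location_range``; e.g. locations -12..-10 are
    plotted at -11. Empty bins carry NaN and are flagged.
    """
    if sign == "positive":
        events = [e for e in events if e.slope >= 0]
    elif sign == "negative":
        events = [e for e in events if e.slope < 0]
    lo, hi = location_range
    edges = np.arange(lo, hi + 1e-9, bin_width_sites)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = [e.slope for e in events if a <= e.location_to_stop < b]
        center = 0.5 * (a + b)
        if not sel:
            rows.append({"location": center, "mean_slope": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan, "n": 0, "defined": False})
            continue
        vals = np.asarray(sel)
        ci_lo, ci_hi = bootstrap_ci(vals, np.mean, n_resamples=n_resamples, seed=seed)
        rows.append({"location": center, "mean_slope": float(vals.mean()),
                     "ci_lo": ci_lo, "ci_hi": ci_hi, "n": vals.size, "defined": True})
    return pd.DataFrame(rows)


def events_to_frame(events: list[SequenceEvent]) -> pd.DataFrame:
    """Flatten sequence events into the per-event table downstream stats consume."""
    rows = []
    for e in events:
        rows.append(
            {
                "t_start": e.t_start, "t_end": e.t_end, "t_span": e.t_span,
                "slope": e.slope, "slope_sign": e.slope_sign, "x_span": e.x_span,
                "r2": e.fit.r2, "resultant": e.fit.resultant,
                "n_cells": e.n_cells, "n_spikes": e.n_spikes,
                "near_line_fraction": e.near_line_fraction,
                "min_line_to_position": e.min_line_to_position,
                "location_to_stop": e.location_to_stop, "mode": e.mode,
                "trial_id": e.trial_id, "phase": e.phase, "outcome": e.outcome,
            }
        )
    return pd.DataFrame(rows)
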