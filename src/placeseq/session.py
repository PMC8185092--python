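"""Core data containers for one recording session and their file formats.

A session is the unit of analysis: a circular track with reward sites, a
tracked trajectory, per-unit spike trains, multi-channel LFP, and a trial
table. Sessions are read/written as a directory of plain TSV files plus a
JSON ground-truth manifest (synthetic sessions only):

    spikes.tsv    unit_id, time_s
    position.tsv  time_s, angle_rad
    lfp.tsv       time_s, ch0, ch1, ...
    trials.tsv    trial_id, stage, phase, t_start_s, t_stop_s, stop_site, outcome
    truth.json    ground-truth manifest (optional)

Conventions: angles in radians, wrapped to [0, 2pi), increasing in the
running direction, rest-box exit at 0; reward sites indexed 0..n_sites-1
counterclockwise from the rest-box exit; all time intervals half-open
[start, end).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

STAGES = ("pre-running", "sample-test", "post-test")
PHASES = ("pre-running", "sample", "test", "post-test")


@dataclass(frozen=True)
class TaskGeometry:
    """Circular-track geometry: reward sites, rest box, and the goal.

    The default matches a 100-cm-diameter track with 19 reward sites spaced
    10 cm (0.199 rad) apart; the 10 sites farthest from the rest box are the
    candidate goal locations.
    """

    track_radius: float = 50.0  # cm
    n_sites: int = 19
    site_spacing: float = 0.199  # rad
    restbox_angle: float = 0.0
    site_start: float = 0.55  # angle of site 0 (rad past rest-box exit)
    goal_site: int = 11
    n_candidates: int = 10

    def __post_init__(self):
        if self.site_spacing <= 0:
            raise ValueError("site_spacing must be positive")
        if self.n_sites * self.site_spacing > TWO_PI:
            raise ValueError("reward sites overlap: n_sites * site_spacing > 2*pi")
        if self.goal_site not in self.candidate_sites:
            raise ValueError(
                f"goal_site {self.goal_site} not among candidate sites "
                f"{list(self.candidate_sites)}"
            )

    @property
    def site_angles(self) -> np.ndarray:
        return (self.site_start + np.arange(self.n_sites) * self.site_spacing) % TWO_PI

    @property
    def candidate_sites(self) -> np.ndarray:
        """The n_candidates sites farthest (circularly) from the rest box."""
        from .circstats import circular_distance

        d = circular_distance(self.site_angles, self.restbox_angle)
        order = np.argsort(-d, kind="stable")
        return np.sort(order[: self.n_candidates])

    @property
    def goal_angle(self) -> float:
        return float(self.site_angles[self.goal_site])

    @property
    def circumference(self) -> float:
        return TWO_PI * self.track_radius

    def nearest_site(self, angle) -> np.ndarray:
        """Index of the reward site nearest to each angle."""
        from .circstats import circular_distance

        a = np.atleast_1d(np.asarray(angle, dtype=float))
        d = circular_distance(a[:, None], self.site_angles[None, :])
        out = np.argmin(d, axis=1)
        return out if np.ndim(angle) else int(out[0])


@dataclass
class PositionSeries:
    """Tracked head position: times (s), wrapped angles (rad), speeds (cm/s).

    ``unwrapped`` carries the cumulative angle (monotone during running),
    from which speeds are derived; ``speeds`` is filled by
    :func:`placeseq.preprocess.estimate_speed`.
    """

    times: np.ndarray
    angles: np.ndarray
    unwrapped: np.ndarray | None = None
    speeds: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float) % TWO_PI
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("position timestamps must be strictly increasing")
        if self.unwrapped is None:
            self.unwrapped = np.unwrap(self.angles)

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    def angle_at(self, t):
        """True angle interpolated (circularly, via the unwrapped series)."""
        return np.interp(t, self.times, self.unwrapped) % TWO_PI

    def speed_at(self, t):
        if self.speeds is None:
            raise ValueError("speeds not computed; call estimate_speed first")
        return np.interp(t, self.times, self.speeds)


@dataclass
class SpikeSet:
    """Per-unit spike trains: mapping unit id -> sorted spike times (s)."""

    trains: dict[int, np.ndarray]
    t_start: float = 0.0
    t_stop: float | None = None

    def __post_init__(self):
        clean = {}
        for uid, st in self.trains.items():
            st = np.asarray(st, dtype=float)
            if np.any(np.diff(st) < 0):
                st = np.sort(st)
            clean[int(uid)] = st
        self.trains = clean
        if self.t_stop is None:
            ends = [st[-1] for st in self.trains.values() if st.size]
            self.t_stop = max(ends) if ends else self.t_start

    @property
    def unit_ids(self) -> list[int]:
        return sorted(self.trains)

    @property
    def n_units(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return sum(st.size for st in self.trains.values())

    def mean_rates(self) -> dict[int, float]:
        dur = max(self.t_stop - self.t_start, 1e-12)
        return {uid: st.size / dur for uid, st in self.trains.items()}

    def subset(self, unit_ids) -> "SpikeSet":
        return SpikeSet(
            {u: self.trains[u] for u in unit_ids},
            t_start=self.t_start,
            t_stop=self.t_stop,
        )

    def windowed(self, t0: float, t1: float) -> "SpikeSet":
        out = {}
        for uid, st in self.trains.items():
            out[uid] = st[(st >= t0) & (st < t1)]
        return SpikeSet(out, t_start=t0, t_stop=t1)

    def merged_times(self) -> np.ndarray:
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate(list(self.trains.values())))


@dataclass
class LFPSet:
    """Multi-channel LFP: times (s) and one column per channel (uV)."""

    times: np.ndarray
    traces: np.ndarray  # (n_samples, n_channels)
    fs: float = 2000.0
    channel_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape[0] != self.times.size:
            self.traces = self.traces.T
        if not self.channel_ids:
            self.channel_ids = list(range(self.traces.shape[1]))

    @property
    def n_channels(self) -> int:
        return self.traces.shape[1]


@dataclass
class GroundTruth:
    """What the synthetic generator planted, for verifying the pipeline.

    planted_swr_intervals : list of (start, end) seconds inside rest windows.
    planted_replays : one dict per event: start_angle, end_angle, direction
        ('forward'/'reverse'), t_start, t_end, end_site.
    true_precession_slope : rad of theta phase per rad of position.
    trial_labels : per sample/test trial: stop site and outcome.
    """

    planted_swr_intervals: list = field(default_factory=list)
    planted_replays: list = field(default_factory=list)
    true_precession_slope: float = float("nan")
    trial_labels: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "planted_swr_intervals": [list(map(float, iv)) for iv in self.planted_swr_intervals],
            "planted_replays": self.planted_replays,
            "true_precession_slope": self.true_precession_slope,
            "trial_labels": self.trial_labels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            planted_swr_intervals=[tuple(iv) for iv in d.get("planted_swr_intervals", [])],
            planted_replays=d.get("planted_replays", []),
            true_precession_slope=d.get("true_precession_slope", float("nan")),
            trial_labels=d.get("trial_labels", []),
        )


@dataclass
class SessionData:
    """One session: spikes + position + LFP + trial table + geometry."""

    spikes: SpikeSet
    position: PositionSeries
    lfp: LFPSet
    trials: pd.DataFrame
    geometry: TaskGeometry

    def validate(self):
        required = {"trial_id", "stage", "phase", "t_start_s", "t_stop_s", "stop_site", "outcome"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        st = self.trials[self.trials["phase"].isin(["sample", "test"])]
        if st["outcome"].isna().any():
            raise ValueError("every sample/test trial must carry an outcome label")
        return self

    def stage_window(self, stage: str) -> tuple[float, float]:
        rows = self.trials[self.trials["stage"] == stage]
        if rows.empty:
            raise ValueError(f"no trials in stage {stage!r}")
        return float(rows["t_start_s"].min()), float(rows["t_stop_s"].max())

    def rest_windows(self) -> list[tuple[float, float]]:
        """Gaps between consecutive trials (the rest-box periods)."""
        tr = self.trials.sort_values("t_start_s")
        out = []
        for (_, a), (_, b) in zip(tr.iterrows(), tr.iloc[1:].iterrows()):
            if b["t_start_s"] > a["t_stop_s"]:
                out.append((float(a["t_stop_s"]), float(b["t_start_s"])))
        return out


def write_session(session: SessionData, out_dir, truth: GroundTruth | None = None):
    """Write a session as the plain-TSV file set this package reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        (uid, t) for uid, st in session.spikes.trains.items() for t in st
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).sort_values(
        ["time_s", "unit_id"]
    ).to_csv(out / "spikes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"time_s": session.position.times, "angle_rad": session.position.angles}
    ).to_csv(out / "position.tsv", sep="\t", index=False)
    lfp_df = pd.DataFrame(
        np.round(session.lfp.traces, 3),
        columns=[f"ch{c}" for c in session.lfp.channel_ids],
    )
    lfp_df.insert(0, "time_s", session.lfp.times)
    lfp_df.to_csv(out / "lfp.tsv", sep="\t", index=False)
    session.trials.to_csv(out / "trials.tsv", sep="\t", index=False)
    geo = {
        "track_radius": session.geometry.track_radius,
        "n_sites": session.geometry.n_sites,
        "site_spacing": session.geometry.site_spacing,
        "restbox_angle": session.geometry.restbox_angle,
        "site_start": session.geometry.site_start,
        "goal_site": session.geometry.goal_site,
        "n_candidates": session.geometry.n_candidates,
    }
    (out / "geometry.json").write_text(json.dumps(geo, indent=1))
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))


def read_session(in_dir) -> tuple[SessionData, GroundTruth | None]:
    """Read a session directory written by :func:`write_session`."""
    p = Path(in_dir)
    spikes_df = pd.read_csv(p / "spikes.tsv", sep="\t")
    trains: dict[int, list] = {}
    for uid, grp in spikes_df.groupby("unit_id"):
        trains[int(uid)] = grp["time_s"].to_numpy()
    pos_df = pd.read_csv(p / "position.tsv", sep="\t")
    lfp_df = pd.read_csv(p / "lfp.tsv", sep="\t")
    trials = pd.read_csv(p / "trials.tsv", sep="\t")
    geo = TaskGeometry(**json.loads((p / "geometry.json").read_text()))
    lfp_times = lfp_df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(lfp_times))) if lfp_times.size > 1 else 2000.0
    lfp = LFPSet(
        times=lfp_times,
        traces=lfp_df.drop(columns=["time_s"]).to_numpy(),
        fs=round(fs),
        channel_ids=[int(c[2:]) for c in lfp_df.columns if c.startswith("ch")],
    )
    t0 = float(min(pos_df["time_s"].iloc[0], lfp_times[0] if lfp_times.size else 0.0))
    t1 = float(max(pos_df["time_s"].iloc[-1], lfp_times[-1] if lfp_times.size else 0.0))
    session = SessionData(
        spikes=SpikeSet(trains, t_start=t0, t_stop=t1),
        position=PositionSeries(pos_df["time_s"].to_numpy(), pos_df["angle_rad"].to_numpy()),
        lfp=lfp,
        trials=trials,
        geometry=geo,
    )
    truth = None
    if (p / "truth.json").exists():
        truth = GroundTruth.from_dict(json.loads((p / "truth.json").read_text()))
    return session, truth
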