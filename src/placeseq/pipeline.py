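"""Session-level orchestration: configuration, stage execution, reports.

``run_session`` executes the full analysis in order — preprocessing
(speed, rate maps, unit selection), decoder cross-validation on the
pre-running laps, sequence detection during approach periods (continuous
and theta-cycle modes) with posterior sums and slope profiles, LFP phase
analyses, and SWR/replay detection with the goal-bias tests per trial
block — and returns a report bundle of event tables and summary numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import lfp as lfpmod
from . import replay as replaymod
from . import sequences as seqmod
from .decoder import bin_spikes, decode_posterior, evaluate_decoder
from .preprocess import compute_rate_map, estimate_speed, select_units
from .session import SessionData, TaskGeometry

CHANCE_LEVEL = 0.2  # uniform choice over the 5 sites nearest the goal


@dataclass
class AnalysisConfig:
    """Every analysis threshold, defaulting to the published values."""

    tau: float = 0.040
    step: float = 0.010
    rate_floor: float = 0.01
    n_bins: int = 90
    kernel_sd: float = 0.14
    speed_min: float = 5.0
    seq_min_windows: int = 6
    seq_max_jump: float = 1.4
    seq_min_span: float = 0.07
    seq_min_cells: int = 3
    seq_min_spikes: int = 5
    seq_near_line: float = 0.35
    seq_near_fraction: float = 0.60
    swr_band: tuple = (150.0, 250.0)
    swr_smooth_sd: float = 0.025
    swr_threshold_sd: float = 5.0
    swr_min_duration: float = 0.050
    replay_r2: float = 0.5
    replay_empty_max: float = 0.20
    replay_min_duration: float = 0.050
    n_shuffles: int = 5000
    bias_tail: float = 97.5
    n_bootstrap: int = 5000
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path):
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _approach_epoch(trial) -> tuple[float, float]:
    """Run start to stop for one trial (the sequence-analysis period)."""
    t_reach = trial["t_reach_s"] if "t_reach_s" in trial and np.isfinite(trial["t_reach_s"]) else trial["t_stop_s"]
    return float(trial["t_start_s"]), float(t_reach)


def trial_block(trials: pd.DataFrame, trial_id: int) -> str:
    """'trials 1-4' / 'trials 5-8' / 'post-test' label for one trial."""
    row = trials.loc[trials["trial_id"] == trial_id].iloc[0]
    if row["stage"] == "post-test":
        return "post-test"
    if row["stage"] != "sample-test":
        return "pre-running"
    st = trials[trials["stage"] == "sample-test"].sort_values("t_start_s")
    pair_index = (st["trial_id"] < trial_id).sum() // 2  # 0-based pair number
    return "trials 1-4" if pair_index < 4 else "trials 5-8"


def run_session(session: SessionData, config: AnalysisConfig | None = None) -> dict:
    """Run every analysis stage on one session; returns the report bundle."""
    config = config or AnalysisConfig()
    session.validate()
    geometry = session.geometry
    report: dict = {"config_hash": config.hash(), "chance_level": CHANCE_LEVEL}

    # ---- preprocess -------------------------------------------------------
    if session.position.speeds is None:
        estimate_speed(session.position, geometry.track_radius)
    if session.spikes.n_spikes == 0:
        raise ValueError("session has no spikes; nothing to analyze")
    pre0, pre1 = session.stage_window("pre-running")
    t_end = float(session.position.times[-1])
    maps_pre = compute_rate_map(
        session.spikes, session.position, speed_min=config.speed_min,
        epoch=(pre0, pre1), n_bins=config.n_bins, kernel_sd=config.kernel_sd,
        restbox_angle=geometry.restbox_angle,
    )
    maps_post = compute_rate_map(
        session.spikes, session.position, speed_min=config.speed_min,
        epoch=(pre1, t_end), n_bins=config.n_bins, kernel_sd=config.kernel_sd,
        restbox_angle=geometry.restbox_angle,
    )
    selection = select_units(maps_post, session.spikes, geometry, seed=config.seed)
    retained = selection["retained"]
    if not retained:
        raise ValueError("unit selection retained no units; decoding refused")
    spikes = session.spikes.subset(retained)
    maps = maps_post.subset(retained)
    report["unit_selection"] = {k: v for k, v in selection.items()}

    # ---- decoder cross-validation on pre-running --------------------------
    counts_pre = bin_spikes(spikes, (pre0, pre1), tau=config.tau, step=config.step)
    posterior_pre = decode_posterior(counts_pre, maps)
    ev = evaluate_decoder(posterior_pre, session.position)
    moving = session.position.speed_at(posterior_pre.centers) > config.speed_min
    report["decoding"] = {
        "median_error_rad": float(np.median(ev["errors"][moving])) if moving.any() else np.nan,
        "median_error_bins": float(np.median(ev["errors"][moving]) / posterior_pre.bin_width)
        if moving.any()
        else np.nan,
        "n_windows": int(posterior_pre.n_windows),
    }
    report["confusion"] = ev["confusion"]

    # ---- sequences during approach periods --------------------------------
    all_events = []
    fig2_rows = []
    approach_trials = session.trials[session.trials["phase"].isin(["sample", "test", "post-test"])]
    for _, trial in approach_trials.iterrows():
        a0, a1 = _approach_epoch(trial)
        if a1 - a0 < config.tau:
            continue
        counts = bin_spikes(spikes, (a0, a1), tau=config.tau, step=config.step)
        if counts.n_windows == 0:
            continue
        posterior = decode_posterior(counts, maps)
        stop_angle = float(geometry.site_angles[int(trial["stop_site"])])
        events = seqmod.detect_sequences(
            posterior, counts, session.position, stop_angle, geometry
        )
        for e in events:
            e.trial_id = int(trial["trial_id"])
            e.phase = str(trial["phase"])
            e.outcome = str(trial["outcome"])
        all_events.extend(events)
        sums = seqmod.posterior_sums(posterior, session.position, stop_angle)
        fig2_rows.append(
            {"trial_id": int(trial["trial_id"]), "phase": trial["phase"],
             "outcome": trial["outcome"], "ahead": sums["ahead"],
             "behind": sums["behind"], "trajectory": sums["trajectory"]}
        )
    report["sequences"] = seqmod.events_to_frame(all_events)
    report["posterior_sums"] = pd.DataFrame(fig2_rows)
    report["slope_profile"] = {
        outcome: seqmod.slope_profile(
            [e for e in all_events if e.outcome == outcome],
            n_resamples=config.n_bootstrap, seed=config.seed,
        )
        for outcome in ("correct", "error")
    }

    # ---- LFP: theta channel, cycles, cycle-mode sequences ------------------
    cycle_events = []
    if session.lfp.times.size > 100:
        mask = lfpmod.movement_mask(session.lfp.times, session.position, geometry,
                                    config.speed_min)
        theta_ch = lfpmod.select_theta_channel(session.lfp, mask)
        col = session.lfp.channel_ids.index(theta_ch)
        theta = lfpmod.band_analytic(
            session.lfp.traces[:, col], session.lfp.fs, "theta",
            times=session.lfp.times, mask=mask,
        )
        run_epochs = [
            _approach_epoch(t) for _, t in approach_trials.iterrows()
        ]
        try:
            cycles = lfpmod.segment_theta_cycles(
                theta, spikes, session.position, run_epochs
            )
        except ValueError:
            cycles = None
        if cycles is not None:
            for _, trial in approach_trials.iterrows():
                a0, a1 = _approach_epoch(trial)
                if a1 - a0 < config.tau:
                    continue
                counts = bin_spikes(spikes, (a0, a1), tau=config.tau, step=config.step)
                if counts.n_windows == 0:
                    continue
                posterior = decode_posterior(counts, maps)
                stop_angle = float(geometry.site_angles[int(trial["stop_site"])])
                evs = seqmod.detect_cycle_sequences(
                    posterior, counts, cycles, session.position, stop_angle, geometry,
                    speed_min=config.speed_min,
                )
                for e in evs:
                    e.trial_id = int(trial["trial_id"])
                    e.phase = str(trial["phase"])
                    e.outcome = str(trial["outcome"])
                cycle_events.extend(evs)
        report["theta_channel"] = theta_ch
        report["phase_by_location"] = lfpmod.spike_phase_by_location(
            all_events, spikes, maps, theta, geometry
        )
    report["cycle_sequences"] = seqmod.events_to_frame(cycle_events)
    report["slope_sign_table"] = _slope_sign_table(all_events, cycle_events)

    # ---- SWRs and replay ---------------------------------------------------
    rest_windows = session.rest_windows()
    replay_rows = pd.DataFrame()
    if session.lfp.times.size > 100 and rest_windows:
        swrs = replaymod.detect_swr(session.lfp, rest_windows)
        replays = []
        trials_sorted = session.trials.sort_values("t_start_s").reset_index(drop=True)
        for swr in swrs:
            rep = replaymod.qualify_replay(swr, spikes, maps, geometry,
                                           tau=config.tau, step=config.step)
            if rep is None:
                continue
            nxt = trials_sorted[trials_sorted["t_start_s"] >= swr.t_end]
            if not nxt.empty:
                ctx = nxt.iloc[0]
                rep.block = trial_block(session.trials, int(ctx["trial_id"]))
                rep.outcome = str(ctx["outcome"])
                rep.stop_site = int(ctx["stop_site"])
            replays.append(rep)
        report["swrs"] = pd.DataFrame(
            [{"t_start": s.t_start, "t_end": s.t_end, "peak_z": s.peak_z,
              "channels": s.channels} for s in swrs]
        )
        replay_rows = replaymod.replays_to_frame(replays)
        if replays:
            report["termination_bias"] = {
                block: replaymod.termination_bias(
                    evs, geometry, n_shuffles=config.n_shuffles, seed=config.seed
                )
                for block in ("trials 1-4", "trials 5-8", "post-test")
                if (evs := [r for r in replays if r.block == block])
            }
            report["initiation_bias"] = replaymod.termination_bias(
                replays, geometry, end="first", n_shuffles=config.n_shuffles,
                seed=config.seed,
            )
            report["end_vs_stop"] = replaymod.end_vs_stop_correlation(
                replays, geometry, n_resamples=config.n_bootstrap, seed=config.seed
            )
    report["replays"] = replay_rows
    return report


def _slope_sign_table(continuous_events, cycle_events) -> np.ndarray:
    """2x2 counts of positive/negative slopes by detection mode."""
    def counts(evs):
        pos = sum(1 for e in evs if e.slope >= 0)
        return [pos, len(evs) - pos]

    return np.array([counts(continuous_events), counts(cycle_events)])


def write_report(report: dict, out_dir):
    """Serialize the report bundle: TSV event tables + summary JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"config_hash": report["config_hash"], "chance_level": report["chance_level"]}
    for key in ("sequences", "cycle_sequences", "replays", "posterior_sums", "swrs"):
        if key in report and isinstance(report[key], pd.DataFrame) and not report[key].empty:
            report[key].to_csv(out / f"{key}.tsv", sep="\t", index=False)
            summary[f"n_{key}"] = int(len(report[key]))
    if "decoding" in report:
        summary["decoding"] = report["decoding"]
    if "unit_selection" in report:
        summary["unit_selection"] = {
            k: v for k, v in report["unit_selection"].items() if not isinstance(v, np.ndarray)
        }
    if "termination_bias" in report:
        summary["termination_bias"] = {
            block: {
                "significant_locations": [int(x) for x in br.significant_locations()],
                "n_events": br.n_events,
            }
            for block, br in report["termination_bias"].items()
        }
    if "end_vs_stop" in report:
        report["end_vs_stop"].to_csv(out / "end_vs_stop.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return out / "summary.json"
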