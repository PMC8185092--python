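"""Synthetic session generator with known ground truth.

Generates complete sessions of the circular-track delayed match-to-sample
task — unidirectional-lap trajectory, place-cell spike trains with theta
phase precession, multi-channel LFP with theta/gamma during movement and
planted sharp wave-ripples during rest, and rest-period replay spike
patterns with a controllable bias to terminate at the goal — so that every
downstream detector and statistic can be verified against what was planted.

Model summary
-------------
* Tuning curves are von Mises bumps: f_i(x) = baseline + peak *
  exp(kappa*(cos(x - c_i) - 1)), peak-normalized so the maximum is ``peak_rate``.
* Run-period spiking is an inhomogeneous Poisson process
  lambda_i(t) = f_i(x(t)) * (1 + m*cos(theta(t) - psi_i(t))) * g(t)
  where theta(t) = 2*pi*f_theta*t is the theta phase, psi_i precesses
  (moves earlier) at ``precession_slope`` radians of phase per radian of
  distance into the field, and g(t) = 1 + m_gate*cos(theta(t) - phi_gate)
  is a population gate that silences the ensemble near the theta trough
  (this is what segments decoding into discrete cycle-scale sequences).
  The decoded sequence sweep speed is approximately
  v + 2*pi*f_theta / precession_slope, so a SHALLOWER precession slope
  yields STEEPER (more compressed) decodable sequences.
* Rest-period replay: inside each planted ripple interval, units fire in
  field-center order along a constant-speed trajectory that ends at the
  goal site with probability ``replay_end_bias`` (uniform over sites
  otherwise); reverse events traverse the same path backwards.
* LFP: theta + gamma sinusoids during movement, white noise everywhere,
  and ripple-frequency packets at the planted intervals whose amplitude is
  a stated multiple of the background ripple-band envelope SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt

from .preprocess import N_BINS_DEFAULT, RateMap, estimate_speed
from .session import (
    TWO_PI,
    GroundTruth,
    LFPSet,
    PositionSeries,
    SessionData,
    SpikeSet,
    TaskGeometry,
)

__all__ = [
    "SimulationSpec",
    "build_session",
    "build_trial_schedule",
    "simulate_trajectory",
    "simulate_run_spikes",
    "simulate_lfp",
    "simulate_rest_replay",
    "tuning_curves",
    "analytic_rate_map",
    "expected_mean_rates",
]


@dataclass(frozen=True)
class SimulationSpec:
    """All knobs of the generator. Fixed seed => byte-identical output."""

    n_units: int = 50
    field_centers: np.ndarray | None = None  # default: evenly spaced
    field_concentration: float = 40.0  # von Mises kappa (~30-cm fields)
    peak_rate: float = 15.0  # Hz
    baseline_rate: float = 0.1  # Hz
    theta_freq: float = 8.0  # Hz
    theta_mod_depth: float = 0.7  # per-cell modulation depth m
    phase_concentration: float = 4.0  # von Mises kappa of the phase kernel
    gate_depth: float = 0.8  # population theta gate depth
    # maximal population activity at the mid-sweep phase (where the ensemble
    # represents the current position), minimum at the sweep-edge phase
    gate_phase: float = float(np.pi)
    precession_slope: float = 6.3  # rad of phase per rad of position (~one cycle per field)
    lfp_fs: float = 2000.0
    ripple_freq: float = 200.0
    ripple_duration: float = 0.080  # s
    ripple_amplitude_sd: float = 8.0  # multiples of background envelope SD
    replay_speed: float = 25.0  # rad/s of decoded motion during replay
    replay_end_bias: float = 0.0
    replay_p_forward: float = 0.5
    replays_per_rest: int = 2
    noise_sd: float = 20.0  # uV
    run_speed_mean: float = 40.0  # cm/s
    run_speed_sd: float = 4.0  # cm/s
    pos_fs: float = 30.0
    n_channels: int = 4
    n_pairs: int = 8
    n_pre_laps: int | None = None  # None: draw 4 or 6
    n_post_trials: int | None = None
    rest_within_pair: float = 30.0  # s between sample and test
    rest_between_pairs: float = 60.0
    rest_between_stages: float = 60.0
    p_correct: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if min(self.peak_rate, self.baseline_rate) < 0:
            raise ValueError("rates must be nonnegative")
        if not (0.0 <= self.replay_end_bias <= 1.0):
            raise ValueError("replay_end_bias must be in [0, 1]")
        if self.n_units < 0:
            raise ValueError("n_units must be nonnegative")

    def centers(self) -> np.ndarray:
        if self.field_centers is not None:
            return np.asarray(self.field_centers, dtype=float) % TWO_PI
        return np.arange(self.n_units) * TWO_PI / max(self.n_units, 1)


def tuning_curves(spec: SimulationSpec, angles) -> np.ndarray:
    """Programmed tuning f_i(x): (n_units, len(angles)) in Hz."""
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    c = spec.centers()
    kappa = spec.field_concentration
    bump = np.exp(kappa * (np.cos(angles[None, :] - c[:, None]) - 1.0))
    return spec.baseline_rate + spec.peak_rate * bump


def analytic_rate_map(spec: SimulationSpec, n_bins: int = N_BINS_DEFAULT) -> RateMap:
    """RateMap built directly from the programmed tuning (no sampling).

    Useful as a noiseless encoding model when testing detectors in
    isolation from rate-map estimation.
    """
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    rates = tuning_curves(spec, centers)
    occ = np.ones(n_bins)
    return RateMap(
        bin_edges=edges,
        unit_ids=list(range(spec.n_units)),
        rates=rates,
        occupancy=occ,
        occupancy_raw=occ,
        spike_counts=np.zeros_like(rates),
    )


# ---------------------------------------------------------------------------
# trial schedule and trajectory


def build_trial_schedule(geometry: TaskGeometry, spec: SimulationSpec) -> pd.DataFrame:
    """Draw the session's trial sequence: stages, stop sites, outcomes.

    Sample trials always stop at the goal (it is cued); test and post-test
    trials stop at the goal with probability ``p_correct`` and otherwise at
    a neighboring candidate site (offsets -2..2, biased toward +/-1,
    matching the dominant one-site errors). Sample trials inherit the
    outcome of their pair's test trial.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 11]))
    cand = set(int(s) for s in geometry.candidate_sites)
    offsets = np.array([-2, -1, 1, 2])
    offset_p = np.array([0.15, 0.35, 0.35, 0.15])

    def draw_stop() -> int:
        if rng.random() < spec.p_correct:
            return geometry.goal_site
        for off in rng.choice(offsets, size=8, p=offset_p):
            s = geometry.goal_site + int(off)
            if s in cand:
                return s
        return geometry.goal_site  # goal at candidate-set edge; fall back

    rows = []
    n_pre = spec.n_pre_laps if spec.n_pre_laps is not None else int(rng.choice([4, 6]))
    rows.append({"stage": "pre-running", "phase": "pre-running", "stop_site": -1, "laps": n_pre})
    for _ in range(spec.n_pairs):
        test_stop = draw_stop()
        outcome = "correct" if test_stop == geometry.goal_site else "error"
        rows.append(
            {"stage": "sample-test", "phase": "sample", "stop_site": geometry.goal_site,
             "laps": 0, "outcome": outcome}
        )
        rows.append(
            {"stage": "sample-test", "phase": "test", "stop_site": test_stop,
             "laps": 0, "outcome": outcome}
        )
    n_post = (
        spec.n_post_trials if spec.n_post_trials is not None else int(rng.choice([4, 6]))
    )
    for _ in range(n_post):
        stop = draw_stop()
        rows.append(
            {"stage": "post-test", "phase": "post-test", "stop_site": stop, "laps": 0,
             "outcome": "correct" if stop == geometry.goal_site else "error"}
        )
    return pd.DataFrame(rows)


def _rest_duration(prev_phase: str, next_phase: str, spec: SimulationSpec) -> float:
    if prev_phase == "sample" and next_phase == "test":
        return spec.rest_within_pair
    if {prev_phase, next_phase} & {"pre-running", "post-test"} and prev_phase != next_phase:
        return spec.rest_between_stages
    return spec.rest_between_pairs


def simulate_trajectory(
    geometry: TaskGeometry, spec: SimulationSpec, schedule: pd.DataFrame
) -> tuple[PositionSeries, pd.DataFrame]:
    """Integrate the lap kinematics for every trial in the schedule.

    During a run the angle increases monotonically at a speed drawn around
    ``run_speed_mean`` with smooth (low-pass filtered) noise; the speed
    ramps down to a stop over the last 15 cm before the trial's stop site,
    the rat dwells there ~1.5 s, then completes the lap back to the rest
    box at running speed. During rest windows the angle is pinned at the
    rest-box angle. Returns the position series and the timed trial table.
    """
    for _, row in schedule.iterrows():
        if row["phase"] in ("test", "post-test", "sample") and (
            int(row["stop_site"]) not in set(int(s) for s in geometry.candidate_sites)
        ):
            raise ValueError(f"stop site {row['stop_site']} outside the candidate set")

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 12]))
    dt = 1.0 / spec.pos_fs
    radius = geometry.track_radius
    ramp_dist = 15.0  # cm
    v_min = 3.0  # cm/s floor inside the ramp
    dwell = 1.5  # s at the stop site

    times: list[float] = [0.0]
    unwrapped: list[float] = [geometry.restbox_angle]
    t = 0.0
    pos = geometry.restbox_angle  # cumulative angle
    trial_rows = []

    def step_to(target: float, ramp: bool):
        """Advance until cumulative angle reaches target."""
        nonlocal t, pos
        # smooth speed noise: AR(1) low-pass on white noise
        state = 0.0
        alpha = np.exp(-dt / 0.5)  # 0.5 s correlation time
        while pos < target:
            state = alpha * state + np.sqrt(1 - alpha**2) * rng.normal(0.0, spec.run_speed_sd)
            v = spec.run_speed_mean + state
            if ramp:
                remaining = (target - pos) * radius
                if remaining < ramp_dist:
                    v = min(v, v_min + (spec.run_speed_mean - v_min) * remaining / ramp_dist)
            v = max(v, v_min)
            pos = min(target, pos + (v / radius) * dt)
            t += dt
            times.append(t)
            unwrapped.append(pos)

    def stay(duration: float):
        nonlocal t
        n = int(round(duration / dt))
        for _ in range(n):
            t += dt
            times.append(t)
            unwrapped.append(pos)

    first = True
    prev_phase = None
    for _, row in schedule.iterrows():
        phase = row["phase"]
        if not first:
            stay(_rest_duration(prev_phase, phase, spec))
        first = False
        t_start = t
        lap_base = np.floor((pos - geometry.restbox_angle) / TWO_PI) * TWO_PI
        t_reach = np.nan
        if phase == "pre-running":
            step_to(pos + row["laps"] * TWO_PI, ramp=False)
        else:
            stop_angle = geometry.site_angles[int(row["stop_site"])]
            target = lap_base + geometry.restbox_angle + (
                (stop_angle - geometry.restbox_angle) % TWO_PI
            )
            if target <= pos:
                target += TWO_PI
            step_to(target, ramp=True)
            t_reach = t
            stay(dwell)
            step_to(lap_base + geometry.restbox_angle + TWO_PI, ramp=False)
        trial_rows.append(
            {
                "trial_id": len(trial_rows),
                "stage": row["stage"],
                "phase": phase,
                "t_start_s": t_start,
                "t_stop_s": t,
                "t_reach_s": t_reach,
                "stop_site": int(row["stop_site"]),
                "outcome": row.get("outcome", None),
            }
        )
        prev_phase = phase
    stay(spec.rest_between_stages)  # final rest period

    u = np.asarray(unwrapped)
    position = PositionSeries(times=np.asarray(times), angles=u % TWO_PI, unwrapped=u)
    estimate_speed(position, track_radius=radius)
    return position, pd.DataFrame(trial_rows)


# ---------------------------------------------------------------------------
# run-period spiking with phase precession


def _rate_on_grid(spec: SimulationSpec, unit: int, t, ang_u, moving):
    """Intensity lambda_i(t) of one unit on a time grid (vectorized)."""
    c = spec.centers()[unit]
    kappa = spec.field_concentration
    ang = ang_u % TWO_PI
    bump = np.exp(kappa * (np.cos(ang - c) - 1.0))
    tuning = spec.peak_rate * bump
    theta = (TWO_PI * spec.theta_freq * t) % TWO_PI
    # phase precesses from 2*pi toward 0 across the field; distance into the
    # field measured from the field start (center - half width)
    half_width = np.pi / np.sqrt(max(kappa, 1e-9))
    d_in = (ang - (c - half_width)) % TWO_PI
    psi = (TWO_PI - spec.precession_slope * d_in) % TWO_PI
    # phase kernel: mean-preserving mixture of an unmodulated floor and a
    # von Mises bump at the precessing preferred phase; the bump must be
    # concentrated enough that a 40-ms decoding window (~2 rad of theta
    # phase) resolves the within-cycle position sweep
    from scipy.special import i0e

    m = spec.theta_mod_depth
    kp = spec.phase_concentration
    bump = np.exp(kp * (np.cos(theta - psi) - 1.0)) / i0e(kp)
    mod = (1.0 - m) + m * bump
    gate = 1.0 + spec.gate_depth * np.cos(theta - spec.gate_phase)
    # pyramidal cells are largely silent during quiet rest outside SWRs:
    # the flat baseline is strongly suppressed when the animal is still
    baseline = spec.baseline_rate * (moving + 0.2 * (1.0 - moving))
    lam = baseline + tuning * mod * gate * moving
    return lam


def simulate_run_spikes(
    position: PositionSeries,
    spec: SimulationSpec,
    grid_dt: float = 0.001,
) -> SpikeSet:
    """Inhomogeneous-Poisson spike trains for every unit during movement.

    Spiking follows the phase-precession model described in the module
    docstring, evaluated on a ``grid_dt`` grid and sampled bin-wise
    (Bernoulli with p = lambda*dt, valid for lambda*dt << 1), with uniform
    jitter inside the bin. Rest periods carry only the baseline rate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 13]))
    t0, t1 = position.times[0], position.times[-1]
    t = np.arange(t0, t1, grid_dt)
    ang_u = np.interp(t, position.times, position.unwrapped)
    speed = np.interp(t, position.times, position.speeds)
    moving = (speed > 5.0).astype(float)
    trains: dict[int, np.ndarray] = {}
    for u in range(spec.n_units):
        lam = _rate_on_grid(spec, u, t, ang_u, moving)
        p = np.clip(lam * grid_dt, 0.0, 1.0)
        hits = rng.random(t.size) < p
        st = t[hits] + rng.uniform(0.0, grid_dt, size=int(hits.sum()))
        trains[u] = np.sort(st)
    return SpikeSet(trains, t_start=t0, t_stop=t1)


def expected_mean_rates(
    position: PositionSeries, spec: SimulationSpec, grid_dt: float = 0.001
) -> np.ndarray:
    """Exact per-unit expected mean rate (Hz) under the generator's intensity."""
    t0, t1 = position.times[0], position.times[-1]
    t = np.arange(t0, t1, grid_dt)
    ang_u = np.interp(t, position.times, position.unwrapped)
    speed = np.interp(t, position.times, position.speeds)
    moving = (speed > 5.0).astype(float)
    out = np.empty(spec.n_units)
    for u in range(spec.n_units):
        out[u] = _rate_on_grid(spec, u, t, ang_u, moving).mean()
    return out


# ---------------------------------------------------------------------------
# rest-period SWRs and replay content


def plant_swr_intervals(
    rest_windows: list[tuple[float, float]], spec: SimulationSpec
) -> list[tuple[float, float]]:
    """Place ``replays_per_rest`` non-overlapping ripple intervals per rest window."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 14]))
    out = []
    dur = spec.ripple_duration
    for w0, w1 in rest_windows:
        usable = (w1 - w0) - 2.0  # 1 s margin each side
        n = spec.replays_per_rest
        if usable < n * (dur + 0.5):
            n = max(int(usable // (dur + 0.5)), 0)
        if n == 0:
            continue
        slots = np.sort(rng.uniform(0.0, 1.0, size=n))
        # spread starts over the usable span, forcing >= 0.3 s separation
        starts = w0 + 1.0 + slots * (usable - dur)
        starts = np.maximum.accumulate(starts)
        for k in range(1, n):
            starts[k] = max(starts[k], starts[k - 1] + dur + 0.3)
        for s in starts:
            if s + dur <= w1 - 1.0:
                out.append((float(s), float(s + dur)))
    return out


def simulate_rest_replay(
    swr_intervals: list[tuple[float, float]],
    spec: SimulationSpec,
    geometry: TaskGeometry,
) -> tuple[SpikeSet, list[dict]]:
    """Plant replay spike patterns inside each ripple interval.

    Units fire in field-center order along a constant-speed trajectory
    (``replay_speed`` rad/s); 'reverse' events traverse the path backwards
    in time. With probability ``replay_end_bias`` the path's end angle is
    the goal site; otherwise the end site is uniform over all sites.
    """
    if spec.replay_speed <= 0:
        raise ValueError("replay_speed must be positive (degenerate trajectory)")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 15]))
    centers = spec.centers()
    trains: dict[int, list] = {u: [] for u in range(spec.n_units)}
    truth_events = []
    # the represented trajectory dwells briefly at its start and end sites
    # (as goal-terminating replay does), so that the causal decoding windows
    # at the event edges are dominated by the intended start/end locations
    dwell = 0.030  # s
    for t0, t1 in swr_intervals:
        ta, tb = t0 + 0.002, t1 - 0.002
        move_span = (tb - ta) - 2 * dwell
        if move_span <= 0:
            raise ValueError("ripple interval too short for a replay path")
        direction = "forward" if rng.random() < spec.replay_p_forward else "reverse"
        if rng.random() < spec.replay_end_bias:
            end_site = geometry.goal_site
        else:
            end_site = int(rng.integers(0, geometry.n_sites))
        sign = 1.0 if direction == "forward" else -1.0
        end_angle = float(geometry.site_angles[end_site])
        path_len = spec.replay_speed * move_span
        start_angle = end_angle - sign * path_len
        t_move = ta + dwell  # moving phase: [t_move, t_move + move_span]
        if spec.n_units == 0:
            truth_events.append(
                {
                    "t_start": float(ta), "t_end": float(tb),
                    "start_angle": float(start_angle % TWO_PI),
                    "end_angle": end_angle, "end_site": end_site,
                    "direction": direction, "swr_interval": [float(t0), float(t1)],
                }
            )
            continue
        # crossing time of each field center (mod 2*pi) along the moving path
        for u in range(spec.n_units):
            delta = (sign * (centers[u] - start_angle)) % TWO_PI
            # keep a short spike-free margin next to each dwell so the edge
            # windows are dominated by the start/end site units alone
            if 0.008 * spec.replay_speed <= delta <= path_len - 0.008 * spec.replay_speed:
                tc = t_move + delta / spec.replay_speed
                n_sp = 1 + rng.poisson(0.7)
                sp = tc + rng.normal(0.0, 0.002, size=n_sp)
                sp = sp[(sp >= t0) & (sp < t1)]
                trains[u].extend(sp.tolist())
        # dwell spikes from the units nearest the start and end angles
        u_start = int(np.argmin(np.abs((centers - start_angle + np.pi) % TWO_PI - np.pi)))
        u_end = int(np.argmin(np.abs((centers - end_angle + np.pi) % TWO_PI - np.pi)))
        dwell_offs = np.array([0.026, 0.0205, 0.015, 0.0095, 0.004])
        trains[u_start].extend((ta + dwell_offs).tolist())
        trains[u_end].extend((tb - dwell_offs).tolist())
        truth_events.append(
            {
                "t_start": float(ta),
                "t_end": float(tb),
                "start_angle": float(start_angle % TWO_PI),
                "end_angle": end_angle,
                "end_site": end_site,
                "direction": direction,
                "swr_interval": [float(t0), float(t1)],
            }
        )
    spikes = SpikeSet({u: np.sort(np.asarray(v)) for u, v in trains.items()})
    return spikes, truth_events


# ---------------------------------------------------------------------------
# LFP


def simulate_lfp(
    position: PositionSeries,
    spec: SimulationSpec,
    swr_intervals: list[tuple[float, float]] | None = None,
    rest_windows: list[tuple[float, float]] | None = None,
) -> LFPSet:
    """Multi-channel LFP: theta+gamma during movement, ripples during rest.

    Ripple packets (Hann-windowed ``ripple_freq`` sinusoids) are planted at
    the given intervals with amplitude ``ripple_amplitude_sd`` times the
    channel's background ripple-band envelope SD, so detector sensitivity
    can be tested directly against the 5-SD threshold.
    """
    swr_intervals = swr_intervals or []
    if rest_windows is not None:
        for s, e in swr_intervals:
            if not any(w0 <= s and e <= w1 for w0, w1 in rest_windows):
                raise ValueError(f"ripple interval ({s:.2f}, {e:.2f}) outside rest windows")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 16]))
    fs = spec.lfp_fs
    t = np.arange(position.times[0], position.times[-1], 1.0 / fs)
    speed = np.interp(t, position.times, position.speeds)
    moving = (speed > 5.0).astype(float)
    # phase 0 at oscillation peak: use cosines
    theta_wave = np.cos(TWO_PI * spec.theta_freq * t)
    sg_wave = np.cos(TWO_PI * 40.0 * t + 1.0)
    fg_wave = np.cos(TWO_PI * 80.0 * t + 2.0)
    amp_scale = 1.0 + 0.1 * np.arange(spec.n_channels)  # distinct theta power per channel
    rng.shuffle(amp_scale)

    sos = butter(4, [150.0, 250.0], btype="bandpass", fs=fs, output="sos")
    traces = np.empty((t.size, spec.n_channels))
    for ch in range(spec.n_channels):
        noise = rng.normal(0.0, spec.noise_sd, size=t.size)
        slow = gaussian_filter1d(rng.normal(0.0, spec.noise_sd, size=t.size), 30.0) * 6.0
        x = noise + slow + moving * amp_scale[ch] * (
            60.0 * theta_wave + 12.0 * sg_wave + 10.0 * fg_wave
        )
        if swr_intervals:
            bg_env = np.abs(hilbert(sosfiltfilt(sos, noise)))
            env_sd = bg_env.std()
            for s, e in swr_intervals:
                sel = (t >= s) & (t < e)
                n = int(sel.sum())
                if n == 0:
                    continue
                window = np.hanning(n)
                packet = np.cos(TWO_PI * spec.ripple_freq * (t[sel] - s))
                # Hann mean ~0.5: scale so the mid-event envelope hits the target
                x[sel] += 2.0 * spec.ripple_amplitude_sd * env_sd * window * packet
        traces[:, ch] = x
    return LFPSet(times=t, traces=traces, fs=fs, channel_ids=list(range(spec.n_channels)))


# ---------------------------------------------------------------------------
# full session


def build_session(
    geometry: TaskGeometry | None = None,
    spec: SimulationSpec | None = None,
    with_lfp: bool = True,
) -> tuple[SessionData, GroundTruth]:
    """Generate one complete session plus its ground-truth manifest.

    Pre-running laps, ``n_pairs`` sample-test pairs separated by 30-s
    within-pair rests and ~1-min inter-trial rests, then post-test trials;
    ripples and replay content are planted in every rest window.
    """
    geometry = geometry or TaskGeometry()
    spec = spec or SimulationSpec()
    schedule = build_trial_schedule(geometry, spec)
    position, trials = simulate_trajectory(geometry, spec, schedule)
    run_spikes = simulate_run_spikes(position, spec)

    # rest windows: gaps between trials plus the final tail
    rest = []
    tr = trials.sort_values("t_start_s").reset_index(drop=True)
    for i in range(len(tr) - 1):
        a, b = tr.loc[i, "t_stop_s"], tr.loc[i + 1, "t_start_s"]
        if b > a:
            rest.append((float(a), float(b)))
    rest.append((float(tr["t_stop_s"].max()), float(position.times[-1])))

    swr_intervals = plant_swr_intervals(rest, spec)
    replay_spikes, replay_truth = simulate_rest_replay(swr_intervals, spec, geometry)
    merged = {
        u: np.sort(
            np.concatenate([run_spikes.trains.get(u, np.empty(0)), replay_spikes.trains.get(u, np.empty(0))])
        )
        for u in range(spec.n_units)
    }
    spikes = SpikeSet(merged, t_start=position.times[0], t_stop=position.times[-1])

    lfp = (
        simulate_lfp(position, spec, swr_intervals, rest)
        if with_lfp
        else LFPSet(times=np.array([0.0]), traces=np.zeros((1, 1)), fs=spec.lfp_fs)
    )
    truth = GroundTruth(
        planted_swr_intervals=swr_intervals,
        planted_replays=replay_truth,
        true_precession_slope=spec.precession_slope,
        trial_labels=[
            {"trial_id": int(r["trial_id"]), "stop_site": int(r["stop_site"]),
             "outcome": r["outcome"]}
            for _, r in trials.iterrows()
        ],
    )
    session = SessionData(
        spikes=spikes, position=position, lfp=lfp, trials=trials, geometry=geometry
    ).validate()
    return session, truth


def two_condition_specs(base: SimulationSpec) -> tuple[SimulationSpec, SimulationSpec]:
    """A steep-sequence and a shallow-sequence variant of ``base``.

    The two specs differ only in ``precession_slope``; the first yields
    steeper decodable sequences (the 'correct-trial' analogue), the second
    shallower ones (the 'error-trial' analogue).
    """
    return (
        replace(base, precession_slope=3.0),
        replace(base, precession_slope=12.0),
    )


def planted_replay_events(
    geometry: TaskGeometry,
    spec: SimulationSpec,
    n_events: int,
    interval_spacing: float = 1.0,
):
    """Plant, decode, and qualify ``n_events`` replay events in isolation.

    Builds a bare sequence of ripple intervals, plants replay spiking in
    them, and runs the replay qualifier against the programmed-tuning rate
    map — the fast path for calibrating the bias test, where the rest of
    the session is irrelevant.

    Returns (qualified ReplayEvents, planted truth dicts).
    """
    from .replay import SWREvent, qualify_replay

    intervals = [
        (0.5 + i * interval_spacing, 0.5 + i * interval_spacing + spec.ripple_duration)
        for i in range(n_events)
    ]
    spikes, truth = simulate_rest_replay(intervals, spec, geometry)
    maps = analytic_rate_map(spec)
    events = []
    for t0, t1 in intervals:
        swr = SWREvent(t_start=t0, t_end=t1, core_start=t0, core_end=t1, peak_z=10.0)
        ev = qualify_replay(swr, spikes, maps, geometry)
        if ev is not None:
            events.append(ev)
    return events, truth
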