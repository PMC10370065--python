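"""Generative model of a human observer in the crosshair-tracking task.

Produces everything the real experiment records: Weibull identification
responses, a cursor trace that pursues the moving crosshair (lag plus
Gaussian noise), and a gaze trace with smooth pursuit, anisotropic
fixational jitter, occasional "peeks" toward the peripheral target
during stimulus presentation, post-stimulus "looking at nothing"
saccades, and a constant per-session eye-tracker calibration bias.
:func:`simulate_session_logs` runs a full QUEST-driven session through
the trial engine and emits the two timestamped log streams on a shared
POSIX clock: a 60 Hz frame log and a 100 Hz (10 ms) gaze log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .geometry import (
    CrosshairTrajectory,
    DisplayGeometry,
    crosshair_position_at,
    visual_to_screen,
)
from .quest import (
    PsychometricParams,
    estimate_threshold,
    init_state,
    propose_intensity,
    psychometric_probability,
    update_state,
)

__all__ = [
    "ObserverModel",
    "GazeTrace",
    "SessionLogs",
    "simulate_identification",
    "simulate_cursor_trace",
    "simulate_gaze_trace",
    "simulate_session_logs",
    "simulate_threshold_table",
]

#: POSIX clock origin for simulated sessions (an arbitrary 2023 instant).
DEFAULT_T0_POSIX = 1_700_000_000.0


@dataclass(frozen=True)
class ObserverModel:
    """Generative parameters of one simulated observer.

    Thresholds are per meridian in log10 deg.  Gaze jitter is white (or
    optionally AR(1)) Gaussian around the pursued crosshair, wider
    horizontally than vertically as is typical of fixational eye
    movements.  ``calibration_offset_deg`` is the constant reporting bias
    of the eye tracker for this session, in visual degrees; the default
    has a 0.64 deg radial magnitude.  The tracker logs one gaze sample
    every 10 ms (100 Hz).
    """

    log10_threshold_left: float = math.log10(3.0)
    log10_threshold_right: float = math.log10(3.0)
    beta: float = 2.3
    lapse_rate: float = 0.01
    gaze_jitter_sd_x_deg: float = 0.45
    gaze_jitter_sd_y_deg: float = 0.37
    gaze_jitter_ar1: float = 0.0
    pursuit_lag_s: float = 0.10
    peek_probability: float = 0.05
    peek_latency_s: float = 0.12
    peek_landing_sd_deg: float = 1.0
    look_at_nothing_probability: float = 0.9
    look_at_nothing_latency_s: float = 0.15
    look_at_nothing_sd_deg: float = 1.0
    cursor_lag_s: float = 0.05
    cursor_noise_sd_deg: float = 0.08 / math.sqrt(2.0)
    calibration_offset_deg: tuple[float, float] = (0.5, -0.4)
    tracker_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "gaze_jitter_sd_x_deg",
            "gaze_jitter_sd_y_deg",
            "peek_landing_sd_deg",
            "look_at_nothing_sd_deg",
            "cursor_noise_sd_deg",
        ):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("peek_probability", "look_at_nothing_probability"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1.0 < self.gaze_jitter_ar1 < 1.0:
            raise ValueError("gaze_jitter_ar1 must lie in (-1, 1)")
        if self.tracker_rate_hz <= 0.0:
            raise ValueError("tracker_rate_hz must be > 0")

    def true_log10_threshold(self, eccentricity_deg: float) -> float:
        """True threshold for the meridian containing ``eccentricity_deg``."""
        return self.log10_threshold_left if eccentricity_deg < 0 else self.log10_threshold_right


def simulate_identification(
    spacing_deg: float,
    eccentricity_deg: float,
    observer: ObserverModel,
    rng: np.random.Generator,
    target: str | None = None,
    character_set: str = "DHKNORSVZ",
) -> tuple[str, bool]:
    """One identification response at the given letter spacing.

    Correct with probability given by the observer's Weibull function for
    that meridian; an incorrect response is drawn uniformly from the
    non-target letters.  Returns ``(response_letter, correct)``.
    """
    if spacing_deg <= 0.0:
        raise ValueError(f"spacing_deg must be > 0, got {spacing_deg!r}")
    letters = list(character_set)
    if target is None:
        target = letters[rng.integers(len(letters))]
    params = PsychometricParams(
        guess_rate=1.0 / len(letters),
        lapse_rate=observer.lapse_rate,
        beta=observer.beta,
    )
    p = psychometric_probability(
        math.log10(spacing_deg), observer.true_log10_threshold(eccentricity_deg), params
    )
    correct = bool(rng.random() < p)
    if correct:
        return target, True
    others = [c for c in letters if c != target]
    return others[rng.integers(len(others))], False


def _jitter(n: int, sd: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian jitter, white by default or AR(1) when ``rho`` is nonzero."""
    w = rng.normal(0.0, sd, size=n)
    if rho == 0.0 or n == 0:
        return w
    innovations = w * math.sqrt(1.0 - rho * rho)
    out = lfilter([1.0], [1.0, -rho], innovations)
    out[0] = w[0]  # start at stationary variance
    return out


def simulate_cursor_trace(
    times_s,
    traj: CrosshairTrajectory,
    geometry: DisplayGeometry,
    observer: ObserverModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cursor positions (px) at the given trajectory times.

    The cursor follows the crosshair delayed by ``cursor_lag_s`` with
    isotropic Gaussian noise of ``cursor_noise_sd_deg`` per axis.
    """
    t = np.asarray(times_s, dtype=float)
    pos = crosshair_position_at(t - observer.cursor_lag_s, traj, geometry)
    sd_px = observer.cursor_noise_sd_deg * geometry.px_per_deg
    if sd_px > 0.0:
        pos = pos + rng.normal(0.0, sd_px, size=pos.shape)
    return pos


@dataclass(frozen=True)
class GazeTrace:
    """Gaze samples (px) for one trial segment plus the latent choices made."""

    samples_px: np.ndarray
    peeked: bool
    looked_at_nothing: bool


def simulate_gaze_trace(
    times_s,
    traj: CrosshairTrajectory,
    geometry: DisplayGeometry,
    observer: ObserverModel,
    rng: np.random.Generator,
    onset_s: float | None = None,
    offset_s: float | None = None,
    target_px=None,
) -> GazeTrace:
    """Gaze positions (px) for one trial's tracker samples.

    Before stimulus onset gaze pursues the crosshair delayed by
    ``pursuit_lag_s``.  From onset (the crosshair is hidden) gaze holds
    at the last pursued position.  With probability ``peek_probability``
    a saccade lands near the target ``peek_latency_s`` after onset and
    returns at offset; with probability ``look_at_nothing_probability``
    gaze revisits the now-empty target location after offset.  Jitter and
    the calibration offset are added to every sample.
    """
    t = np.asarray(times_s, dtype=float)
    base = crosshair_position_at(t - observer.pursuit_lag_s, traj, geometry)
    peeked = looked = False
    if onset_s is not None:
        hold = crosshair_position_at(onset_s - observer.pursuit_lag_s, traj, geometry)
        base[t >= onset_s] = hold
        # latent draws happen unconditionally so the stream stays aligned
        peek_draw = rng.random()
        peek_landing = rng.normal(0.0, observer.peek_landing_sd_deg * geometry.px_per_deg, 2)
        lan_draw = rng.random()
        lan_landing = rng.normal(0.0, observer.look_at_nothing_sd_deg * geometry.px_per_deg, 2)
        if target_px is not None and offset_s is not None:
            target_px = np.asarray(target_px, dtype=float)
            if peek_draw < observer.peek_probability:
                peeked = True
                m = (t >= onset_s + observer.peek_latency_s) & (t < offset_s)
                base[m] = target_px + peek_landing
            if lan_draw < observer.look_at_nothing_probability:
                looked = True
                m = t >= offset_s + observer.look_at_nothing_latency_s
                base[m] = target_px + lan_landing
    ppd = geometry.px_per_deg
    base[..., 0] += _jitter(len(t), observer.gaze_jitter_sd_x_deg * ppd, observer.gaze_jitter_ar1, rng)
    base[..., 1] += _jitter(len(t), observer.gaze_jitter_sd_y_deg * ppd, observer.gaze_jitter_ar1, rng)
    dx, dy = observer.calibration_offset_deg
    base[..., 0] += dx * ppd
    base[..., 1] -= dy * ppd  # visual y up, screen y down
    return GazeTrace(samples_px=base, peeked=peeked, looked_at_nothing=looked)


@dataclass
class SessionLogs:
    """All artifacts of one simulated session.

    ``frames`` is the 60 Hz stimulus log, ``gaze`` the 100 Hz tracker
    log; both share the same POSIX clock.  ``trials`` has one row per
    trial including the latent peek/look-at-nothing flags, and
    ``thresholds`` one row per block x meridian.
    """

    frames: pd.DataFrame
    gaze: pd.DataFrame
    trials: pd.DataFrame
    thresholds: pd.DataFrame
    observer: ObserverModel
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)


def simulate_session_logs(
    observer: ObserverModel,
    config=None,
    geometry: DisplayGeometry | None = None,
    rng: np.random.Generator | None = None,
    staircase_kwargs: dict | None = None,
    t0_posix: float = DEFAULT_T0_POSIX,
    observer_id: str = "S1",
    method: str = "easyeyes_lab",
) -> SessionLogs:
    """Run a full QUEST-driven session and emit both log streams.

    Blocks map to sessions of the test-retest design: block 1 is the
    "test" measurement, block 2 the "retest".  Each block interleaves the
    left and right meridian conditions and yields one threshold per
    meridian.
    """
    from .trial import TaskConfig, run_trial, schedule_session

    if config is None:
        config = TaskConfig()
    if geometry is None:
        geometry = DisplayGeometry()
    if rng is None:
        rng = np.random.default_rng()
    staircase_kwargs = dict(staircase_kwargs or {})
    staircase_kwargs.setdefault(
        "params", PsychometricParams(guess_rate=1.0 / len(config.character_set))
    )

    fps = config.frame_rate_hz
    frame_counter = 0
    frame_parts: list[pd.DataFrame] = []
    trial_rows: list[dict] = []
    threshold_rows: list[dict] = []
    segments: list[dict] = []
    session_names = ("test", "retest")
    schedule = schedule_session(config, rng)
    trial_index = 0
    for block_idx, block in enumerate(schedule.blocks):
        states = {ecc: init_state(**staircase_kwargs) for ecc in config.eccentricities_deg}
        for ecc in block:
            track_start = t0_posix + frame_counter / fps
            record, states[ecc] = run_trial(
                states[ecc],
                observer,
                config,
                geometry,
                rng,
                eccentricity_deg=ecc,
                trial_index=trial_index,
                t0_posix=t0_posix,
                start_frame=frame_counter,
            )
            frame_parts.append(record.frames)
            frame_counter += len(record.frames)
            end = t0_posix + frame_counter / fps
            segments.append(
                {
                    "track_start": track_start,
                    "onset": record.onset_posix,
                    "offset": record.offset_posix,
                    "end": end,
                    "traj": record.trajectory,
                    "target_px": record.target_px,
                }
            )
            trial_rows.append(
                {
                    "trial": trial_index,
                    "block": block_idx + 1,
                    "session": session_names[block_idx % 2],
                    "eccentricity_deg": ecc,
                    "spacing_deg": record.stimulus.spacing_deg,
                    "size_deg": record.stimulus.size_deg,
                    "target": record.stimulus.target_letter,
                    "flanker_left": record.stimulus.flanker_left,
                    "flanker_right": record.stimulus.flanker_right,
                    "response": record.response_letter,
                    "correct": record.correct,
                    "timer_s": record.timer_duration_s,
                    "restarts": record.n_restarts,
                    "track_start_posix": track_start,
                    "onset_posix": record.onset_posix,
                    "offset_posix": record.offset_posix,
                    "phase_rad": record.trajectory.initial_phase_rad,
                }
            )
            trial_index += 1
        for ecc, state in states.items():
            est = estimate_threshold(state)
            threshold_rows.append(
                {
                    "observer": observer_id,
                    "method": method,
                    "meridian": ecc,
                    "session": session_names[block_idx % 2],
                    "threshold_deg": est.threshold_deg,
                    "log10_threshold": est.log10_threshold_deg,
                    "posterior_sd": est.posterior_sd,
                }
            )

    # gaze stream: one global 10 ms grid sliced into per-trial segments
    rate = observer.tracker_rate_hz
    session_end = segments[-1]["end"]
    n_gaze = int(math.floor((session_end - t0_posix) * rate - 1e-9)) + 1
    gaze_t = t0_posix + np.arange(n_gaze) / rate
    gaze_xy = np.empty((n_gaze, 2), dtype=float)
    for i, seg in enumerate(segments):
        lo = np.searchsorted(gaze_t, seg["track_start"] - 1e-9, side="left")
        hi = np.searchsorted(gaze_t, seg["end"] - 1e-9, side="left") if i < len(segments) - 1 else n_gaze
        rel = gaze_t[lo:hi] - seg["track_start"]
        trace = simulate_gaze_trace(
            rel,
            seg["traj"],
            geometry,
            observer,
            rng,
            onset_s=seg["onset"] - seg["track_start"],
            offset_s=seg["offset"] - seg["track_start"],
            target_px=seg["target_px"],
        )
        gaze_xy[lo:hi] = trace.samples_px
        trial_rows[i]["peeked_true"] = trace.peeked
        trial_rows[i]["looked_at_nothing_true"] = trace.looked_at_nothing

    frames = pd.concat(frame_parts, ignore_index=True)
    gaze = pd.DataFrame(
        {"t_posix": gaze_t, "gazeX_px": gaze_xy[:, 0], "gazeY_px": gaze_xy[:, 1]}
    )
    return SessionLogs(
        frames=frames,
        gaze=gaze,
        trials=pd.DataFrame(trial_rows),
        thresholds=pd.DataFrame(threshold_rows),
        observer=observer,
        geometry=geometry,
    )


def simulate_threshold_table(
    rng: np.random.Generator,
    n_observers: int = 12,
    methods: tuple[str, ...] = ("criticalspacing_lab", "easyeyes_lab", "easyeyes_home"),
    sessions: tuple[str, ...] = ("test", "retest"),
    meridians: tuple[float, ...] = (-10.0, 10.0),
    base_threshold_deg: float = 3.0,
    observer_sd_log: float = 0.2,
    meridian_sd_log: float = 0.05,
    retest_threshold_ratio: float = 0.8,
    n_trials: int = 35,
    beta: float = 2.3,
    lapse_rate: float = 0.01,
) -> pd.DataFrame:
    """Threshold table for a cohort, one 35-trial staircase per cell.

    Each observer has a latent log threshold (between-observer SD 0.2 log
    units) shared across methods, a small per-meridian deviation, and a
    practice effect shrinking retest thresholds by the given ratio.
    Methods add no systematic effect, reflecting equivalence of the
    measurement procedures.
    """
    rows = []
    params = PsychometricParams(beta=beta, lapse_rate=lapse_rate)
    retest_shift = math.log10(retest_threshold_ratio)
    for i in range(n_observers):
        base = math.log10(base_threshold_deg) + rng.normal(0.0, observer_sd_log)
        per_meridian = {m: base + rng.normal(0.0, meridian_sd_log) for m in meridians}
        for method in methods:
            for session_idx, session in enumerate(sessions):
                for m in meridians:
                    truth = per_meridian[m] + (retest_shift if session_idx > 0 else 0.0)
                    state = init_state(params=params)
                    for _ in range(n_trials):
                        x = propose_intensity(state)
                        p = psychometric_probability(x, truth, params)
                        state = update_state(state, x, bool(rng.random() < p))
                    est = estimate_threshold(state)
                    rows.append(
                        {
                            "observer": f"S{i + 1}",
                            "method": method,
                            "meridian": m,
                            "session": session,
                            "threshold_deg": est.threshold_deg,
                            "log10_threshold": est.log10_threshold_deg,
                            "posterior_sd": est.posterior_sd,
                        }
                    )
    return pd.DataFrame(rows)
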