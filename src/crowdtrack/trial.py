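"""Discrete-time engine for cursor-tracked crowding trials.

A trial unfolds at the 60 Hz display rate: a tracking epoch in which the
observer keeps the cursor tip inside the moving crosshair's invisible
0.1 deg hotspot, an unannounced timer drawn uniformly from 0.75-1.25 s,
a 150 ms trigram presentation with crosshair and cursor hidden, and a
700 ms pause before the identification response.  A session comprises
two blocks of 70 trials, each block randomly interleaving the -10 and
+10 deg meridian conditions (35 trials each).

Two tracking criteria are offered.  ``endpoints`` (default, the original
protocol) checks the cursor only when the timer starts and fires;
``continuous`` (the later, stricter protocol) aborts the interval on any
frame where the cursor leaves the hotspot.

:func:`run_awaited_fixation_trial` implements the classic
gaze-contingent comparison mode: a static crosshair, stimulus onset
after 250 ms of fixation within 1.5 deg, trial rejection on fixation
loss during the stimulus, and a recalibration prompt after a 10 s wait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    CrosshairTrajectory,
    DisplayGeometry,
    crosshair_position_at,
    screen_to_visual,
    visual_to_screen,
)
from .observer import ObserverModel, simulate_cursor_trace, simulate_identification
from .quest import QuestState, propose_intensity, update_state

__all__ = [
    "TaskConfig",
    "SessionSchedule",
    "StimulusSpec",
    "TrackingResult",
    "TrackingTimeout",
    "TrialRecord",
    "AwaitedFixationRecord",
    "schedule_session",
    "draw_trigram",
    "make_stimulus",
    "run_tracking_interval",
    "run_trial",
    "run_awaited_fixation_trial",
]

FRAME_COLUMNS = [
    "t_posix",
    "crosshairX_px",
    "crosshairY_px",
    "cursorX_px",
    "cursorY_px",
    "targetX_px",
    "targetY_px",
    "bold",
    "epoch",
]


@dataclass(frozen=True)
class TaskConfig:
    """Geometry-independent parameters of the identification task."""

    eccentricities_deg: tuple[float, ...] = (-10.0, 10.0)
    target_duration_s: float = 0.15
    spacing_to_size_ratio: float = 1.4
    character_set: str = "DHKNORSVZ"
    hotspot_radius_deg: float = 0.1
    timer_range_s: tuple[float, float] = (0.75, 1.25)
    frame_rate_hz: float = 60.0
    tracking_criterion: str = "endpoints"
    response_delay_s: float = 0.70
    trials_per_condition: int = 35
    blocks_per_session: int = 2
    tracking_timeout_s: float = 60.0

    def __post_init__(self) -> None:
        if self.spacing_to_size_ratio <= 1.0:
            raise ValueError("spacing_to_size_ratio must be > 1")
        if self.target_duration_s <= 0.0:
            raise ValueError("target_duration_s must be > 0")
        lo, hi = self.timer_range_s
        if not lo < hi:
            raise ValueError("timer_range_s must be ascending")
        if len(set(self.character_set)) != len(self.character_set) or len(self.character_set) < 3:
            raise ValueError("character_set must contain at least 3 distinct letters")
        if self.tracking_criterion not in ("endpoints", "continuous"):
            raise ValueError("tracking_criterion must be 'endpoints' or 'continuous'")
        if self.frame_rate_hz <= 0.0:
            raise ValueError("frame_rate_hz must be > 0")

    @property
    def conditions_per_block(self) -> int:
        return len(self.eccentricities_deg)


@dataclass(frozen=True)
class SessionSchedule:
    """Condition order for each block of a session."""

    blocks: tuple[tuple[float, ...], ...]

    @property
    def trials_per_block(self) -> int:
        return len(self.blocks[0])

    @property
    def total_trials(self) -> int:
        return sum(len(b) for b in self.blocks)


def schedule_session(config: TaskConfig, rng: np.random.Generator) -> SessionSchedule:
    """Randomly interleaved condition order with exact per-condition counts."""
    blocks = []
    for _ in range(config.blocks_per_session):
        labels = np.repeat(config.eccentricities_deg, config.trials_per_condition)
        blocks.append(tuple(float(x) for x in rng.permutation(labels)))
    return SessionSchedule(blocks=tuple(blocks))


def draw_trigram(rng: np.random.Generator, character_set: str = "DHKNORSVZ") -> tuple[str, str, str]:
    """Target and two flankers, distinct, uniform without replacement."""
    letters = list(character_set)
    if len(letters) < 3 or len(set(letters)) != len(letters):
        raise ValueError("character_set must contain at least 3 distinct letters")
    picked = rng.choice(letters, size=3, replace=False)
    return str(picked[0]), str(picked[1]), str(picked[2])


@dataclass(frozen=True)
class StimulusSpec:
    """One trigram stimulus: letters, spacing, size, and layout.

    Flankers sit radially (along the horizontal meridian), symmetric
    about the target at center-to-center distance ``spacing_deg``.
    Letter size is locked to spacing by the 1.4:1 ratio.
    """

    target_letter: str
    flanker_left: str
    flanker_right: str
    eccentricity_x_deg: float
    spacing_deg: float
    size_deg: float

    @property
    def target_position_deg(self) -> tuple[float, float]:
        return (self.eccentricity_x_deg, 0.0)

    @property
    def flanker_positions_deg(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (
            (self.eccentricity_x_deg - self.spacing_deg, 0.0),
            (self.eccentricity_x_deg + self.spacing_deg, 0.0),
        )


def make_stimulus(
    spacing_deg: float,
    eccentricity_x_deg: float,
    trigram: tuple[str, str, str],
    config: TaskConfig,
) -> StimulusSpec:
    """Stimulus spec with size locked to spacing by the configured ratio."""
    if spacing_deg <= 0.0:
        raise ValueError(f"spacing_deg must be > 0, got {spacing_deg!r}")
    target, left, right = trigram
    return StimulusSpec(
        target_letter=target,
        flanker_left=left,
        flanker_right=right,
        eccentricity_x_deg=float(eccentricity_x_deg),
        spacing_deg=float(spacing_deg),
        size_deg=float(spacing_deg) / config.spacing_to_size_ratio,
    )


@dataclass(frozen=True)
class TrackingResult:
    """Outcome of one tracking interval."""

    fire_frame: int | None
    fire_time_s: float | None
    timer_duration_s: float | None
    n_restarts: int
    timed_out: bool


class TrackingTimeout(RuntimeError):
    """The cursor never satisfied the tracking criterion within the trace."""


def run_tracking_interval(
    cursor_px: np.ndarray,
    traj: CrosshairTrajectory,
    geometry: DisplayGeometry,
    config: TaskConfig,
    rng: np.random.Generator,
) -> TrackingResult:
    """Find when the random tracking timer first fires.

    ``cursor_px`` holds per-frame cursor positions starting at trajectory
    time 0.  The timer starts at the first frame with the cursor tip
    inside the hotspot, waits a uniform 0.75-1.25 s (quantized to the
    frame grid), and fires if the criterion holds: in ``endpoints`` mode
    the cursor must be back inside at the final frame; in ``continuous``
    mode it must stay inside throughout.  On failure the timer restarts
    at the next frame with the cursor inside, without disturbing the
    crosshair's motion.
    """
    cursor = np.asarray(cursor_px, dtype=float)
    n = len(cursor)
    fps = config.frame_rate_hz
    times = np.arange(n) / fps
    crosshair = crosshair_position_at(times, traj, geometry)
    dev = screen_to_visual(cursor, geometry, crosshair)
    inside = np.hypot(dev[..., 0], dev[..., 1]) <= config.hotspot_radius_deg
    inside_idx = np.flatnonzero(inside)

    def next_inside(after: int) -> int | None:
        k = np.searchsorted(inside_idx, after, side="left")
        return int(inside_idx[k]) if k < len(inside_idx) else None

    restarts = 0
    i = next_inside(0)
    while i is not None:
        duration_frames = int(round(rng.uniform(*config.timer_range_s) * fps))
        j = i + duration_frames
        if j >= n:
            break
        if config.tracking_criterion == "endpoints":
            ok = inside[j]
            resume = j + 1
        else:
            exits = np.flatnonzero(~inside[i : j + 1])
            ok = len(exits) == 0
            resume = i + int(exits[0]) + 1 if not ok else j + 1
        if ok:
            return TrackingResult(
                fire_frame=j,
                fire_time_s=j / fps,
                timer_duration_s=duration_frames / fps,
                n_restarts=restarts,
                timed_out=False,
            )
        restarts += 1
        i = next_inside(resume)
    return TrackingResult(
        fire_frame=None,
        fire_time_s=None,
        timer_duration_s=None,
        n_restarts=restarts,
        timed_out=True,
    )


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial: timeline, stimulus, response, and frame log."""

    trial_index: int
    eccentricity_deg: float
    timer_duration_s: float
    n_restarts: int
    stimulus: StimulusSpec
    onset_posix: float
    offset_posix: float
    response_letter: str
    correct: bool
    frames: pd.DataFrame
    trajectory: CrosshairTrajectory
    target_px: tuple[float, float]


def run_trial(
    state: QuestState,
    observer: ObserverModel,
    config: TaskConfig,
    geometry: DisplayGeometry,
    rng: np.random.Generator,
    *,
    eccentricity_deg: float,
    trial_index: int = 0,
    t0_posix: float = 0.0,
    start_frame: int = 0,
) -> tuple[TrialRecord, QuestState]:
    """Run one QUEST-driven trial and return its record and updated state.

    The frame log covers the tracking epoch (crosshair, cursor, bold
    flag), the stimulus epoch (target only: crosshair and cursor are
    hidden, so their fields are empty), and the response-delay epoch
    (all positions empty).  Raises :class:`TrackingTimeout` if the
    cursor never satisfies the criterion within the timeout.
    """
    fps = config.frame_rate_hz
    x = propose_intensity(state)
    spacing = 10.0 ** x
    trigram = draw_trigram(rng, config.character_set)
    stimulus = make_stimulus(spacing, eccentricity_deg, trigram, config)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    traj = CrosshairTrajectory(center_px=geometry.screen_center_px, initial_phase_rad=phase)

    n_track_max = int(round(config.tracking_timeout_s * fps))
    track_times = np.arange(n_track_max) / fps
    cursor = simulate_cursor_trace(track_times, traj, geometry, observer, rng)
    tracking = run_tracking_interval(cursor, traj, geometry, config, rng)
    if tracking.timed_out:
        raise TrackingTimeout(
            f"trial {trial_index}: cursor never satisfied the tracking criterion "
            f"within {config.tracking_timeout_s} s"
        )
    k_fire = tracking.fire_frame
    n_stim = int(round(config.target_duration_s * fps))
    n_resp = int(round(config.response_delay_s * fps))
    n_total = k_fire + n_stim + n_resp

    # target anchored to the crosshair center at fire time
    anchor = crosshair_position_at(k_fire / fps, traj, geometry)
    target_px = visual_to_screen(stimulus.target_position_deg, geometry, anchor)

    t = t0_posix + (start_frame + np.arange(n_total)) / fps
    chx = np.full(n_total, np.nan)
    chy = np.full(n_total, np.nan)
    curx = np.full(n_total, np.nan)
    cury = np.full(n_total, np.nan)
    tgx = np.full(n_total, np.nan)
    tgy = np.full(n_total, np.nan)
    bold = np.zeros(n_total, dtype=int)
    epoch = np.empty(n_total, dtype=object)

    ch = crosshair_position_at(track_times[:k_fire], traj, geometry)
    chx[:k_fire], chy[:k_fire] = ch[:, 0], ch[:, 1]
    curx[:k_fire], cury[:k_fire] = cursor[:k_fire, 0], cursor[:k_fire, 1]
    track_dev = screen_to_visual(cursor[:k_fire], geometry, ch)
    bold[:k_fire] = (np.hypot(track_dev[:, 0], track_dev[:, 1]) <= config.hotspot_radius_deg).astype(int)
    epoch[:k_fire] = "tracking"
    tgx[k_fire : k_fire + n_stim] = target_px[0]
    tgy[k_fire : k_fire + n_stim] = target_px[1]
    epoch[k_fire : k_fire + n_stim] = "stimulus"
    epoch[k_fire + n_stim :] = "response"

    frames = pd.DataFrame(
        {
            "t_posix": t,
            "crosshairX_px": chx,
            "crosshairY_px": chy,
            "cursorX_px": curx,
            "cursorY_px": cury,
            "targetX_px": tgx,
            "targetY_px": tgy,
            "bold": bold,
            "epoch": epoch,
        }
    )

    onset = t0_posix + (start_frame + k_fire) / fps
    offset = t0_posix + (start_frame + k_fire + n_stim) / fps
    response, correct = simulate_identification(
        spacing,
        eccentricity_deg,
        observer,
        rng,
        target=stimulus.target_letter,
        character_set=config.character_set,
    )
    new_state = update_state(state, math.log10(spacing), correct)
    record = TrialRecord(
        trial_index=trial_index,
        eccentricity_deg=float(eccentricity_deg),
        timer_duration_s=tracking.timer_duration_s,
        n_restarts=tracking.n_restarts,
        stimulus=stimulus,
        onset_posix=onset,
        offset_posix=offset,
        response_letter=response,
        correct=correct,
        frames=frames,
        trajectory=traj,
        target_px=(float(target_px[0]), float(target_px[1])),
    )
    return record, new_state


@dataclass(frozen=True)
class AwaitedFixationRecord:
    """Outcome of one gaze-contingent (awaited-fixation) trial."""

    fired: bool
    onset_s: float | None
    offset_s: float | None
    rejected: bool
    recalibration_needed: bool
    wait_s: float


def run_awaited_fixation_trial(
    gaze_px: np.ndarray,
    config: TaskConfig,
    geometry: DisplayGeometry,
    *,
    crosshair_px=None,
    fixation_radius_deg: float = 1.5,
    fixation_duration_s: float = 0.25,
    recalibration_wait_s: float = 10.0,
    tracker_rate_hz: float = 100.0,
) -> AwaitedFixationRecord:
    """Gaze-contingent trial against a static crosshair.

    The stimulus fires once gaze has stayed within ``fixation_radius_deg``
    of the crosshair for ``fixation_duration_s``; the trial is rejected
    if gaze leaves that radius during the stimulus.  Waiting longer than
    ``recalibration_wait_s`` for fixation raises the recalibration flag.
    """
    gaze = np.asarray(gaze_px, dtype=float)
    if crosshair_px is None:
        crosshair_px = geometry.screen_center_px
    dev = screen_to_visual(gaze, geometry, crosshair_px)
    inside = np.hypot(dev[..., 0], dev[..., 1]) <= fixation_radius_deg
    n_fix = int(round(fixation_duration_s * tracker_rate_hz))
    n_stim = int(round(config.target_duration_s * tracker_rate_hz))

    onset_idx = None
    run = 0
    for k, ok in enumerate(inside):
        run = run + 1 if ok else 0
        if run >= n_fix:
            onset_idx = k + 1
            break
    if onset_idx is None:
        wait = len(inside) / tracker_rate_hz
        return AwaitedFixationRecord(
            fired=False,
            onset_s=None,
            offset_s=None,
            rejected=False,
            recalibration_needed=wait > recalibration_wait_s,
            wait_s=wait,
        )
    onset_s = onset_idx / tracker_rate_hz
    stim = inside[onset_idx : onset_idx + n_stim]
    return AwaitedFixationRecord(
        fired=True,
        onset_s=onset_s,
        offset_s=onset_s + config.target_duration_s,
        rejected=bool((~stim).any()),
        recalibration_needed=onset_s > recalibration_wait_s,
        wait_s=onset_s,
    )
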