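"""Experiment configuration: validated YAML blocks mapped to domain objects.

A config file has up to six top-level blocks -- ``geometry``, ``task``,
``staircase``, ``observer`` (simulation only), ``analysis`` -- plus a
``seed``.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import math
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .geometry import DisplayGeometry
from .io import sha256_of_config
from .observer import ObserverModel
from .quest import PsychometricParams
from .trial import TaskConfig

__all__ = [
    "ExperimentConfig",
    "load_config",
    "config_hash",
]

_TAN_1DEG = math.tan(math.radians(1.0))


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryBlock(_Strict):
    viewing_distance_cm: float = 40.0
    px_per_cm: float = 60.0 / (40.0 * _TAN_1DEG)
    screen_width_px: float = 1920.0
    screen_height_px: float = 1080.0
    tangent_mapping: bool = False

    def to_domain(self) -> DisplayGeometry:
        return DisplayGeometry(**self.model_dump())


class TaskBlock(_Strict):
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

    def to_domain(self) -> TaskConfig:
        return TaskConfig(**self.model_dump())


class StaircaseBlock(_Strict):
    prior_guess_deg: float = 3.0
    prior_sd_log: float = 2.0
    beta: float = 2.3
    lapse_rate: float = 0.01
    guess_rate: float = 1.0 / 9.0
    criterion: float = 0.70
    n_trials: int = 35
    spacing_min_deg: float = 0.2
    spacing_max_deg: float = 12.0
    grid_step: float = 0.005

    def psychometric_params(self) -> PsychometricParams:
        return PsychometricParams(
            guess_rate=self.guess_rate,
            lapse_rate=self.lapse_rate,
            beta=self.beta,
            criterion=self.criterion,
        )

    def init_kwargs(self) -> dict:
        return {
            "prior_guess_deg": self.prior_guess_deg,
            "prior_sd_log": self.prior_sd_log,
            "params": self.psychometric_params(),
            "spacing_bounds_deg": (self.spacing_min_deg, self.spacing_max_deg),
            "grid_step": self.grid_step,
        }


class ObserverBlock(_Strict):
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

    def to_domain(self) -> ObserverModel:
        return ObserverModel(**self.model_dump())


class AnalysisBlock(_Strict):
    criterion_deg: float = 1.5
    tolerance_s: float = 0.010
    pre_window_s: float = 0.75
    post_window_s: float = 0.55
    rmse_aggregation: str = "per_trial"
    apply_offset_correction: bool = True


class ExperimentConfig(_Strict):
    seed: int = 0
    geometry: GeometryBlock = GeometryBlock()
    task: TaskBlock = TaskBlock()
    staircase: StaircaseBlock = StaircaseBlock()
    observer: ObserverBlock = ObserverBlock()
    analysis: AnalysisBlock = AnalysisBlock()


def load_config(path) -> ExperimentConfig:
    """Parse and validate a YAML experiment configuration."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return ExperimentConfig.model_validate(payload)


def config_hash(config: ExperimentConfig) -> str:
    """SHA-256 over the canonical JSON dump; changes iff a field changes."""
    return sha256_of_config(config.model_dump(mode="json"))
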