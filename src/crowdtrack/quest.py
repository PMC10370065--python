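"""Grid-based Bayesian adaptive staircase (QUEST) over log letter spacing.

The staircase maintains a discrete posterior over the log10
crowding-distance threshold, places each trial at the posterior mean
(the robust "mean" variant of QUEST), and reports the posterior mean as
the final threshold.  The psychometric family is a Weibull in log10
spacing, shifted so that the function passes through the criterion
proportion correct (default 70%) exactly at threshold:

    psi(x | T) = delta*gamma
               + (1 - delta) * (1 - (1 - gamma) * exp(-10**(beta*(x - T + eps))))

with guess rate ``gamma`` (1/9 for nine-alternative letter
identification), lapse rate ``delta``, steepness ``beta``, and ``eps``
solving ``psi(T | T) = criterion``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "PsychometricParams",
    "QuestState",
    "ThresholdEstimate",
    "psychometric_probability",
    "init_state",
    "propose_intensity",
    "update_state",
    "estimate_threshold",
    "run_staircase",
]


@dataclass(frozen=True)
class PsychometricParams:
    """Weibull psychometric-function parameters for letter identification."""

    guess_rate: float = 1.0 / 9.0
    lapse_rate: float = 0.01
    beta: float = 2.3
    criterion: float = 0.70

    def __post_init__(self) -> None:
        if not 0.0 < self.guess_rate < 1.0:
            raise ValueError(f"guess_rate must lie in (0, 1), got {self.guess_rate!r}")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError(f"lapse_rate must lie in [0, 1), got {self.lapse_rate!r}")
        if not self.beta > 0.0:
            raise ValueError(f"beta must be > 0, got {self.beta!r}")
        ceiling = 1.0 - self.lapse_rate * (1.0 - self.guess_rate)
        if not self.guess_rate < self.criterion < ceiling:
            raise ValueError(
                "criterion must lie strictly between the guess rate "
                f"({self.guess_rate:.4f}) and the lapse ceiling ({ceiling:.4f}), "
                f"got {self.criterion!r}"
            )

    @property
    def threshold_shift(self) -> float:
        """Offset ``eps`` making psi equal the criterion exactly at threshold."""
        g, d, pc = self.guess_rate, self.lapse_rate, self.criterion
        k = -math.log((d * g + (1.0 - d) - pc) / ((1.0 - d) * (1.0 - g)))
        return math.log10(k) / self.beta


def psychometric_probability(log_spacing, log_threshold, params: PsychometricParams):
    """Probability of a correct identification at ``log_spacing`` given a threshold.

    Vectorized over both arguments.  Ranges from the guess rate (tight
    spacing) to ``1 - lapse_rate*(1 - guess_rate)`` (wide spacing) and
    equals ``params.criterion`` exactly at ``log_spacing == log_threshold``.
    """
    x = np.asarray(log_spacing, dtype=float)
    t = np.asarray(log_threshold, dtype=float)
    with np.errstate(over="ignore"):
        expo = 10.0 ** (params.beta * (x - t + params.threshold_shift))
        surv = np.exp(-expo)
    p = params.lapse_rate * params.guess_rate + (1.0 - params.lapse_rate) * (
        1.0 - (1.0 - params.guess_rate) * surv
    )
    return p if p.shape else float(p)


@dataclass
class QuestState:
    """Posterior over log10 threshold on a fixed grid, plus trial history."""

    grid: np.ndarray
    log_posterior: np.ndarray
    params: PsychometricParams
    spacing_bounds_deg: tuple[float, float]
    history: list[tuple[float, bool]] = field(default_factory=list)

    @property
    def posterior(self) -> np.ndarray:
        """Normalized posterior masses over the grid (sums to 1)."""
        p = np.exp(self.log_posterior - self.log_posterior.max())
        return p / p.sum()

    @property
    def posterior_mean(self) -> float:
        return float(np.sum(self.grid * self.posterior))

    @property
    def posterior_sd(self) -> float:
        p = self.posterior
        mu = np.sum(self.grid * p)
        return float(np.sqrt(np.sum(p * (self.grid - mu) ** 2)))


@dataclass(frozen=True)
class ThresholdEstimate:
    """Final threshold from one staircase: posterior mean in log10 deg."""

    log10_threshold_deg: float
    threshold_deg: float
    n_trials: int
    posterior_sd: float


def init_state(
    prior_guess_deg: float = 3.0,
    prior_sd_log: float = 2.0,
    params: PsychometricParams | None = None,
    spacing_bounds_deg: tuple[float, float] = (0.2, 12.0),
    grid_range: tuple[float, float] = (-1.5, 1.5),
    grid_step: float = 0.005,
) -> QuestState:
    """Fresh staircase state with a Gaussian prior in log10 spacing.

    The default prior (3 deg guess, SD 2 log units) is nearly flat over
    the presentable spacing range and centered on a typical crowding
    distance at 10 deg eccentricity.
    """
    if params is None:
        params = PsychometricParams()
    lo, hi = spacing_bounds_deg
    if not (0.0 < lo < hi):
        raise ValueError(f"spacing bounds must satisfy 0 < lo < hi, got {spacing_bounds_deg!r}")
    if not lo <= prior_guess_deg <= hi:
        raise ValueError(
            f"prior_guess_deg {prior_guess_deg!r} outside spacing bounds {spacing_bounds_deg!r}"
        )
    if prior_sd_log <= 0.0:
        raise ValueError(f"prior_sd_log must be > 0, got {prior_sd_log!r}")
    g_lo, g_hi = grid_range
    n = int(round((g_hi - g_lo) / grid_step)) + 1
    grid = np.linspace(g_lo, g_hi, n)
    mu = math.log10(prior_guess_deg)
    log_post = -0.5 * ((grid - mu) / prior_sd_log) ** 2
    log_post -= logsumexp(log_post)
    return QuestState(
        grid=grid,
        log_posterior=log_post,
        params=params,
        spacing_bounds_deg=(float(lo), float(hi)),
    )


def propose_intensity(state: QuestState) -> float:
    """Next log10 spacing to test: posterior mean, clamped to the bounds."""
    lo, hi = state.spacing_bounds_deg
    return float(np.clip(state.posterior_mean, math.log10(lo), math.log10(hi)))


def update_state(state: QuestState, log_spacing: float, correct: bool) -> QuestState:
    """Bayesian update of the threshold posterior after one trial."""
    p = psychometric_probability(log_spacing, state.grid, state.params)
    with np.errstate(divide="ignore"):
        ll = np.log(p) if correct else np.log1p(-p)
    log_post = state.log_posterior + ll
    log_post -= logsumexp(log_post)
    return replace(
        state,
        log_posterior=log_post,
        history=state.history + [(float(log_spacing), bool(correct))],
    )


def estimate_threshold(state: QuestState) -> ThresholdEstimate:
    """Threshold after at least one trial: posterior mean of log10 spacing.

    By construction the psychometric function evaluated at the returned
    intensity, conditioned on the posterior-mean threshold parameter,
    equals the criterion proportion correct.
    """
    if not state.history:
        raise ValueError("cannot estimate a threshold from an empty trial history")
    mean = state.posterior_mean
    return ThresholdEstimate(
        log10_threshold_deg=mean,
        threshold_deg=10.0 ** mean,
        n_trials=len(state.history),
        posterior_sd=state.posterior_sd,
    )


def run_staircase(
    respond: Callable[[float], bool],
    n_trials: int = 35,
    state: QuestState | None = None,
    **init_kwargs,
) -> tuple[ThresholdEstimate, QuestState]:
    """Drive a staircase for ``n_trials`` trials against a response callback.

    ``respond(spacing_deg)`` must return whether the identification was
    correct at that spacing.  Extra keyword arguments go to
    :func:`init_state` when no initial state is supplied.
    """
    if state is None:
        state = init_state(**init_kwargs)
    for _ in range(n_trials):
        x = propose_intensity(state)
        correct = respond(10.0 ** x)
        state = update_state(state, x, correct)
    return estimate_threshold(state), state
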