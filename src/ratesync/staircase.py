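"""Weighted up-down (WUD) adaptive staircase for relative rate-difference thresholds.

The staircase tracks the relative difference
``d = (rate_comparison - rate_standard) / rate_standard``.  A correct response
reduces d by the current step size; an incorrect response increases it by
three times that step, so the procedure converges on the level where
p(correct) = 3/4 (down-step * p = up-step * (1 - p)).  The initial 1% step is
halved after six reversals and again after twelve; a run ends after 18
reversals, and the threshold is the mean of the last six reversal levels.
When d falls to or below one step size, a correct response halves d instead of
subtracting the step, which keeps d strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "ThresholdEstimate",
    "start_values",
    "new_state",
    "update",
    "is_complete",
    "estimate_threshold",
    "run_staircase",
]


@dataclass(frozen=True)
class StaircaseConfig:
    start_value: float = 0.20
    initial_step: float = 0.01
    step_halving_reversals: tuple = (6, 12)
    up_weight: float = 3.0
    stop_reversals: int = 18
    n_threshold_reversals: int = 6
    ceiling: float = 0.5          # maximal expected threshold; clips runaways
    max_trials: int = 1000        # safety bound for degenerate observers

    def __post_init__(self):
        if not self.start_value > 0:
            raise ValueError("start_value must be > 0")
        if not self.initial_step > 0:
            raise ValueError("initial_step must be > 0")
        if not self.up_weight >= 1:
            raise ValueError("up_weight must be >= 1")
        if not self.stop_reversals > self.n_threshold_reversals:
            raise ValueError("stop_reversals must exceed n_threshold_reversals")


@dataclass(frozen=True)
class StaircaseState:
    current_d: float
    current_step: float
    reversal_values: tuple = ()
    trial_log: tuple = ()          # (d_presented, correct, direction) per trial
    last_direction: str = "none"   # "down" | "up" | "none"
    n_clips: int = 0


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold: float
    rate_hz: float | None
    n_trials: int
    reversal_values: tuple
    complete: bool = True          # False iff terminated by the trial bound


def start_values(rate_grid) -> np.ndarray:
    """Start levels per standard rate: linearly spaced 20%..27% across 8 rates.

    Training runs use these plus 0.10 (30%..37%).
    """
    rate_grid = np.asarray(rate_grid)
    if rate_grid.size != 8:
        raise ValueError(f"expected a grid of 8 standard rates, got {rate_grid.size}")
    return np.linspace(0.20, 0.27, 8)


def new_state(config: StaircaseConfig) -> StaircaseState:
    return StaircaseState(current_d=config.start_value,
                          current_step=config.initial_step)


def is_complete(state: StaircaseState, config: StaircaseConfig) -> bool:
    return len(state.reversal_values) >= config.stop_reversals


def update(state: StaircaseState, config: StaircaseConfig,
           correct: bool) -> StaircaseState:
    """Advance the staircase by one trial with the given response.

    A reversal is recorded when the movement direction flips relative to the
    previous effective movement; the reversal value is the level presented on
    the flipping trial.  The step size halves when the cumulative reversal
    count reaches each entry of ``step_halving_reversals``.
    """
    if is_complete(state, config):
        raise RuntimeError("staircase already complete; no further updates allowed")

    d, step = state.current_d, state.current_step
    n_clips = state.n_clips
    if correct:
        direction = "down"
        new_d = d / 2.0 if d <= step else d - step
    else:
        direction = "up"
        new_d = d + config.up_weight * step
        if new_d > config.ceiling:
            new_d = config.ceiling
            n_clips += 1

    reversals = state.reversal_values
    if state.last_direction != "none" and direction != state.last_direction:
        reversals = reversals + (d,)

    new_step = config.initial_step
    for i, at in enumerate(sorted(config.step_halving_reversals)):
        if len(reversals) >= at:
            new_step = config.initial_step / 2.0 ** (i + 1)

    return replace(
        state,
        current_d=new_d,
        current_step=new_step,
        reversal_values=reversals,
        trial_log=state.trial_log + ((d, bool(correct), direction),),
        last_direction=direction,
        n_clips=n_clips,
    )


def estimate_threshold(state: StaircaseState, config: StaircaseConfig,
                       rate_hz: float | None = None) -> ThresholdEstimate:
    """Mean of the final ``n_threshold_reversals`` reversal levels."""
    if not is_complete(state, config):
        raise RuntimeError("staircase incomplete; cannot estimate threshold")
    tail = state.reversal_values[-config.n_threshold_reversals:]
    return ThresholdEstimate(
        threshold=float(np.mean(tail)), rate_hz=rate_hz,
        n_trials=len(state.trial_log), reversal_values=tail,
    )


def run_staircase(observer, config: StaircaseConfig, seed=None,
                  rate_hz: float | None = None):
    """Run a full adaptive track against a simulated observer.

    The observer must expose ``p_correct(d) -> probability``.  Responses are
    Bernoulli draws, so runs are reproducible under ``seed``.  Degenerate
    observers that never reverse (e.g. always correct) are cut off at
    ``config.max_trials``; the estimate then falls back to the mean of the
    available reversal tail, or of the last six presented levels if there were
    none, and is flagged ``complete=False``.

    Returns ``(ThresholdEstimate, trial_log_dataframe)``.
    """
    rng = np.random.default_rng(seed)
    state = new_state(config)
    while not is_complete(state, config) and len(state.trial_log) < config.max_trials:
        p = float(observer.p_correct(state.current_d))
        state = update(state, config, correct=bool(rng.random() < p))

    if is_complete(state, config):
        est = estimate_threshold(state, config, rate_hz=rate_hz)
    else:
        tail = state.reversal_values[-config.n_threshold_reversals:]
        if not tail:
            tail = tuple(t[0] for t in state.trial_log[-config.n_threshold_reversals:])
        est = ThresholdEstimate(
            threshold=float(np.mean(tail)), rate_hz=rate_hz,
            n_trials=len(state.trial_log), reversal_values=tuple(tail),
            complete=False,
        )

    log = pd.DataFrame(
        [(i + 1, d, c, dr) for i, (d, c, dr) in enumerate(state.trial_log)],
        columns=["trial", "d", "response_correct", "direction"],
    )
    # mark trials on which a reversal was recorded
    rev_flags = np.zeros(len(log), dtype=bool)
    prev_dir = None
    for i, dr in enumerate(log["direction"]):
        if prev_dir is not None and dr != prev_dir:
            rev_flags[i] = True
        prev_dir = dr
    log["reversal_flag"] = rev_flags
    return est, log
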