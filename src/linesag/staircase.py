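"""Adaptive staircase for the Line Sag Test.

A single-interval forced-choice staircase adjusts the sag of the presented
line to *neutralise* the observer's perceived distortion: an "inwards"
response moves the sag outwards (more positive) by the current step, an
"outwards" response moves it inwards, so the sag converges on the point
where the observer perceives a straight line.  If the observer's internal
distortion at the location is ``d`` arc minutes, that point is ``-d``.

Under the default schedule the step starts at 30 arcmin and halves at each
reversal (a change in adjustment direction) down to a floor of 3.75 arcmin.
A run terminates after six reversals; the threshold is the mean of the sag
values at the final four reversals.

Conventions (the narrative description of the procedure leaves these open;
they are fixed here and documented):

* A reversal is a change in adjustment direction between consecutive
  updates, equivalently a response that differs from the previous response.
* The sag recorded at a reversal is the sag presented on the trial that
  elicited the direction change.
* The step halves immediately upon each reversal, before the next
  adjustment, and stays at the floor once reached.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import TestLocation

__all__ = [
    "Response",
    "StaircaseConfig",
    "Trial",
    "StaircaseState",
    "ThresholdEstimate",
    "StaircaseError",
    "init_staircase",
    "next_sag",
    "threshold",
    "run_staircase",
]

logger = logging.getLogger(__name__)


class StaircaseError(RuntimeError):
    """Raised when the staircase is driven outside its contract."""


class Response(enum.Enum):
    """Forced-choice response: the line appeared to bulge inwards (towards
    fixation) or outwards (away from fixation).  There is no abstain
    option."""

    INWARD = "inward"
    OUTWARD = "outward"


@dataclass(frozen=True)
class StaircaseConfig:
    """Staircase schedule parameters (arc minutes).

    Defaults implement the standard schedule: start step 30 arcmin (0.5 deg),
    halving per reversal to a 3.75 arcmin (0.0625 deg) floor, six reversals
    total with the final four averaged.  The starting sag is drawn uniformly
    from ``[-start_sag_range_arcmin, +start_sag_range_arcmin]``.
    """

    start_step_arcmin: float = 30.0
    min_step_arcmin: float = 3.75
    n_reversals_total: int = 6
    n_reversals_averaged: int = 4
    start_sag_range_arcmin: float = 60.0
    max_trials: int = 200

    def __post_init__(self) -> None:
        if not (self.start_step_arcmin >= self.min_step_arcmin > 0):
            raise ValueError("require start_step >= min_step > 0")
        if not (1 <= self.n_reversals_averaged <= self.n_reversals_total):
            raise ValueError("require 1 <= n_reversals_averaged <= n_reversals_total")
        ratio = self.start_step_arcmin / self.min_step_arcmin
        if abs(math.log2(ratio) - round(math.log2(ratio))) > 1e-9:
            raise ValueError(
                "start_step / min_step must be a power of 2 so halving lands "
                f"exactly on the floor (got ratio {ratio})"
            )
        if self.start_sag_range_arcmin < 0:
            raise ValueError("start_sag_range_arcmin must be >= 0")
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")


@dataclass(frozen=True)
class Trial:
    """One presentation: the sag shown, the step in force, and the response."""

    index: int
    sag_arcmin: float
    step_arcmin: float
    response: Response
    is_reversal: bool


@dataclass
class StaircaseState:
    """Evolving state of one staircase run."""

    config: StaircaseConfig
    current_sag_arcmin: float
    current_step_arcmin: float
    trials: list[Trial] = field(default_factory=list)
    reversal_sags: list[float] = field(default_factory=list)
    reversal_steps: list[float] = field(default_factory=list)
    complete: bool = False
    _last_direction: int | None = None  # +1 outward adjustment, -1 inward


@dataclass(frozen=True)
class ThresholdEstimate:
    """Sag threshold for one run: mean of the final averaged reversal sags."""

    threshold_arcmin: float
    n_trials: int
    n_reversals: int
    converged: bool


def init_staircase(
    config: StaircaseConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> StaircaseState:
    """Start a run with a randomised initial sag.

    ``rng`` may be a seed or a Generator; given the same seed the initial
    sag is identical on repeat.
    """
    config = config or StaircaseConfig()
    gen = np.random.default_rng(rng)
    r = config.start_sag_range_arcmin
    if r == 0:
        logger.warning("degenerate start_sag_range (0): starting every run at 0 sag")
    start = float(gen.uniform(-r, r)) if r > 0 else 0.0
    return StaircaseState(
        config=config,
        current_sag_arcmin=start,
        current_step_arcmin=config.start_step_arcmin,
    )


def next_sag(state: StaircaseState, response: Response) -> StaircaseState:
    """Record a response to the current sag and adjust the staircase.

    Mutates and returns ``state``.  An INWARD response moves the sag
    outwards (+step), an OUTWARD response moves it inwards (-step).  On a
    reversal the presented sag is recorded, the step halves (floored at
    ``min_step_arcmin``) and the run completes once
    ``n_reversals_total`` reversals have accumulated.
    """
    if state.complete:
        raise StaircaseError("cannot update a completed staircase")
    cfg = state.config
    direction = +1 if response is Response.INWARD else -1
    is_reversal = state._last_direction is not None and direction != state._last_direction

    state.trials.append(
        Trial(
            index=len(state.trials),
            sag_arcmin=state.current_sag_arcmin,
            step_arcmin=state.current_step_arcmin,
            response=response,
            is_reversal=is_reversal,
        )
    )
    if is_reversal:
        state.reversal_sags.append(state.current_sag_arcmin)
        state.reversal_steps.append(state.current_step_arcmin)
        state.current_step_arcmin = max(
            state.current_step_arcmin / 2.0, cfg.min_step_arcmin
        )
    state._last_direction = direction

    if len(state.reversal_sags) >= cfg.n_reversals_total:
        state.complete = True
    elif len(state.trials) >= cfg.max_trials:
        logger.warning(
            "staircase hit max_trials=%d with only %d reversals",
            cfg.max_trials,
            len(state.reversal_sags),
        )
        state.complete = True
    else:
        state.current_sag_arcmin += direction * state.current_step_arcmin
    return state


def threshold(state: StaircaseState) -> ThresholdEstimate:
    """Threshold of a completed run: mean of the last averaged reversal sags.

    ``converged`` is true iff the full reversal count was reached before the
    trial cap.  A run that stopped with fewer reversals than the averaging
    window yields a NaN threshold.
    """
    if not state.complete:
        raise StaircaseError("threshold requested on an incomplete staircase")
    cfg = state.config
    n_rev = len(state.reversal_sags)
    converged = n_rev >= cfg.n_reversals_total
    if n_rev >= cfg.n_reversals_averaged:
        value = float(np.mean(state.reversal_sags[-cfg.n_reversals_averaged :]))
    else:
        value = float("nan")
    return ThresholdEstimate(
        threshold_arcmin=value,
        n_trials=len(state.trials),
        n_reversals=n_rev,
        converged=converged,
    )


def run_staircase(
    observer,
    location: TestLocation,
    config: StaircaseConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[ThresholdEstimate, StaircaseState]:
    """Drive one staircase against an observer at one location.

    Loops present -> respond -> update until the run completes, then
    extracts the threshold.  Deterministic given the seed (the same
    Generator stream feeds the initial-sag draw and every response).

    Parameters
    ----------
    observer
        Anything with ``respond_to(location, sag_arcmin, rng) -> Response``
        (see :class:`linesag.observer.ObserverModel`).
    """
    gen = np.random.default_rng(rng)
    state = init_staircase(config, gen)
    while not state.complete:
        response = observer.respond_to(location, state.current_sag_arcmin, gen)
        next_sag(state, response)
    return threshold(state), state
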