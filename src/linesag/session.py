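"""Session orchestration: a full Line Sag Test over the 24-location grid.

A session runs ``runs_per_location`` independent staircases at every grid
location, with randomised starting sags and a shuffled presentation order,
and reduces the per-run thresholds to a per-location *metamorphopsia score*
(their arithmetic mean, in arc minutes).

Seeding is hierarchical: the protocol's ``master_seed`` spawns one seed
stream per grid location (keyed by the location's position in the grid, not
by presentation order), which in turn yields one seed per run plus retry
seeds.  Any single staircase is therefore reproducible in isolation, and
shuffling the presentation order does not change the scores.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import TestLocation, full_grid
from .observer import ObserverModel
from .staircase import StaircaseConfig, StaircaseState, ThresholdEstimate, run_staircase

__all__ = ["ProtocolConfig", "RunResult", "ScoreMap", "run_session", "run_pair_for_repeatability"]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


def _child_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0]) % _SEED_MOD


@dataclass(frozen=True)
class ProtocolConfig:
    """Full-session protocol: grid, repeats, staircase schedule and seeding."""

    grid: tuple[TestLocation, ...] = field(default_factory=full_grid)
    runs_per_location: int = 2
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    interleave_meridians: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ValueError("grid must be non-empty")
        if len(set(self.grid)) != len(self.grid):
            raise ValueError("grid contains duplicate locations")
        if self.runs_per_location < 1:
            raise ValueError("runs_per_location must be >= 1")


@dataclass(frozen=True)
class RunResult:
    """Outcome of one staircase run at one location."""

    location: TestLocation
    run_index: int
    seed: int
    threshold_arcmin: float
    converged: bool
    n_trials: int
    state: StaircaseState | None = None


@dataclass
class ScoreMap:
    """Per-subject metamorphopsia scores over the test grid.

    The score at a location is the mean of that location's converged run
    thresholds (arc minutes); locations where every run failed are recorded
    as missing (NaN score).
    """

    subject_id: str
    runs: list[RunResult]
    protocol: ProtocolConfig | None = None
    provenance: dict = field(default_factory=dict)

    def locations(self) -> tuple[TestLocation, ...]:
        if self.protocol is not None:
            return tuple(self.protocol.grid)
        seen: dict[TestLocation, None] = {}
        for r in self.runs:
            seen.setdefault(r.location, None)
        return tuple(seen)

    def thresholds(self, location: TestLocation) -> list[float]:
        return [
            r.threshold_arcmin
            for r in self.runs
            if r.location == location and r.converged
        ]

    def score(self, location: TestLocation) -> float:
        vals = self.thresholds(location)
        return float(np.mean(vals)) if vals else float("nan")

    def scores(self) -> dict[TestLocation, float]:
        return {loc: self.score(loc) for loc in self.locations()}

    def missing_locations(self) -> tuple[TestLocation, ...]:
        return tuple(loc for loc in self.locations() if not self.thresholds(loc))

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-run table (one row per staircase run)."""
        rows = []
        for r in self.runs:
            rows.append(
                {
                    "subject_id": self.subject_id,
                    "meridian_deg": r.location.meridian_deg,
                    "eccentricity_deg": r.location.eccentricity_deg,
                    "run_index": r.run_index,
                    "threshold_arcmin": r.threshold_arcmin,
                    "score_arcmin": self.score(r.location),
                }
            )
        return pd.DataFrame(rows)


def _run_location(
    observer: ObserverModel,
    location: TestLocation,
    config: StaircaseConfig,
    run_index: int,
    run_seq: np.random.SeedSequence,
    keep_traces: bool,
) -> RunResult:
    """One run with a single retry on non-convergence, then marked missing."""
    first_seq, retry_seq = run_seq.spawn(2)
    for attempt, seq in enumerate((first_seq, retry_seq)):
        seed = _child_seed(seq)
        estimate, state = run_staircase(observer, location, config, seed)
        if estimate.converged:
            return RunResult(
                location=location,
                run_index=run_index,
                seed=seed,
                threshold_arcmin=estimate.threshold_arcmin,
                converged=True,
                n_trials=estimate.n_trials,
                state=state if keep_traces else None,
            )
        logger.warning(
            "staircase at %s run %d (attempt %d) did not converge",
            location.key,
            run_index,
            attempt,
        )
    return RunResult(
        location=location,
        run_index=run_index,
        seed=seed,
        threshold_arcmin=float("nan"),
        converged=False,
        n_trials=estimate.n_trials,
        state=state if keep_traces else None,
    )


def run_session(
    observer: ObserverModel,
    protocol: ProtocolConfig | None = None,
    subject_id: str = "sim",
    keep_traces: bool = True,
) -> ScoreMap:
    """Run a complete session and return the subject's score map.

    Presentation order is shuffled (location-by-location, or run-by-run when
    ``interleave_meridians`` is set), but seeds are keyed to grid position,
    so ordering affects bookkeeping only: identical ``master_seed`` gives an
    identical ScoreMap.
    """
    protocol = protocol or ProtocolConfig()
    root = np.random.SeedSequence(protocol.master_seed)
    order_seq, *loc_seqs = root.spawn(1 + len(protocol.grid))
    order_rng = np.random.default_rng(order_seq)

    tasks: list[tuple[TestLocation, int, np.random.SeedSequence]] = []
    for loc, loc_seq in zip(protocol.grid, loc_seqs):
        for run_index, run_seq in enumerate(loc_seq.spawn(protocol.runs_per_location)):
            tasks.append((loc, run_index, run_seq))
    if protocol.interleave_meridians:
        order = order_rng.permutation(len(tasks))
    else:
        # shuffle locations, keep runs of a location consecutive
        loc_order = order_rng.permutation(len(protocol.grid))
        order = np.concatenate(
            [
                np.arange(
                    i * protocol.runs_per_location, (i + 1) * protocol.runs_per_location
                )
                for i in loc_order
            ]
        )

    runs = [None] * len(tasks)
    for presented, task_idx in enumerate(order):
        loc, run_index, run_seq = tasks[task_idx]
        runs[task_idx] = _run_location(
            observer, loc, protocol.staircase, run_index, run_seq, keep_traces
        )
    score_map = ScoreMap(
        subject_id=subject_id,
        runs=list(runs),
        protocol=protocol,
        provenance={"master_seed": protocol.master_seed},
    )
    missing = score_map.missing_locations()
    if missing:
        logger.warning(
            "subject %s: %d location(s) missing after retries: %s",
            subject_id,
            len(missing),
            [m.key for m in missing],
        )
    return score_map


def run_pair_for_repeatability(
    observer: ObserverModel,
    protocol: ProtocolConfig | None = None,
    subject_id: str = "sim",
    seed_pair: tuple[int, int] | None = None,
    keep_traces: bool = False,
) -> tuple[ScoreMap, ScoreMap]:
    """Two complete sessions with disjoint seed streams (test vs retest).

    The pair feeds Bland-Altman repeatability analysis.  By default the two
    session seeds derive from the protocol's ``master_seed``; passing
    ``seed_pair`` explicitly (and swapped) swaps the results exactly.
    """
    protocol = protocol or ProtocolConfig()
    if seed_pair is None:
        s1_seq, s2_seq = np.random.SeedSequence(protocol.master_seed).spawn(2)
        seed_pair = (_child_seed(s1_seq), _child_seed(s2_seq))
    maps = []
    for run_label, seed in zip(("run1", "run2"), seed_pair):
        cfg = dataclasses.replace(protocol, master_seed=seed)
        maps.append(
            run_session(
                observer, cfg, subject_id=f"{subject_id}", keep_traces=keep_traces
            )
        )
    return maps[0], maps[1]
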