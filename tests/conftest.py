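import numpy as np
import pytest
from hypothesis import settings

import linesag as ls

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def noiseless_zero_observer() -> ls.ObserverModel:
    """Perfect observer with no distortion, no noise and no lapses."""
    return ls.ObserverModel.uniform(0.0, noise_sigma_arcmin=0.0, lapse_rate=0.0)


def noiseless_observer(distortion_arcmin: float) -> ls.ObserverModel:
    return ls.ObserverModel.uniform(
        distortion_arcmin, noise_sigma_arcmin=0.0, lapse_rate=0.0
    )


@pytest.fixture
def some_location() -> ls.TestLocation:
    return ls.TestLocation(90.0, 6.0)


def score_map_from_values(subject_id: str, values: dict) -> ls.ScoreMap:
    """Build a ScoreMap directly from per-location score values (one run)."""
    from linesag.session import RunResult

    runs = [
        RunResult(
            location=loc,
            run_index=0,
            seed=0,
            threshold_arcmin=float(v),
            converged=True,
            n_trials=0,
        )
        for loc, v in values.items()
    ]
    return ls.ScoreMap(subject_id=subject_id, runs=runs)
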