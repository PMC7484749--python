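"""Synthetic observer cohorts for end-to-end validation without subjects.

Two cohort kinds are generated:

``normal``
    Per-location internal distortion drawn iid from N(0, distortion_sd^2)
    (default SD 1 arcmin), representing the small idiosyncratic biases of
    healthy observers.

``ierm``
    A normal baseline field plus 1-4 localised "lesions", emulating the
    focal distortion produced by tangential epiretinal-membrane traction.
    Each lesion picks a random grid cell as its centre, draws a peak
    amplitude (log-uniform on 2-40 arcmin by default, so mild sub-threshold
    disease is common, as in clinical cohorts drawn from the milder end of
    the spectrum) with random sign (inward and outward distortions both
    occur clinically), and decays over neighbouring grid cells with a
    Gaussian profile in grid distance (meridian steps wrap around the
    circle).

Generation is a pure function of the spec (including its seed): each
subject's observer derives from a per-subject child seed, and the manifest
records every seed plus a hash of the spec so a cohort can be regenerated
exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .geometry import (
    ECCENTRICITIES_DEG,
    MERIDIANS_DEG,
    TestLocation,
    full_grid,
)
from .observer import ObserverModel

__all__ = [
    "CohortSpec",
    "grid_distance",
    "make_normal_observer",
    "make_ierm_observer",
    "generate_cohort",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults are the study conditions used throughout: observer noise
    sigma = 4 arcmin and lapse rate 0.02; normals carry 1 arcmin of
    between-location distortion SD; disease-like observers add 1-4 lesions
    with peak amplitudes log-uniform on 2-40 arcmin and a spread of one
    grid cell.
    """

    n_subjects: int
    kind: str = "normal"  # "normal" | "ierm"
    distortion_sd_arcmin: float = 1.0
    n_lesions_range: tuple[int, int] = (1, 4)
    lesion_amplitude_range_arcmin: tuple[float, float] = (2.0, 40.0)
    lesion_amplitude_distribution: str = "log_uniform"  # "log_uniform" | "uniform"
    lesion_spread_cells: float = 1.0
    noise_sigma_arcmin: float = 4.0
    lapse_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.kind not in ("normal", "ierm"):
            raise ValueError(f"kind must be 'normal' or 'ierm', got {self.kind!r}")
        lo, hi = self.n_lesions_range
        if not (0 <= lo <= hi):
            raise ValueError("n_lesions_range must satisfy 0 <= lo <= hi")
        alo, ahi = self.lesion_amplitude_range_arcmin
        if not (0 < alo <= ahi):
            raise ValueError("lesion amplitude range must be positive")
        if self.lesion_amplitude_distribution not in ("log_uniform", "uniform"):
            raise ValueError(
                "lesion_amplitude_distribution must be 'log_uniform' or 'uniform', "
                f"got {self.lesion_amplitude_distribution!r}"
            )
        if self.lesion_spread_cells < 0:
            raise ValueError("lesion_spread_cells must be >= 0")
        if self.distortion_sd_arcmin < 0:
            raise ValueError("distortion_sd_arcmin must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def grid_distance(a: TestLocation, b: TestLocation) -> float:
    """Distance between grid cells in cell units.

    One unit per 45-degree meridian step (wrapping around the circle) and
    one unit per eccentricity step; Euclidean combination.
    """
    mi = MERIDIANS_DEG.index(a.meridian_deg)
    mj = MERIDIANS_DEG.index(b.meridian_deg)
    dm = abs(mi - mj)
    dm = min(dm, len(MERIDIANS_DEG) - dm)
    ei = ECCENTRICITIES_DEG.index(a.eccentricity_deg)
    ej = ECCENTRICITIES_DEG.index(b.eccentricity_deg)
    return float(np.hypot(dm, ei - ej))


def _normal_field(spec: CohortSpec, rng: np.random.Generator) -> dict[TestLocation, float]:
    grid = full_grid()
    if spec.distortion_sd_arcmin == 0:
        return {loc: 0.0 for loc in grid}
    draws = rng.normal(0.0, spec.distortion_sd_arcmin, size=len(grid))
    return {loc: float(d) for loc, d in zip(grid, draws)}


def make_normal_observer(spec: CohortSpec, seed: int | None = None) -> ObserverModel:
    """Healthy observer: iid Gaussian distortion field, fixed noise/lapse."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    return ObserverModel(
        distortion_arcmin=_normal_field(spec, rng),
        noise_sigma_arcmin=spec.noise_sigma_arcmin,
        lapse_rate=spec.lapse_rate,
    )


def make_ierm_observer(spec: CohortSpec, seed: int | None = None) -> ObserverModel:
    """Disease-like observer: normal baseline plus clustered lesion bumps."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    field = _normal_field(spec, rng)
    grid = full_grid()
    lo, hi = spec.n_lesions_range
    n_lesions = int(rng.integers(lo, hi + 1))
    alo, ahi = spec.lesion_amplitude_range_arcmin
    for _ in range(n_lesions):
        centre = grid[int(rng.integers(len(grid)))]
        if spec.lesion_amplitude_distribution == "log_uniform":
            amplitude = float(np.exp(rng.uniform(np.log(alo), np.log(ahi))))
        else:
            amplitude = float(rng.uniform(alo, ahi))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for loc in grid:
            dist = grid_distance(centre, loc)
            if spec.lesion_spread_cells == 0:
                decay = 1.0 if dist == 0 else 0.0
            else:
                decay = float(np.exp(-(dist**2) / (2.0 * spec.lesion_spread_cells**2)))
            field[loc] += sign * amplitude * decay
    return ObserverModel(
        distortion_arcmin=field,
        noise_sigma_arcmin=spec.noise_sigma_arcmin,
        lapse_rate=spec.lapse_rate,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[ObserverModel], dict]:
    """Generate ``n_subjects`` observers plus a reproducibility manifest.

    The manifest records the spec, its hash and every per-subject seed;
    regenerating from the same spec yields an identical cohort.
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = [
        int(child.generate_state(1)[0]) % _SEED_MOD
        for child in root.spawn(spec.n_subjects)
    ]
    maker = make_normal_observer if spec.kind == "normal" else make_ierm_observer
    observers = [maker(spec, seed=s) for s in subject_seeds]
    manifest = {
        "schema_version": 1,
        "spec": spec.to_dict(),
        "spec_sha256": spec.sha256(),
        "subject_seeds": subject_seeds,
        "subject_ids": [f"{spec.kind}-{i:03d}" for i in range(spec.n_subjects)],
    }
    return observers, manifest
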