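"""Simulated observers for closed-loop validation of the Line Sag Test.

An observer is modelled by a per-location internal distortion field ``d``
(arc minutes, positive = perceives an extra outward bulge), additive
zero-mean Gaussian perceptual noise on the sag axis, and a lapse rate (the
probability of an attention slip producing a uniformly random response).

The perceived sag of a presented stimulus is ``sag + d + noise``; the
forced-choice response is OUTWARD when the perceived sag is positive,
INWARD when negative, and a fair coin on an exact tie (the observer is
instructed to guess when unsure).  The 50% point of the resulting
psychometric function sits exactly at ``sag = -d`` regardless of noise or
lapses -- this neutralisation point is what the staircase estimates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .geometry import TestLocation, SagStimulus, full_grid
from .staircase import Response

__all__ = ["ObserverModel", "respond", "psychometric_function"]


@dataclass(frozen=True)
class ObserverModel:
    """Generative response model for one simulated subject.

    Parameters
    ----------
    distortion_arcmin
        Mapping of test location to internal distortion ``d`` in arc
        minutes (signed; positive = extra outward bulge perceived).
    noise_sigma_arcmin
        SD of the zero-mean Gaussian perceptual noise, default 4 arcmin.
    lapse_rate
        Probability of a uniformly random response, default 0.02.
    """

    distortion_arcmin: dict[TestLocation, float]
    noise_sigma_arcmin: float = 4.0
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.noise_sigma_arcmin < 0:
            raise ValueError("noise_sigma_arcmin must be >= 0")
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5)")
        for loc, d in self.distortion_arcmin.items():
            if not math.isfinite(d):
                raise ValueError(f"distortion at {loc.key} must be finite, got {d}")

    def distortion_at(self, location: TestLocation) -> float:
        return self.distortion_arcmin[location]

    def respond_to(
        self,
        location: TestLocation,
        sag_arcmin: float,
        rng: np.random.Generator | int | None = None,
    ) -> Response:
        """Forced-choice response to a sag presented at a location.

        Deterministic given the Generator state / seed.  Raises ``KeyError``
        for a location outside the observer's distortion field.
        """
        d = self.distortion_arcmin[location]
        gen = np.random.default_rng(rng)
        if gen.random() < self.lapse_rate:
            return Response.OUTWARD if gen.random() < 0.5 else Response.INWARD
        perceived = sag_arcmin + d
        if self.noise_sigma_arcmin > 0:
            perceived += gen.normal(0.0, self.noise_sigma_arcmin)
        if perceived > 0:
            return Response.OUTWARD
        if perceived < 0:
            return Response.INWARD
        return Response.OUTWARD if gen.random() < 0.5 else Response.INWARD

    def respond(
        self, stimulus: SagStimulus, rng: np.random.Generator | int | None = None
    ) -> Response:
        """Respond to a fully specified stimulus (see :meth:`respond_to`)."""
        return self.respond_to(stimulus.location, stimulus.sag_arcmin, rng)

    def p_outward(self, location: TestLocation, sag_arcmin: float) -> float:
        """Closed-form probability of an OUTWARD response.

        ``p = lapse/2 + (1 - lapse) * Phi((sag + d) / sigma)``; with zero
        noise the Gaussian CDF degenerates to a step with branches
        ``lapse/2``, ``1/2`` and ``1 - lapse/2``.  Monotone non-decreasing
        in sag, with p = 1/2 exactly at the neutralisation point
        ``sag = -d`` for any sigma and lapse.
        """
        d = self.distortion_arcmin[location]
        x = sag_arcmin + d
        if self.noise_sigma_arcmin == 0:
            core = 0.5 if x == 0 else (1.0 if x > 0 else 0.0)
        else:
            core = float(norm.cdf(x / self.noise_sigma_arcmin))
        return self.lapse_rate / 2.0 + (1.0 - self.lapse_rate) * core

    # ------------------------------------------------------------------ IO
    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "distortion_arcmin": {
                loc.key: float(d) for loc, d in sorted(self.distortion_arcmin.items())
            },
            "noise_sigma_arcmin": self.noise_sigma_arcmin,
            "lapse_rate": self.lapse_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverModel":
        return cls(
            distortion_arcmin={
                TestLocation.from_key(k): float(v)
                for k, v in d["distortion_arcmin"].items()
            },
            noise_sigma_arcmin=float(d.get("noise_sigma_arcmin", 4.0)),
            lapse_rate=float(d.get("lapse_rate", 0.02)),
        )

    @classmethod
    def uniform(
        cls,
        distortion_arcmin: float = 0.0,
        noise_sigma_arcmin: float = 4.0,
        lapse_rate: float = 0.02,
    ) -> "ObserverModel":
        """Observer with the same distortion at every grid location."""
        return cls(
            {loc: distortion_arcmin for loc in full_grid()},
            noise_sigma_arcmin=noise_sigma_arcmin,
            lapse_rate=lapse_rate,
        )


def respond(
    observer: ObserverModel,
    stimulus: SagStimulus,
    rng: np.random.Generator | int | None = None,
) -> Response:
    """Functional alias for :meth:`ObserverModel.respond`."""
    return observer.respond(stimulus, rng)


def psychometric_function(
    observer: ObserverModel, location: TestLocation, sag_arcmin: float
) -> float:
    """Functional alias for :meth:`ObserverModel.p_outward`."""
    return observer.p_outward(location, sag_arcmin)
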