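"""Stimulus geometry for the Line Sag Test.

The Line Sag Test (LST) probes metamorphopsia -- the perceived distortion of
straight lines that accompanies macular disease -- by briefly flashing a
parabolic line and asking the observer whether it bulges towards or away from
fixation.  The adaptive variable is the line's *sag*: the maximal
perpendicular deviation of the parabola from a straight chord, expressed in
arc minutes of visual angle.

The test grid covers eight meridians (0 deg to 315 deg in 45-degree steps)
crossed with three eccentricities (3, 6 and 9 deg from fixation), giving 24
locations; fixation itself is never tested.  Each stimulus is a thin bright
bar oriented perpendicular to its meridian, so that the parabola's bulge axis
points along the meridian ray.

Conventions
-----------
* Positive sag bulges *away* from fixation (outwards); negative sag bulges
  towards fixation.
* Meridians are measured counter-clockwise from the positive horizontal
  axis, the standard visual-field convention.
* Visual-field coordinates are eye-referred degrees; conversion to screen
  pixels uses the exact tangent mapping at the configured viewing distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

__all__ = [
    "ARCMIN_PER_DEG",
    "MERIDIANS_DEG",
    "ECCENTRICITIES_DEG",
    "TestLocation",
    "SagStimulus",
    "ScreenGeometry",
    "StimulusPlacement",
    "full_grid",
    "sag_curve",
    "place_stimulus",
    "deg_to_arcmin",
    "arcmin_to_deg",
    "deg_to_pixels",
    "weber_to_luminance",
]

ARCMIN_PER_DEG = 60.0

#: The eight tested meridians, counter-clockwise from the right horizontal.
MERIDIANS_DEG: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)

#: The three tested eccentricities (degrees from fixation).
ECCENTRICITIES_DEG: tuple[float, ...] = (3.0, 6.0, 9.0)


@dataclass(frozen=True, order=True)
class TestLocation:
    """One (meridian, eccentricity) cell of the 24-point test grid."""

    meridian_deg: float
    eccentricity_deg: float

    def __post_init__(self) -> None:
        m = float(self.meridian_deg)
        e = float(self.eccentricity_deg)
        if not (0.0 <= m <= 315.0 and m % 45.0 == 0.0):
            raise ValueError(
                f"meridian_deg must be a multiple of 45 in [0, 315], got {m}"
            )
        if not e > 0.0:
            raise ValueError(
                f"eccentricity_deg must be positive (fixation is not tested), got {e}"
            )
        object.__setattr__(self, "meridian_deg", m)
        object.__setattr__(self, "eccentricity_deg", e)

    @property
    def key(self) -> str:
        """Compact ``"meridian:eccentricity"`` identifier used in JSON files."""
        return f"{self.meridian_deg:g}:{self.eccentricity_deg:g}"

    @classmethod
    def from_key(cls, key: str) -> "TestLocation":
        try:
            m, e = key.split(":")
            return cls(float(m), float(e))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed location key {key!r}") from exc


def full_grid() -> tuple[TestLocation, ...]:
    """The canonical 24-location grid (8 meridians x 3 eccentricities)."""
    return tuple(
        TestLocation(m, e) for e in ECCENTRICITIES_DEG for m in MERIDIANS_DEG
    )


@dataclass(frozen=True)
class SagStimulus:
    """One presented curved-line stimulus.

    ``sag_arcmin`` is signed: positive bulges away from fixation.  The
    remaining fields carry the physical stimulus parameters -- a 2-degree
    white bar, 0.05 degrees thick, at log10 Weber contrast +0.7, flashed for
    200 ms on a 187.5 cd/m^2 background.
    """

    location: TestLocation
    sag_arcmin: float
    width_deg: float = 2.0
    thickness_deg: float = 0.05
    log_weber_contrast: float = 0.7
    duration_ms: float = 200.0
    background_cd_m2: float = 187.5

    def __post_init__(self) -> None:
        if not self.width_deg > 0:
            raise ValueError(f"width_deg must be positive, got {self.width_deg}")
        if not self.thickness_deg > 0:
            raise ValueError(
                f"thickness_deg must be positive, got {self.thickness_deg}"
            )
        if not self.duration_ms > 0:
            raise ValueError(f"duration_ms must be positive, got {self.duration_ms}")
        if not math.isfinite(self.sag_arcmin):
            raise ValueError(f"sag_arcmin must be finite, got {self.sag_arcmin}")

    def to_dict(self) -> dict:
        """JSON-serialisable description for consumption by any renderer."""
        d = asdict(self)
        d["location"] = self.location.key
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SagStimulus":
        d = dict(d)
        d["location"] = TestLocation.from_key(d["location"])
        return cls(**d)


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display description used for degree-to-pixel conversion."""

    viewing_distance_cm: float = 50.0
    pixels_per_cm: float = 40.0
    frame_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        for name in ("viewing_distance_cm", "pixels_per_cm", "frame_rate_hz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class StimulusPlacement:
    """Chord endpoints and orientation of a stimulus in visual-field degrees.

    ``bulge_unit`` points along the meridian ray away from fixation; positive
    sag displaces the curve in this direction.
    """

    location: TestLocation
    centre_deg: tuple[float, float]
    endpoints_deg: tuple[tuple[float, float], tuple[float, float]]
    chord_unit: tuple[float, float]
    bulge_unit: tuple[float, float]


def deg_to_arcmin(x_deg: float) -> float:
    """Degrees of visual angle to arc minutes (exact factor of 60)."""
    return x_deg * ARCMIN_PER_DEG


def arcmin_to_deg(x_arcmin: float) -> float:
    """Arc minutes of visual angle to degrees (exact factor of 60)."""
    return x_arcmin / ARCMIN_PER_DEG


def sag_curve(
    sag_arcmin: float, width_deg: float = 2.0, n_points: int = 101
) -> np.ndarray:
    """Sample the parabolic stimulus profile y = s * x^2 / (w/2)^2.

    Parameters
    ----------
    sag_arcmin
        Sag ``s`` in arc minutes; the maximal deviation from straightness,
        attained at the chord endpoints x = +-w/2.
    width_deg
        Chord width ``w`` in degrees; x spans [-w/2, +w/2].
    n_points
        Number of evenly spaced samples (odd values sample the vertex x=0).

    Returns
    -------
    ndarray of shape (n_points, 2)
        (x, y) samples in degrees.
    """
    if not width_deg > 0:
        raise ValueError(f"width_deg must be positive, got {width_deg}")
    if n_points < 3:
        raise ValueError(f"n_points must be >= 3, got {n_points}")
    half = width_deg / 2.0
    x = np.linspace(-half, half, n_points)
    s_deg = arcmin_to_deg(sag_arcmin)
    y = s_deg * x**2 / half**2
    return np.column_stack([x, y])


def place_stimulus(location: TestLocation, width_deg: float = 2.0) -> StimulusPlacement:
    """Place a stimulus chord at a grid location.

    The chord of length ``width_deg`` is centred at polar position
    (eccentricity, meridian) and oriented perpendicular to the meridian ray;
    the parabola's bulge axis lies along the ray, so positive sag displaces
    the curve away from fixation.
    """
    if not width_deg > 0:
        raise ValueError(f"width_deg must be positive, got {width_deg}")
    theta = math.radians(location.meridian_deg)
    radial = (math.cos(theta), math.sin(theta))
    tangential = (-math.sin(theta), math.cos(theta))
    e = location.eccentricity_deg
    centre = (e * radial[0], e * radial[1])
    half = width_deg / 2.0
    p0 = (centre[0] - half * tangential[0], centre[1] - half * tangential[1])
    p1 = (centre[0] + half * tangential[0], centre[1] + half * tangential[1])
    return StimulusPlacement(
        location=location,
        centre_deg=centre,
        endpoints_deg=(p0, p1),
        chord_unit=tangential,
        bulge_unit=radial,
    )


def deg_to_pixels(x_deg: float, screen: ScreenGeometry) -> float:
    """Visual angle to on-screen extent in pixels via the tangent mapping.

    Exact (not small-angle) form: ``tan(x) * distance * density``.  Only
    angles strictly inside (-90, 90) degrees map onto a flat screen.
    """
    if abs(x_deg) >= 90.0:
        raise ValueError(f"|x_deg| must be < 90 for a flat display, got {x_deg}")
    return math.tan(math.radians(x_deg)) * screen.viewing_distance_cm * screen.pixels_per_cm


def weber_to_luminance(log_weber_contrast: float, background_cd_m2: float) -> float:
    """Stimulus luminance from log10 Weber contrast on a given background.

    Weber contrast is defined as C = (L - L_bg) / L_bg, so
    L = L_bg * (1 + 10**logC).
    """
    if not background_cd_m2 > 0:
        raise ValueError(
            f"background_cd_m2 must be positive, got {background_cd_m2}"
        )
    return background_cd_m2 * (1.0 + 10.0**log_weber_contrast)
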