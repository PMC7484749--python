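"""Normative modelling, abnormality flagging and agreement statistics.

Detection criterion
-------------------
Metamorphopsia scores from a normal cohort define a per-location normative
distribution (sample mean and SD).  A subject tests positive when any
location's score deviates from the normative mean by more than
``z_detect = 3.08`` SD -- i.e. falls outside the two-sided 99.79% limits of
a normal distribution.  The inflated z cut-off (rather than the usual 1.96)
compensates for sampling 24 locations per subject; a looser 2-SD band is
kept alongside for display purposes.

Agreement and repeatability
---------------------------
Paired binary outcomes of two tests on the same subjects are summarised in
a 2x2 table and compared with McNemar's test (continuity-corrected
chi-squared by default; an exact binomial variant is also provided).
Independent hit rates are compared with Fisher's exact test.  Test-retest
agreement uses the Bland-Altman repeatability coefficient
``RC = 2.77 * S_w``, where ``S_w`` is the SD of the paired run differences;
RC is conventionally reported in degrees while scores are measured in arc
minutes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .geometry import ARCMIN_PER_DEG, TestLocation
from .session import ScoreMap

__all__ = [
    "NormativeModel",
    "DetectionResult",
    "Agreement2x2",
    "RepeatabilityResult",
    "HitRate",
    "fit_normative",
    "coverage_of_z",
    "flag_subject",
    "hit_rate",
    "mcnemar_test",
    "fisher_exact_test",
    "bland_altman_repeatability",
    "paired_score_differences",
    "hedges_g",
    "compare_cohort_scores",
]

#: Bland-Altman repeatability multiplier (1.96 * sqrt(2), rounded as 2.77).
RC_FACTOR = 2.77


# --------------------------------------------------------------- normative
@dataclass(frozen=True)
class NormativeModel:
    """Per-location normative mean and SD of metamorphopsia scores."""

    mean_arcmin: dict[TestLocation, float]
    sd_arcmin: dict[TestLocation, float]
    n_subjects: int
    z_detect: float = 3.08
    z_display: float = 2.0

    def locations(self) -> tuple[TestLocation, ...]:
        return tuple(self.mean_arcmin)

    def z_score(self, location: TestLocation, score_arcmin):
        """Standardised deviation of a score from the normative band.

        Accepts scalars or numpy arrays of scores.
        """
        return (score_arcmin - self.mean_arcmin[location]) / self.sd_arcmin[location]

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "n_subjects": self.n_subjects,
            "z_detect": self.z_detect,
            "z_display": self.z_display,
            "mean_arcmin": {l.key: float(v) for l, v in sorted(self.mean_arcmin.items())},
            "sd_arcmin": {l.key: float(v) for l, v in sorted(self.sd_arcmin.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModel":
        return cls(
            mean_arcmin={TestLocation.from_key(k): float(v) for k, v in d["mean_arcmin"].items()},
            sd_arcmin={TestLocation.from_key(k): float(v) for k, v in d["sd_arcmin"].items()},
            n_subjects=int(d["n_subjects"]),
            z_detect=float(d.get("z_detect", 3.08)),
            z_display=float(d.get("z_display", 2.0)),
        )


def fit_normative(
    normal_scoremaps: Sequence[ScoreMap],
    z_detect: float = 3.08,
    z_display: float = 2.0,
) -> NormativeModel:
    """Fit per-location sample mean and SD (ddof=1) from a normal cohort.

    Requires at least two subjects with complete grids; a location with zero
    variance would yield a degenerate normative band and raises.
    """
    if len(normal_scoremaps) < 2:
        raise ValueError("normative model requires >= 2 subjects")
    grid = normal_scoremaps[0].locations()
    means: dict[TestLocation, float] = {}
    sds: dict[TestLocation, float] = {}
    for loc in grid:
        vals = np.array([sm.score(loc) for sm in normal_scoremaps], dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"missing normative score at location {loc.key}")
        sd = float(np.std(vals, ddof=1))
        if sd <= 0:
            raise ValueError(f"zero variance at location {loc.key}: degenerate band")
        means[loc] = float(np.mean(vals))
        sds[loc] = sd
    return NormativeModel(
        mean_arcmin=means,
        sd_arcmin=sds,
        n_subjects=len(normal_scoremaps),
        z_detect=z_detect,
        z_display=z_display,
    )


def coverage_of_z(z: float) -> float:
    """Two-sided standard-normal coverage of the band +-z: 2*Phi(z) - 1."""
    if z < 0:
        raise ValueError("z must be >= 0")
    return float(2.0 * stats.norm.cdf(z) - 1.0)


# --------------------------------------------------------------- detection
@dataclass(frozen=True)
class DetectionResult:
    """Abnormality flags for one subject against a normative model."""

    subject_id: str
    z_scores: dict[TestLocation, float]
    flagged_locations: tuple[TestLocation, ...]
    display_flagged_locations: tuple[TestLocation, ...]
    positive: bool
    missing_locations: tuple[TestLocation, ...] = ()


def flag_subject(scoremap: ScoreMap, normative: NormativeModel) -> DetectionResult:
    """Flag locations outside the normative band; positive if any flagged.

    ``flagged_locations`` uses the detection cut-off (|z| > z_detect, default
    3.08 SD); ``display_flagged_locations`` uses the looser display band
    (|z| > z_display, default 2 SD) used for radial plots.  Locations with a
    missing score are excluded with a warning.
    """
    z_scores: dict[TestLocation, float] = {}
    missing: list[TestLocation] = []
    for loc in scoremap.locations():
        if loc not in normative.mean_arcmin:
            raise KeyError(f"location {loc.key} absent from normative model")
        s = scoremap.score(loc)
        if math.isnan(s):
            missing.append(loc)
            continue
        z_scores[loc] = float(normative.z_score(loc, s))
    if missing:
        warnings.warn(
            f"subject {scoremap.subject_id}: {len(missing)} location(s) with "
            "missing scores excluded from detection",
            stacklevel=2,
        )
    flagged = tuple(l for l, z in z_scores.items() if abs(z) > normative.z_detect)
    display = tuple(l for l, z in z_scores.items() if abs(z) > normative.z_display)
    return DetectionResult(
        subject_id=scoremap.subject_id,
        z_scores=z_scores,
        flagged_locations=flagged,
        display_flagged_locations=display,
        positive=bool(flagged),
        missing_locations=tuple(missing),
    )


# --------------------------------------------------------------- agreement
@dataclass(frozen=True)
class HitRate:
    """Fraction of subjects a test flags positive."""

    n_positive: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_positive / self.n_total

    @property
    def percent(self) -> int:
        """Whole-number percentage, the conventional reporting form."""
        return round(100.0 * self.fraction)


def hit_rate(detection_results: Iterable) -> HitRate:
    """Hit rate from DetectionResults or raw booleans."""
    flags = [
        r.positive if isinstance(r, DetectionResult) else bool(r)
        for r in detection_results
    ]
    if not flags:
        raise ValueError("hit_rate requires a non-empty cohort")
    return HitRate(n_positive=sum(flags), n_total=len(flags))


@dataclass(frozen=True)
class Agreement2x2:
    """Paired-positivity table for two tests on the same subjects.

    ``a``: both positive; ``b``: index positive / reference negative;
    ``c``: index negative / reference positive; ``d``: both negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"count {name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_labels(
        cls, index_positive: Sequence[bool], reference_positive: Sequence[bool]
    ) -> "Agreement2x2":
        if len(index_positive) != len(reference_positive):
            raise ValueError("paired label vectors must have equal length")
        i = np.asarray(index_positive, dtype=bool)
        r = np.asarray(reference_positive, dtype=bool)
        return cls(
            a=int(np.sum(i & r)),
            b=int(np.sum(i & ~r)),
            c=int(np.sum(~i & r)),
            d=int(np.sum(~i & ~r)),
        )

    def index_hit_rate(self) -> HitRate:
        return HitRate(self.a + self.b, self.n)

    def reference_hit_rate(self) -> HitRate:
        return HitRate(self.a + self.c, self.n)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def mcnemar_test(
    table: Agreement2x2, method: str = "continuity_corrected"
) -> tuple[float, float]:
    """McNemar's test for paired binary outcomes.

    ``continuity_corrected`` (default): chi-squared statistic
    ``(|b - c| - 1)^2 / (b + c)`` on 1 df.  ``exact``: two-sided binomial
    test of the discordant count ``b`` given ``b + c`` trials at p = 1/2.
    With no discordant pairs the statistic is degenerate; (0.0, 1.0) is
    returned.
    """
    if method not in ("continuity_corrected", "exact"):
        raise ValueError(f"unknown method {method!r}")
    b, c = table.b, table.c
    if b + c == 0:
        warnings.warn("no discordant pairs: McNemar statistic undefined, p = 1")
        return 0.0, 1.0
    res = _sm_mcnemar(table.as_array(), exact=(method == "exact"), correction=True)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_test(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Accepts an :class:`Agreement2x2` or any 2x2 array of counts.  The
    two-sided p sums the hypergeometric probabilities of all tables with
    the observed margins that are no more probable than the observed one.
    """
    arr = table.as_array() if isinstance(table, Agreement2x2) else np.asarray(table)
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


# ----------------------------------------------------------- repeatability
@dataclass(frozen=True)
class RepeatabilityResult:
    """Bland-Altman test-retest summary.

    Differences are measured in arc minutes; the repeatability coefficient
    is reported in degrees (``rc_deg = 2.77 * s_w_arcmin / 60``).
    """

    n_pairs: int
    mean_diff_arcmin: float
    s_w_arcmin: float

    @property
    def s_w_deg(self) -> float:
        return self.s_w_arcmin / ARCMIN_PER_DEG

    @property
    def rc_deg(self) -> float:
        return RC_FACTOR * self.s_w_deg

    @property
    def rc_arcmin(self) -> float:
        return RC_FACTOR * self.s_w_arcmin


def bland_altman_repeatability(
    run1_scores_arcmin: Sequence[float], run2_scores_arcmin: Sequence[float]
) -> RepeatabilityResult:
    """Repeatability coefficient from paired run-1/run-2 scores.

    The inputs are paired per-location scores (pooled over subjects and
    locations within a cohort), in arc minutes.
    """
    r1 = np.asarray(run1_scores_arcmin, dtype=float)
    r2 = np.asarray(run2_scores_arcmin, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("run1 and run2 scores must be paired (equal length)")
    if r1.size < 2:
        raise ValueError("repeatability requires >= 2 pairs")
    diffs = r1 - r2
    return RepeatabilityResult(
        n_pairs=int(diffs.size),
        mean_diff_arcmin=float(np.mean(diffs)),
        s_w_arcmin=float(np.std(diffs, ddof=1)),
    )


def paired_score_differences(
    pairs: Sequence[tuple[ScoreMap, ScoreMap]],
) -> tuple[np.ndarray, np.ndarray]:
    """Pool per-location (run1, run2) scores over a cohort of session pairs."""
    r1: list[float] = []
    r2: list[float] = []
    for m1, m2 in pairs:
        for loc in m1.locations():
            s1, s2 = m1.score(loc), m2.score(loc)
            if math.isnan(s1) or math.isnan(s2):
                continue
            r1.append(s1)
            r2.append(s2)
    return np.array(r1), np.array(r2)


# ------------------------------------------------------------ cohort tests
def hedges_g(group1, group2) -> float:
    """Hedges' g: bias-corrected standardised mean difference.

    ``g = J * (m1 - m2) / s_pooled`` with the small-sample correction
    ``J = 1 - 3 / (4 * (n1 + n2 - 2) - 1)``; the pooled SD uses ddof=1
    group variances.
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    s_pooled_sq = (
        (n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1)
    ) / (n1 + n2 - 2)
    if s_pooled_sq <= 0:
        raise ValueError("zero pooled variance: effect size undefined")
    d = (np.mean(x1) - np.mean(x2)) / np.sqrt(s_pooled_sq)
    j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    return float(j * d)


def compare_cohort_scores(scores_a, scores_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise.  Two groups of identical constant values carry no
    ordering information and return p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(np.concatenate([a, b]) == a.flat[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)
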