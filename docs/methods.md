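# Methods

## The measurement model

The Line Sag Test treats metamorphopsia as a signed, location-specific
quantity: at each of 24 visual-field locations (meridians 0°–315° in 45°
steps × eccentricities 3°, 6°, 9°; fixation untested, since epiretinal
traction displaces photoreceptors tangentially around the fovea) the test
estimates the parabolic sag *s* (arc minutes) at which a briefly flashed
curved bar is perceived as straight. The stimulus profile is
`y = s·x²/(w/2)²` over `x ∈ [−w/2, +w/2]` with chord width `w = 2°`; the
bar is 0.05° thick at log₁₀ Weber contrast +0.7 on a 187.5 cd/m²
background, flashed for 200 ms, oriented perpendicular to its meridian so
the bulge axis is radial. Positive sag bulges away from fixation. The brief
presentation is a design feature, not an implementation detail: it limits
perceptual filling-in and the opportunity to saccade toward the stimulus,
the two confounders that degrade prolonged-view tests.

The observer model assumes perception is *additive and stationary*:
perceived sag = physical sag + internal distortion *d* + zero-mean Gaussian
noise (SD σ), with a lapse probability of a random response. Under this
model the psychometric function for "outwards" is
`p(sag) = λ/2 + (1 − λ)·Φ((sag + d)/σ)`, whose 50% point is exactly `−d`
for every σ and λ. The staircase therefore estimates `−d`: the sag that
*neutralises* the distortion. Whether real observers' distortion is
additive and stationary across trials is a psychophysical assumption that
per-trial human data would be needed to test; it is the natural first-order
model and the one the neutralisation logic of the test presupposes.

## Staircase conventions

The schedule is fixed by the procedure: start step 30 arcmin, halving at
each reversal to a 3.75 arcmin floor; six reversals end a run; the
threshold is the mean of the final four reversal sags. Three details are
not pinned down by the narrative description and are fixed here:

- a **reversal** is a change of adjustment direction between consecutive
  updates (equivalently, a response differing from the previous response);
- the sag **recorded** at a reversal is the sag presented on the trial that
  elicited the direction change;
- the step **halves immediately** on the reversal, so the adjustment that
  follows a reversal already uses the halved step, and the step stays at
  the floor once reached.

With these conventions a noiseless observer's threshold is provably within
one floor step of `−d` (the final reversals bracket `−d` within ±3.75
arcmin and alternate in sign, so their mean deviates by at most ≈2.8
arcmin); the test suite verifies `|threshold + d| ≤ 3.75` exhaustively over
`d ∈ {−45, …, +45}` arcmin × 100 seeds.

The starting sag is uniform on ±60 arcmin (twice the start step; the value
is configurable and the procedure only requires "randomised"). Sag is never
clamped at zero — thresholds are signed. A `max_trials` cap (default 200)
guards against non-terminating response streams; a capped run is flagged
non-converged, retried once with a fresh sub-seed at session level, then
recorded as missing. None of the simulated conditions in the test suite
ever triggers the cap; it exists because a forced-choice loop driven by an
arbitrary (e.g. human or buggy) responder has no other exit.

## Session protocol and seeding

A session runs `runs_per_location` (default 2) staircases per location and
averages their thresholds into the location's metamorphopsia score.
Presentation order is shuffled; because each staircase's seed derives from
the location's position in the grid (master seed → per-location stream →
per-run stream, all sub-seeds < 2³¹), ordering — including trial-by-trial
interleaving of meridians, which the protocol permits — is pure
bookkeeping: thresholds are staircase-local and identical either way. This
also makes any single run reproducible in isolation from the session
bundle, which stores the protocol, observer, seeds and full traces.

## Detection criterion

Per-location normative mean and SD (sample SD, ddof = 1) are fitted from a
normal cohort's score maps. A subject is positive when any location's score
deviates by more than `z_detect = 3.08` SD — the two-sided 99.79% limits of
a normal distribution. The inflated cut-off is the multiplicity correction:
with 24 independent locations the expected subject-level false-positive
rate is `1 − 0.9979²⁴ ≈ 4.9%`, i.e. roughly the conventional 5% test-wise
level; no FDR-style procedure is layered on top. A looser 2-SD band is kept
for display (radial plots mark these locations as filled). The suite checks
the per-location false-flag rate against `2(1 − Φ(3.08)) ≈ 0.21%` over 10⁵
draws and the subject-level rate against the binomial prediction in a
500-subject leave-one-out experiment.

## Agreement and repeatability statistics

- **McNemar** (paired positivity of two tests on one cohort): the default
  is the continuity-corrected `χ² = (|b − c| − 1)²/(b + c)` on 1 df, which
  reproduces the conventionally reported p = 0.003 for b = 11, c = 0; the
  exact two-sided binomial variant (p ≈ 0.00098 for the same counts) is
  also exposed. With no discordant pairs the statistic is degenerate and
  p = 1 is returned with a warning.
- **Fisher's exact test** compares independent hit rates.
- **Repeatability**: differences between run-1 and run-2 scores are pooled
  over subjects × locations within a cohort (the only pooling that yields a
  single SD per cohort); `RC = 2.77 × S_w`. Scores are in arc minutes but
  RC is reported in **degrees** — the convention the published coefficients
  (0.23°, 0.24°) force, since 2.77 × 5.016 arcmin only equals 0.23 when
  S_w is first converted to degrees.
- **Hedges' g** uses the pooled ddof-1 SD and the small-sample factor
  `J = 1 − 3/(4(n₁+n₂−2) − 1)`; **cohort comparisons** use the two-sided
  Wilcoxon rank-sum (exact for small tie-free samples).

## Synthetic cohorts: what they emulate and what they do not

The generator produces observers, not data files, so every downstream stage
is exercised end-to-end. Defaults (units arc minutes):

| parameter | default | rationale |
|---|---|---|
| response noise σ | 4 | puts simulated normal-cohort score SDs (≈2 arcmin after 2-run averaging) on the same order as the ≈3.8 arcmin reported for real normal observers — an order-of-magnitude calibration, not a fit |
| lapse rate | 0.02 | typical forced-choice lapse allowance |
| normal distortion SD | 1 | small idiosyncratic per-location bias of healthy observers |
| lesions per disease observer | 1–4 | focal, spatially clustered abnormality as seen on distortion maps |
| lesion peak amplitude | log-uniform 2–40 | see below |
| lesion spread | 1 grid cell (Gaussian decay, meridian wraps) | traction distorts a neighbourhood, not a single point |

The lesion amplitude distribution is the one genuinely open design choice.
A uniform floor at 8 arcmin makes *every* simulated disease observer exceed
the ≈6.5 arcmin detection band that emerges from the defaults above, which
contradicts the clinical picture this cohort is meant to emulate — a third
of epiretinal-membrane patients from the milder end of the spectrum screen
negative on the test. A log-uniform severity on 2–40 arcmin concentrates
mass at mild, sub-threshold disease: ≈16% of generated observers have all
peak distortions inside the band, mean peak amplitude ≈13 arcmin, and the
resulting cohort score magnitudes sit near the few-arcminute level reported
clinically. Lesion sign is random (inward and outward distortion both
occur).

What the synthetic cohorts do **not** model: fixation instability,
perceptual filling-in (the 200 ms design is argued to mitigate these, and
no generative model of them is attempted), learning/fatigue, reaction
times and test duration, and any structure–function link between lesion
amplitude and retinal thickness. Passing simulated-cohort tests therefore
demonstrates that the *procedure and analysis chain* behave as designed
under the stated observer model — not that the test performs identically
in human cohorts.

The "Amsler-like" reference in the end-to-end comparison is a deliberately
coarse binary: positive only when an observer's peak |d| exceeds 30 arcmin.
It stands in for an insensitive self-report test; only the *ordering* (LST
hit rate above reference hit rate) is asserted, never its numeric value.

## Numerical choices

- Exact ties in the forced choice (perceived sag exactly 0) resolve by a
  seeded fair coin — the instruction to guess when unsure.
- Scores, thresholds and sags are plain float64; the parabola's evenness
  and unit round-trips are exact to 1e−12.
- CSV files fix floats at 6 decimals, and the score column is computed from
  the 6-decimal-rounded thresholds, so write → read → write is
  byte-identical.
- `start_step/min_step` must be a power of two so halving lands exactly on
  the floor (30 → 15 → 7.5 → 3.75).
- Zero normative variance at a location is an error (a degenerate band
  would flag everything or nothing); a zero-width starting-sag range is
  allowed but logged.

## Problem sizes

The validation suite and the acceptance script use: 100 seeds × 19
distortion levels for the noiseless recovery sweep; 12 normal and 21
disease-like simulated subjects (matching the clinical cohort sizes) with
two sessions each for the pipeline statistics; 50 + 50 subjects for the
stochastic-dominance check and 100 disease observers for the hit-rate
ordering; 10⁵ draws for psychometric and false-flag calibration checks.
These sizes give stable seeded results while keeping a full run in the
tens of seconds.

## Known limitations

- The additive-stationary observer model is an assumption; criterion
  effects beyond lapses (e.g. response bias between "inwards" and
  "outwards") are not modelled.
- The normative band treats locations as independent; spatially correlated
  normal variation would lower the effective subject-level false-positive
  rate below the binomial prediction.
- Whether the 2° stimulus length refers to the chord or the arc is
  unspecified in the procedure's description; the chord is assumed (the
  difference is second-order at these sags).
- No Bayesian/QUEST-style acceleration is provided; the staircase is the
  specified fixed-step transformed procedure.
- Rendering to a physical display (gamma, pixel pitch, timing) is out of
  scope; geometry is emitted in eye-referred degrees with a configurable
  tangent screen mapping.
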