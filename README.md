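# linesag

Adaptive forced-choice psychophysics for quantifying **metamorphopsia** —
the perceived distortion of straight lines that accompanies macular disease
(epiretinal membranes, macular holes, neovascular AMD). Classic clinical
tools such as the Amsler grid only ask *whether* distortion is seen, and
their prolonged, repetitive displays are vulnerable to perceptual filling-in
and fixation drift. `linesag` implements the **Line Sag Test (LST)**: a
briefly flashed (200 ms) thin bright bar, bowed into a parabola

```
y = s · x² / (w/2)²,   x ∈ [−w/2, +w/2]
```

with chord width *w* = 2° and signed sag *s* (arc minutes; positive =
bulging away from fixation), presented at 24 visual-field locations (8
meridians × eccentricities 3°, 6°, 9°). On each trial the observer is
forced to answer "bulging inwards" or "bulging outwards"; a transformed
staircase (step 30 arcmin, halving at each direction reversal to a
3.75 arcmin floor, six reversals, last four averaged) drives the sag to the
point where the line *looks straight*. If the observer's internal
distortion at a location is *d*, the staircase converges on −*d*: the test
neutralises the distortion and thereby measures it.

The package provides, for test developers and visual-psychophysics
researchers:

- **stimulus geometry** (`linesag.geometry`) — the parabola, grid placement,
  degree/arcmin/pixel and Weber-contrast conversions;
- **the staircase engine** (`linesag.staircase`) and **session protocol**
  (`linesag.session`) — seeded, fully reproducible runs and per-location
  metamorphopsia score maps;
- **simulated observers and cohorts** (`linesag.observer`,
  `linesag.cohorts`) — distortion fields plus Gaussian response noise and
  lapses, for closed-loop validation without human subjects;
- **analysis** (`linesag.analysis`) — per-location normative bands with a
  ±3.08 SD detection criterion (99.79% two-sided coverage, compensating for
  24 tested locations), hit rates, McNemar and Fisher exact tests,
  Bland–Altman repeatability (RC = 2.77·S_w), Hedges' g and rank-sum
  comparisons;
- **file formats and a CLI** (`linesag.io`, `linesag.cli`) — tidy score
  CSVs, self-reproducing session bundles, observer/normative JSON, and the
  `linesag` command with `simulate-cohort`, `run-session`,
  `build-normative`, `detect`, `repeatability`, `compare` and `report`
  subcommands.

## Worked example

Simulate a patient with a single focal lesion (+18 arcmin of perceived
outward bulge at meridian 90°, eccentricity 3°), build a normative model
from a simulated 12-subject normal cohort, and screen the patient:

```python
import linesag as ls

field = {loc: 0.0 for loc in ls.full_grid()}
field[ls.TestLocation(90, 3)] = 18.0
patient = ls.ObserverModel(field, noise_sigma_arcmin=4.0, lapse_rate=0.02)

spec = ls.CohortSpec(n_subjects=12, kind="normal", seed=0)
observers, manifest = ls.generate_cohort(spec)
normal_maps = [
    ls.run_session(o, ls.ProtocolConfig(master_seed=s), subject_id=sid,
                   keep_traces=False)
    for o, s, sid in zip(observers, manifest["subject_seeds"],
                         manifest["subject_ids"])
]
normative = ls.fit_normative(normal_maps)

scores = ls.run_session(patient, ls.ProtocolConfig(master_seed=7),
                        subject_id="patient")
result = ls.flag_subject(scores, normative)
loc = ls.TestLocation(90, 3)
print(f"score at (90, 3): {scores.score(loc):.2f} arcmin "
      f"(z = {result.z_scores[loc]:.1f})")
print(f"flagged locations: {[l.key for l in result.flagged_locations]}")
print(f"verdict: {'POSITIVE' if result.positive else 'negative'}")
```

prints

```
score at (90, 3): -21.00 arcmin (z = -10.2)
flagged locations: ['90:3']
verdict: POSITIVE
```

The score is ≈ −18 arcmin (the staircase's neutralising sag is the
*opposite* of the internal distortion, up to response noise), more than ten
normative SDs from the normal mean at that location, so the lesioned
location — and only it — is flagged and the subject screens positive.

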