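# Methods

## The score model

Four OCT/D-OCT features of a debrided pediatric hand burn are graded
and summed: surface irregularity (0–1), loss of the dark epidermal band
(0–1), dermal pattern (0–2) and the microvascular network on the flow
channel (0–2). The dermal item is site-specific: glabrous skin (palm)
shows skin lines, hair-bearing skin (dorsum) a regular grid of dark
papillary spots; a wound carries exactly one of the two, selected by
`skin_type`, so the input schema has a single `dermal_pattern` column.
Grades are integers only — a fractional value is rejected at
validation rather than rounded, because averaging two observers is an
explicit cohort-level decision (observer mode), not something to hide
in the score. There is no "unassessable" grade level: missing data is
an error at the score layer and a permissive-mode row filter at the I/O
layer, mirroring the exclusion of unusable images rather than their
scoring.

Depth bands are 0–2 / 3–4 / 5–6 and the management rule is *heal if
score ≤ threshold* with threshold 4 inclusive on the healing side
(wounds scoring 4 or less healed under dressing; 5 or more marked
deeper wounds). `classify_depth(s) == deep_graft` iff
`predict_management(s, 4) == graft_candidate` for every s, which the
tests check exhaustively over all 36 grade combinations. Scores 0–1
were never observed in patients but are representable: a debrided
wound could in principle grade fully normal.

## Cohort evaluation

`build_confusion` counts predicted-deep (score > threshold) against a
reference standard chosen by `deep_outcome_rule`. Two rules exist
because clinical reality mixes two standards: `grafted_only` counts
only operated wounds as deep, while the default `grafted_or_refused`
also counts a deep wound whose family declined grafting (deep by
healing course). Which observer feeds the score is selectable:
observer 1 (default) or a consensus mode restricted to records where
both observers agree.

Proportions carry 95% confidence intervals from
`statsmodels.stats.proportion.proportion_confint` — Wilson by default,
Clopper–Pearson (`beta`) as the `exact` option; the test suite checks
the exact endpoints against an independent grid-search tail inversion
and Wilson's empirical coverage by simulation. Metrics with a zero
denominator are reported as absent, never as zero. Percentages are
formatted round-half-up on the percent scale, integer precision by
default with a one-decimal mode, and reports state the rounding used,
so 53% vs 52.9% is always explicit.

Inter-observer agreement reports, per item and for the total score,
the observed percent agreement and Cohen's
κ = (p_o − p_e)/(1 − p_e) with chance agreement p_e from the marginal
frequencies. κ is undefined and reported as absent when p_e = 1 (both
observers constant). The hand implementation exists because of that
degenerate case; it is cross-checked against
`sklearn.metrics.cohen_kappa_score` in the tests. The unit of analysis
is the hand, with `patient_id` for grouping, since bilateral injuries
occur.

## Synthetic cohorts

The generator reproduces the statistical structure of the study
cohort. Per wound it draws: skin type (glabrous probability 0.5), a
total score from `score_weights` (default proportional to the observed
counts 0/0/2/15/29/12/5 for scores 0–6), a grade combination uniformly
among all combinations summing to that score (the exact inverse image
of the additive score, enumerated over the 36 tuples), a latent deep
status from `p_deep_given_score`, a grafting decision for deep wounds
(`p_graft_given_deep` = 0.9), days to graft from a Poisson with median
9, observer-2 grades by symmetric one-step per-item perturbation
(probability 0.1, clipped to the item range), and a bedside judgment
that over-calls depth (judged deep with probability 0.95 if deep, 0.17
if superficial — the study reports only aggregate over/under-calls, so
these are the package's own modelling choices).

The outcome probabilities are conditional on score only at the band
level in the source data, so the per-score defaults
{≤3: 0, 4: 0.03, 5: 0.5, 6: 0.9} are calibration choices exposed as
configuration, chosen so the implied band-level values land near the
reported ones: P(deep | score ≥ 5) = (12·0.5 + 5·0.9)/17 ≈ 0.62,
P(grafted | score ≥ 5) ≈ 0.56, P(heals | score ≤ 4) ≈ 0.98. A
50,000-wound cohort recovers these within one percentage point
(acceptance test); 50,000 keeps the binomial standard error of the
high-score PPV near 0.4 points.

Randomness: one cohort seed, spawned into one child stream per record
in record order, so the first k records are identical for any
n_wounds ≥ k (stable partial regeneration), and disjoint seeds give
independent cohorts.

What the generator does **not** emulate: ages, burn causes, dressing
counts, lengths of stay, within-patient correlation of bilateral
injuries, or observer bias that is asymmetric across items. Passing
tests therefore show the statistical machinery is correct under the
stated generative model, not that the score works on real wounds.

## Phantom volumes

`generate_phantom` renders a two-channel volume over a 6 mm × 6 mm
field, axis order (z, y, x) with z increasing into the skin, values in
[0, 1]:

* **Surface**: base depth 100 µm plus an optional tilt (µm per mm of
  x) plus a Gaussian random field with ~150 µm lateral correlation
  scaled to the requested RMS roughness (healthy default 5 µm).
* **Epidermis**: a dark band (intensity 0.18 vs dermis 0.65) of
  configurable thickness (default 120 µm) below the surface, absent
  when `epidermis_present` is false.
* **Dermis**: brighter, with a mild exponential depth attenuation
  (length constant 2 mm).
* **Dermal pattern**: a multiplicative darkening in a layer
  300 ± 40 µm below the *local* surface. Glabrous: a sinusoidal line
  pattern (period 400 µm, random orientation, gently wandering phase);
  level 1 reduces amplitude and blurs, level 2 removes it.
  Hair-bearing: Gaussian spots (σ 45 µm) on a 300 µm grid jittered by
  30 µm; level 1 keeps a random 45% at reduced amplitude, level 2
  removes all.
* **Vascular channel**: an en-face recursive branching tree (4 trunks,
  2 children per segment over 4 generations, segment length ×0.72 and
  width ×0.68 per generation from 55 µm trunks), rasterised as stamped
  disks and extruded over the 150–450 µm depth band below the surface.
  Level 1 removes the thinnest width quantile (q = 0.6) — small
  vessels disappear first; level 2 keeps only the unbranched trunks.
* **Noise**: additive Gaussian truncated at ±3σ on both channels
  (default σ 0.02), final clip to [0, 1]. Speckle statistics and any
  interferometric physics are out of scope.

Default sampling is dz = 8 µm, dy = dx = 24 µm (150 × 250 × 250 over
1.2 mm × 6 mm × 6 mm). These voxels are chosen as the coarsest grid
that cleanly resolves the generated features (≥100 µm bands, ≥300 µm
patterns, ≥24 µm vessels); the grid and depth are spec fields, so
finer, device-like sampling (3–5 µm axial) is available when wanted.
Generated volumes carry their ground truth (surface map, spot count,
tree junction count) in `meta` for verification.

## Automated graders

All graders measure relative to the detected surface, so a tilted
phantom grades identically to an untilted one (tested per grid cell).

* **Surface extraction**: adaptive threshold at air + 0.25·(tissue −
  air) (medians of the top slice and bottom half); first depth with two
  consecutive supra-threshold voxels; nearest-neighbour completion for
  missed columns with the direct-detection coverage reported, and an
  error below 50% coverage; 3 × 3 median smoothing.
* **Surface grade**: RMS of the plane-detrended height map; grade 1
  above 20 µm (healthy phantoms measure ~5 µm, wound-like ones
  ≥50 µm).
* **Epidermal loss**: contrast between a dermis reference band
  (160–250 µm below surface) and the expected epidermal band
  (16–96 µm); grade 1 below 0.20 (intact band measures ~0.44, absent
  ~0).
* **Dermal pattern** at the 0.3 mm en-face slice: glabrous — the
  strongest 2-D spectral peak in the 180–800 µm period band over the
  median band power; hair-bearing — spot density per mm² from local
  minima detection (≥150 µm separation, ≥0.10 depth), with the
  nearest-neighbour spacing CV reported as a regularity measurement.
* **Vasculature**: maximum-intensity projection of the flow channel,
  binarised at 0.4, morphologically closed, skeletonised; the grade
  statistic is skeleton branch points (≥3 of 8 neighbours) per mm².
  Mean vessel width (2 × distance transform at the skeleton) and the
  small-vessel fraction (<30 µm) are reported.

The two-threshold pairs that split each 0–2 item were calibrated on
the generator itself at default geometry and noise, set at the
geometric midpoint between the statistic ranges of adjacent levels
(glabrous peak ratio 1.3·10⁵ / 1.2·10³; spot density 7 / 1.5 per mm²;
branch density 4 / 0.4 per mm²). The glabrous spectral ratio grows
with the number of lateral samples, so those two thresholds apply at
the default 6 mm / 24 µm grid; the density-based statistics are
per-mm² and carry over to other fields of view. All thresholds live in
one `GraderConfig` and can be overridden from the run configuration.
They quantify inherently qualitative criteria ("partially visible")
and are **non-clinical**: they say nothing about real OCT scans.

On the default evaluation grid (3 dermal × 3 vascular levels × 10
seeds, hair-bearing, healthy surface/epidermis) the graders recover
every item's ground-truth grade on ≥90% of phantoms, and the pattern
and branch statistics degrade monotonically with level at fixed seed
(the grid reuses the seed set across cells precisely so that
comparison is seed-fixed).

## Numerical and formatting choices

* Round-half-up on the percent scale via `decimal.Decimal`, because
  banker's rounding would print 9/17 as 53% but 0.525 as 52%.
* Exhaustive enumeration (36 tuples) wherever possible instead of
  sampling.
* `float32` volumes; determinism is bit-exact for identical spec and
  seed (`numpy.random.default_rng` throughout, no global state).
* Degenerate inputs fail loudly: empty cohorts, all-zero confusion
  tables, all-zero volumes, zero-denominator metrics (absent, not 0),
  κ with degenerate marginals (absent, not 0 or 1).

## Known limitations

* The phantom is geometric, not physical: no speckle, refraction,
  shadowing or motion artifacts, so grader performance on phantoms
  overestimates performance on real scans by construction.
* The printed study statistics mix reference standards and their
  counts are not all mutually consistent; the package exposes the
  counts and the rule choice rather than guessing a single intended
  denominator.
* Spot detection assumes roughly grid-like spot spacing; heavily
  irregular real papillary patterns may need retuned separation and
  depth thresholds.
* The synthetic cohort treats wounds as independent; bilateral hands
  of one patient share nothing but the patient id.
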