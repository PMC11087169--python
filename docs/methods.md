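# Methods

## Dose-volume endpoints

All metrics are computed bin-free from the sorted voxel doses of a
structure; the binned cumulative DVH curve (default bin width 0.01
Gy-RBE) exists for display and cross-checking only. Relative volumes
are always relative to the structure's own volume; percent doses are
relative to that CTV level's own prescription.

* **V100** uses an inclusive comparison (dose ≥ prescription), matching
  the planning-goal wording "receives ≥100% of its prescription dose".
* **Dmax** is the maximum voxel dose, not a small-volume surrogate; it
  is a separate quantity from D0.03cc.
* **D98** (dose at volume) interpolates linearly between the anchors
  `(k/n, k-th largest dose)` of the cumulative volume fraction; a query
  of 100% returns the structure minimum, queries below `1/n` return the
  maximum. Clinical systems differ in whether they interpolate here;
  the rule is declared rather than inferred, and the oracle tests pin
  it down exactly.
* **D0.03cc** (dose at volume in cm³) accumulates descending-sorted
  voxel volumes; when the requested volume boundary splits a voxel,
  that voxel's dose is reported. This is conservative (reports the
  colder voxel at the boundary) and avoids inventing a sub-voxel dose
  model.
* Structures passed as empty masks produce a missing-marker row, the
  in-memory counterpart of the "–" cells of the endpoint tables.

Grids are axis-aligned with voxel-center coordinates; masks must be
congruent with the dose grid. The DICOM RT adapter rasterizes closed
planar contours at the dose grid's voxel centers with the even-odd rule
(multiple contours on a slice XOR together, so nested contours carve
holes); there is no sub-voxel partial-volume weighting.

## Scoring-system calibration

Each non-serial scoring function is modelled as two line segments
joined at a knot pinned on the clinical-goal value, capped at 7 on the
compliant side and unbounded below on the violating side. The free
parameters per function — goal-knot score, compliant-side slope,
violating-side slope — are recovered by linear least squares from the
printed (endpoint value, criterion score) pairs of the packaged tables.
Pairs whose printed score sits on the cap carry no slope information;
they are excluded from the fit and checked against the fitted function
afterwards. A segment with fewer than two informative pairs at distinct
abscissae is reported as under-determined rather than guessed.

One shared coverage function serves all three CTV levels, and one
mean-dose function both parotids. This sharing is itself a fit outcome:
the cross-level residuals stay within print rounding (max |residual|
0.052 over 192 pairs), which a per-level fit could not improve on
meaningfully.

Five table cells conflict with the numbers quoted in the running text
of the source analysis (e.g. a right-parotid mean printed as 29.7 in
the table but 29.5 in the text, with the printed score matching the
text value). These cells are recorded in
`aptqa.scoring.INCONSISTENT_CELLS`, excluded from calibration, and
flagged in the residual report — never silently corrected.

Serial organs are not calibrated: full score 7 within tolerance, step
penalty −150 beyond (configurable). No printed case exceeds tolerance,
so any intermediate slope near the tolerance would be pure invention.

Scores are reported rounded to 0.1; internal arithmetic is unrounded,
and totals are computed from unrounded criteria and rounded once. Some
published totals match the sum of *rounded* criteria instead; the two
conventions differ by at most 0.1 points on the packaged tables.

## Course evaluation and policies

Per-fraction dose grids are full-course equivalent: the in-use plan's
complete prescription recalculated on the day's anatomy. Accumulating
with fraction weights 1/n therefore yields a cumulative grid on the
plan dose scale. Daily evaluation computes the endpoint table and
scorecard of that dose against the day's structures, and the replan
trigger is the disjunction: any clinical goal failed, or total score
more than `drop_threshold` (default 3.0 points, configurable — the
workflow criterion "substantially worse" is qualitative) below the
nominal plan's total.

Policy defaults: offline evaluates at QACT fractions every 10 fractions
(bi-weekly at 5 fractions/week) and swaps plans 5 fractions after a
trigger (about a week of planning turnaround), with the standard 3 mm
setup margin; online evaluates before every fraction, delivers a
triggered replan the same fraction, and uses a 1.5 mm margin — only
defensible online, where the anatomy is imaged in treatment position
immediately before delivery. With lag 0, interval 1 and equal margins
the offline policy reduces exactly to the online policy, which the
tests assert.

Deformable mapping of daily anatomy to the reference frame is
represented by its rigid surrogate: identity plus a translation, with
trilinear resampling and zero outside the source support. The
interfaces accept pre-mapped per-fraction doses, so externally computed
deformable accumulations slot in unchanged. One consequence of the
rigid surrogate is handled explicitly: a volume-preserving deformable
map would carry dose delivered to a regressed target back over the
planning-CT target volume, while a rigid map cannot. Judging cumulative
target coverage on the initial masks would therefore penalize tight
online margins for an artifact of the surrogate, not of the policy.
Cumulative endpoints are instead evaluated on the course-final
structure set at the reference position
(`CourseInputs.evaluation_structures`; default is the reference set, so
static courses are unaffected).

## Synthetic course generator

The phantom is built from analytic primitives — ellipsoids for the
nested CTV levels (≈62 / 153 / 321 cm³ by default, inside the ranges
observed across real adaptive head-and-neck courses), parotids lateral,
oral cavity anterior, brainstem and spinal cord posterior (capsules).
A seed adds small reproducible jitter to centers and radii, giving a
cohort of distinct but comparable anatomies. The canonical (unjittered)
phantom's nominal plan meets every planning goal, like an approved
clinical plan; jittered variants may violate OAR goals for hard
geometries, as several published nominal plans do.

Anatomy change has three components, all seeded:

* per-structure exponential volume change (defaults −0.3 % to −0.5 %
  per fraction for targets and parotids, ≈9–14 % over 30 fractions, the
  magnitude seen in real courses; cumulative shrinkage is validated
  against a 30 % bound);
* a systematic whole-anatomy positional drift (default (0.10, 0.15, 0)
  mm/fraction, ≈5 mm over a course) representing progressive setup
  change, e.g. from weight loss;
* zero-mean isotropic Gaussian daily setup errors, σ = 1.5 mm truncated
  at 5 mm.

The dose surrogate is an analytic conformal field, not a proton
transport calculation: per target level, a plateau inside the
margin-expanded target with a Gaussian penumbra outside (default width
5 mm), combined across levels by voxel-wise maximum. The plateau
defaults to 1.04 × prescription (`hotspot_factor`): clinical plans
carry a hot spot of a few percent — the published CTV-High Dmax values
all lie between 103 % and 109 % — and an exact-prescription plateau
would make V100 collapse under any sub-voxel shift, which is an
artifact, not physics. Distances come from a Euclidean distance
transform with a half-voxel correction (the transform measures voxel
center to center; the structure surface lies about half a voxel
closer), which keeps sub-voxel margins meaningful on coarse grids.
Replans are planned on the anatomy as set up on the trigger day, so an
online replan delivered the same fraction aligns exactly.

What passing the policy tests shows — and what it does not: with common
random numbers the simulated courses demonstrate the *ordering* online
≥ offline ≥ no-adaptation under gradual drift, zero deltas for static
anatomy, and the offline-to-online limit equivalence. The generator
does not model proton range effects, CBCT artifacts, registration
error, rotations, or independent per-structure motion, so absolute
synthetic score values carry no clinical meaning; claims about real
courses rest on the published endpoint tables, which the scoring layer
reproduces.

## Problem sizes and determinism

The default phantom grid is 64×68×56 voxels at 2.5 mm; the test suite
runs its course simulations on a 4 mm coarsening (40×43×35) with 30
fractions and ten drift seeds, where one three-policy course takes
about a second. Every public entry point that consumes randomness takes
a seed; policies of one course share the identical anatomy and
setup-error stream, and repeated runs are bit-identical (the CLI writes
byte-identical manifests for equal seeds).

## Known limitations

* Rigid-translation deformation surrogate; no deformable registration.
* No dose calculation: the mock field has no range uncertainty, no
  beam geometry, no heterogeneity effects.
* Dmax of the mock plan equals the plateau by construction, so the
  hot-spot criterion only varies on imported dose grids.
* The calibration recovers the scoring functions only where printed
  pairs constrain them; behaviour far outside the observed endpoint
  range is linear extrapolation by construction.
* Serial-organ scoring near tolerance is a hard step; if the clinical
  rubric has intermediate slopes close to tolerance, no printed data
  constrains them.
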