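# aptqa

Plan-quality analysis for adaptive proton therapy (APT) courses in
head-and-neck radiotherapy: DVH endpoint extraction from voxel dose
grids, a modified ProKnow piecewise-linear scoring system, fraction-wise
course evaluation with replan triggering and dose accumulation, and
comparison of nominal / offline-adapted / online-adapted treatment
courses. A synthetic adaptive-course generator exercises the entire
pipeline without any clinical data.

## Who this is for

Medical physicists and researchers who want to quantify how much a
treatment course actually delivered — as opposed to what the approved
plan promised — when head-and-neck anatomy changes over 30–36 fractions
(tumour regression, resolving edema, weight loss, daily setup
variation), and to compare adaptation strategies: no adaptation, offline
replanning with a QACT-to-new-plan lag of about a week, or online
replanning before each fraction.

## The scoring model

Each criterion of the institutional planning guideline is scored by a
continuous piecewise-linear function of its dose-volume endpoint, and
the plan total is the equally-weighted sum over criteria:

```
S_total = Σ_c  f_c(m_c)
```

with endpoints `m_c` ∈ {V100 (% of structure volume receiving ≥100% of
prescription), Dmax (% of prescription), Dmean (Gy-RBE), D0.03cc
(Gy-RBE, minimal dose of the hottest 0.03 cm³)}. Every function is
capped at 7 and anchored with a knot at its clinical goal (coverage
V100 ≥ 98%, CTV-High Dmax ≤ 107%, parotid Dmean ≤ 26 Gy-RBE, oral
cavity Dmean ≤ 35 Gy-RBE); beyond the goal the score keeps falling
without a lower bound, so badly degraded courses keep separating.
Brainstem and spinal cord are serial organs: full score 7 inside
tolerance (D0.03cc ≤ 63 / 54 Gy-RBE), a step penalty of −150 beyond it.

The exact segment slopes are not hard-coded. `aptqa.scoring.calibrate`
recovers them by least squares from printed (endpoint, score) pairs
with the knot abscissae pinned at the goals; the packaged defaults were
frozen from that fit (`scripts/calibrate_defaults.py`). The recovered
geometry is strikingly clean: all four fitted functions share a
goal-knot score of 5, the compliant-side slopes are 1 score point per
unit (per % coverage, per Gy) — 0.4/% for the hot spot — and the
violating-side slopes are 5/3 per % (coverage, hot spot) and 5/4 per Gy
(mean doses).

Criteria whose structure a patient lacks are dropped from the sum, not
scored as zero. D98 is carried in every endpoint table but never scored.

## Course machinery

`aptqa.course` evaluates the in-use plan on each fraction's anatomy and
applies the replan trigger verbatim: adapt when any clinical goal fails
*or* the total score drops more than a configurable threshold (default
3 points) below the nominal plan's total. Policies differ only in when
they look and how fast a new plan arrives — `none`, `offline`
(evaluation at QACT fractions, default every 10, new plan after a
5-fraction lag, 3 mm margin) and `online` (every fraction, same-day
plan, 1.5 mm margin). Per-fraction doses are mapped to the reference
frame (rigid surrogate for deformable accumulation) and summed with
fraction weights; the cumulative dose is scored like any plan.

`aptqa.synthetic` generates head-and-neck-like phantoms (nested CTV
levels, parotids, oral cavity, brainstem, cord), drifts them fraction
by fraction, and computes an analytic conformal mock dose so policy
comparisons run end-to-end in seconds. All policies of a course share
one seeded anatomy/setup-error stream, so score differences are
attributable to the policy alone.

## Worked example

Score the packaged cohort endpoint table and build the course
comparison:

```python
from aptqa import score_table, compare_courses
from aptqa.io import load_endpoint_fixture

cards = score_table(load_endpoint_fixture("cohort"))
print(cards[cards.patient == 3].round(1))

totals = cards.pivot(index="patient", columns="course", values="total")
print(compare_courses(totals).table.round(1))
```

For patient 3 this prints (criterion columns abbreviated):

```
 patient  course  ctv_high_v100  ctv_high_dmax  ...  total
       3 nominal            6.9            4.3  ...   48.0
       3 offline            5.2            1.3  ...   28.8
       3  online            5.8            6.0  ...   55.6
```

The nominal plan scores 48.0; the actually delivered offline-adapted
course degrades to 28.8 (hot spot 109.2% → 1.3, CTV-Mid coverage 93.8%
→ −2.0), while the simulated online course ends at 55.6 — better than
the nominal plan, because daily replanning exploits the shrinking
anatomy. Over the ten-patient cohort the comparison table ends with

```
Score Nominal               ...  Average  41.0
Score Offline               ...  Average  25.8
Score Online                ...  Average  37.5
ΔScore Online - Offline     ...  Average  11.7
```

i.e. online adaptation recovers most of the quality the offline
workflow loses, improving every patient's course (mean improvement
11.7 points, up to 26.9).

The same operations are available from the shell:

```
aptqa score-endpoints -o cards.csv
aptqa report -i cards.csv -o comparison.csv
aptqa simulate-course --seed 7 -o sim/        # synthetic 3-policy course
aptqa evaluate-course --manifest sim/manifest.json -o eval.csv
aptqa calibrate -o functions.json             # refit scoring functions
```

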