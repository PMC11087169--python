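"""Fraction-wise course machinery.

Daily plan-quality evaluation with the replan trigger rule, rigid dose
mapping to the reference frame, dose accumulation over fractions, and
the nominal / offline / online course comparison.

Conventions
-----------
Per-fraction dose grids are *full-course equivalent*: the in-use plan's
complete prescription dose recalculated on the day's anatomy, exactly
as daily re-evaluation of an in-use plan produces it.  Accumulating a
course therefore uses fraction weights ``1/n`` so that the cumulative
grid is again on the full-course dose scale.

Deformable mapping of daily anatomy back to the planning frame is
represented by its rigid surrogate (identity plus a translation); the
interfaces accept pre-mapped per-fraction doses so externally computed
deformations slot in unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .dvh import extract_endpoints
from .grids import CongruenceError, DoseGrid, Prescription, StructureMask
from .scoring import (
    AnyScoringFunction,
    ClinicalGoal,
    ScoreCard,
    default_goals,
    score_endpoints,
)

__all__ = [
    "FractionRecord",
    "CourseSummary",
    "ComparisonReport",
    "Policy",
    "CourseInputs",
    "accumulate",
    "resample_to_frame",
    "evaluate_fraction",
    "run_policy",
    "compare_courses",
    "DEFAULT_DROP_THRESHOLD",
]

#: Score-point drop below the nominal total that counts as
#: "substantially worse" and triggers adaptation.  The criterion is
#: qualitative in the clinical workflow; the quantification is exposed
#: here and configurable per policy.
DEFAULT_DROP_THRESHOLD = 3.0


@dataclass
class FractionRecord:
    """One delivered fraction, mapped to the reference frame."""

    index: int
    dose: DoseGrid | None  # full-course-equivalent dose, post-mapping
    plan_id: str
    structures: Mapping[str, StructureMask] | None = None
    endpoints: pd.DataFrame | None = None
    goal_failures: list[str] = field(default_factory=list)
    total: float | None = None
    triggered: bool = False


@dataclass
class CourseSummary:
    """A whole course under one adaptation policy."""

    policy: str
    cumulative_dose: DoseGrid
    endpoints: pd.DataFrame
    scorecard: ScoreCard
    events: list[dict] = field(default_factory=list)
    fraction_log: pd.DataFrame | None = None
    fractions: list[FractionRecord] = field(default_factory=list)

    @property
    def total(self) -> float:
        return self.scorecard.total


def accumulate(
    fractions: Sequence[FractionRecord | DoseGrid],
    weights: Sequence[float] | None = None,
) -> DoseGrid:
    """Voxel-wise weighted sum of frame-aligned fraction doses.

    Weights default to 1 (plain sum); linear in its inputs and
    invariant under permutation of the fraction list.
    """
    doses = [f.dose if isinstance(f, FractionRecord) else f for f in fractions]
    if not doses or any(d is None for d in doses):
        raise ValueError("accumulate needs at least one fraction with a dose grid")
    first = doses[0]
    if weights is None:
        weights = [1.0] * len(doses)
    if len(weights) != len(doses):
        raise ValueError("one weight per fraction required")
    out = np.zeros(first.shape)
    for d, w in zip(doses, weights):
        if not d.same_frame(first):
            raise CongruenceError("fraction doses are on mixed grid frames")
        out += w * d.values
    return first.with_values(out)


def resample_to_frame(
    dose: DoseGrid,
    frame: DoseGrid,
    shift: Sequence[float] = (0.0, 0.0, 0.0),
) -> DoseGrid:
    """Resample ``dose`` onto ``frame`` after translating the field by
    ``shift`` (mm).

    The output value at target voxel-center position ``x`` is the
    trilinear interpolation of the source field at ``x - shift``;
    positions outside the source support are zero.  ``shift`` is the
    rigid displacement applied to the dose field, so the mapping that
    undoes an anatomy offset ``t`` passes ``shift=-t``.
    """
    shift = np.asarray(shift, dtype=float)
    if shift.shape != (3,):
        raise ValueError("shift must be a 3-vector (mm)")
    if min(dose.spacing) <= 0 or min(frame.spacing) <= 0:
        raise ValueError("degenerate spacing")
    # fractional source indices of each target voxel center
    coords = []
    for k in range(3):
        x = frame.origin[k] + frame.spacing[k] * np.arange(frame.shape[k])
        coords.append((x - shift[k] - dose.origin[k]) / dose.spacing[k])
    idx = np.meshgrid(*coords, indexing="ij")
    values = ndimage.map_coordinates(
        dose.values, np.stack(idx), order=1, mode="constant", cval=0.0
    )
    return frame.with_values(values)


def evaluate_fraction(
    record: FractionRecord,
    goals: Sequence[ClinicalGoal],
    fns: Mapping[str, AnyScoringFunction],
    rx: Prescription,
    nominal_total: float,
    drop_threshold: float = DEFAULT_DROP_THRESHOLD,
) -> FractionRecord:
    """Daily evaluation of the in-use plan on the day's anatomy.

    Computes the endpoint table and scorecard of ``record.dose``
    against ``record.structures`` and sets the adaptation trigger:
    adaptation is requested when any clinical goal fails *or* the total
    score falls more than ``drop_threshold`` points below the nominal
    plan's total.
    """
    if record.dose is None or record.structures is None:
        raise ValueError("fraction record needs a dose grid and a structure set")
    endpoints = extract_endpoints(record.dose, record.structures, rx)
    card = score_endpoints(endpoints, goals, fns)
    failures = []
    for g in goals:
        if g.structure not in endpoints.index:
            continue
        value = endpoints.loc[g.structure, g.metric]
        if pd.isna(value):
            continue
        if not g.passed(float(value)):
            failures.append(f"{g.structure} {g.metric} {g.direction} {g.bound}")
    record.endpoints = endpoints
    record.goal_failures = failures
    record.total = card.total
    record.triggered = bool(failures) or card.total < nominal_total - drop_threshold
    return record


@dataclass(frozen=True)
class Policy:
    """An adaptation policy.

    * ``none`` — deliver the nominal plan throughout.
    * ``offline`` — evaluate only at QACT fractions (every
      ``qact_interval`` fractions); a triggered replan becomes the
      in-use plan ``replan_lag`` fractions later, emulating the roughly
      one-week turnaround of offline replanning at 5 fractions/week.
    * ``online`` — evaluate before every fraction; a triggered replan
      is delivered the same fraction with the reduced online margin.
    """

    kind: str
    qact_interval: int = 10
    replan_lag: int = 5
    replan_margin_mm: float = 3.0
    drop_threshold: float = DEFAULT_DROP_THRESHOLD

    def __post_init__(self) -> None:
        if self.kind not in ("none", "offline", "online"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.qact_interval < 1 or self.replan_lag < 0:
            raise ValueError("qact_interval >= 1 and replan_lag >= 0 required")

    @classmethod
    def none(cls) -> "Policy":
        return cls("none")

    @classmethod
    def offline(
        cls,
        qact_interval: int = 10,
        replan_lag: int = 5,
        replan_margin_mm: float = 3.0,
        drop_threshold: float = DEFAULT_DROP_THRESHOLD,
    ) -> "Policy":
        return cls("offline", qact_interval, replan_lag, replan_margin_mm, drop_threshold)

    @classmethod
    def online(
        cls,
        replan_margin_mm: float = 1.5,
        drop_threshold: float = DEFAULT_DROP_THRESHOLD,
    ) -> "Policy":
        return cls("online", 1, 0, replan_margin_mm, drop_threshold)


@dataclass
class CourseInputs:
    """The fraction stream a policy runs against.

    The synthetic course generator produces these; a file-based loader
    can equally supply them from exported dose grids.

    ``daily_structures(f)`` returns the fraction-``f`` structure set in
    the reference frame (anatomy deformation applied, positional offset
    held separately); ``offsets(f)`` returns ``(anatomy_offset,
    setup_error)`` in mm.  ``make_plan(f, margin_mm)`` builds a new
    plan's full-course dose on the fraction-``f`` anatomy, expressed in
    the reference frame; run_policy tracks the positional offset the
    plan was made at.
    """

    frame: DoseGrid
    prescription: Prescription
    n_fractions: int
    reference_structures: Mapping[str, StructureMask]
    daily_structures: Callable[[int], Mapping[str, StructureMask]]
    offsets: Callable[[int], tuple[np.ndarray, np.ndarray]]
    make_plan: Callable[[int, float], DoseGrid]
    nominal_plan: DoseGrid
    #: structure set for cumulative-dose evaluation; defaults to the
    #: reference (planning) set.  With a rigid mapping surrogate a
    #: volume-preserving deformable accumulation is emulated by
    #: evaluating on the course-final structures at reference position.
    evaluation_structures: Mapping[str, StructureMask] | None = None


def _delivered_dose(
    plan: DoseGrid, plan_offset: np.ndarray, frame: DoseGrid, day_offset: np.ndarray
) -> DoseGrid:
    """Plan dose seen by the day's anatomy, in the reference frame.

    The plan field sits at ``plan_offset`` in room coordinates; the
    anatomy (after setup) at ``day_offset``.  When the two coincide the
    plan grid is returned untouched — the exact-alignment case of an
    online replan delivered the same fraction.
    """
    delta = np.asarray(plan_offset, dtype=float) - np.asarray(day_offset, dtype=float)
    if np.allclose(delta, 0.0):
        return plan
    return resample_to_frame(plan, frame, shift=delta)


def run_policy(
    course: CourseInputs,
    policy: Policy,
    goals: Sequence[ClinicalGoal] | None = None,
    fns: Mapping[str, AnyScoringFunction] | None = None,
    keep_fraction_doses: bool = True,
) -> CourseSummary:
    """Run one adaptation policy over a fraction stream.

    Every fraction the in-use plan's dose is mapped to the reference
    frame and evaluated against the day's structures.  Policies differ
    only in when they look and how fast a triggered replan arrives;
    the fraction stream itself (anatomy and setup errors) is identical
    across policies, so score differences are attributable to the
    policy alone.

    The course summary carries the accumulated (fraction-weighted)
    dose, the cumulative endpoints on the reference structures and the
    resulting scorecard.
    """
    if goals is None:
        goals = default_goals()
    if fns is None:
        from .io import default_scoring_functions

        fns = default_scoring_functions()
    frame = course.frame
    n = course.n_fractions
    rx = course.prescription

    nominal_card = score_endpoints(
        extract_endpoints(course.nominal_plan, course.reference_structures, rx),
        goals,
        fns,
    )
    nominal_total = nominal_card.total

    in_use = course.nominal_plan
    in_use_offset = np.zeros(3)
    in_use_id = "nominal"
    pending: tuple[int, DoseGrid, np.ndarray, str] | None = None
    records: list[FractionRecord] = []
    events: list[dict] = []
    log_rows = []
    running = np.zeros(frame.shape)

    for f in range(1, n + 1):
        anatomy_offset, setup_error = course.offsets(f)
        day_offset = np.asarray(anatomy_offset, float) + np.asarray(setup_error, float)
        structures = course.daily_structures(f)

        if pending is not None and f >= pending[0]:
            _, in_use, in_use_offset, in_use_id = pending
            pending = None

        record = FractionRecord(
            index=f,
            dose=_delivered_dose(in_use, in_use_offset, frame, day_offset),
            plan_id=in_use_id,
            structures=structures,
        )

        evaluates = (
            policy.kind == "online"
            or (policy.kind == "offline" and f % policy.qact_interval == 0)
        )
        if evaluates:
            evaluate_fraction(record, goals, fns, rx, nominal_total, policy.drop_threshold)
            if record.triggered and pending is None:
                new_plan = course.make_plan(f, policy.replan_margin_mm)
                new_id = f"replan_f{f}"
                apply_at = f + policy.replan_lag
                if apply_at <= f:
                    in_use, in_use_offset, in_use_id = new_plan, day_offset, new_id
                    record.dose = _delivered_dose(in_use, in_use_offset, frame, day_offset)
                    record.plan_id = in_use_id
                else:
                    pending = (apply_at, new_plan, day_offset, new_id)
                events.append(
                    {"fraction": f, "event": "replan", "applies_at": apply_at, "plan": new_id}
                )

        running += record.dose.values / n
        log_rows.append(
            {
                "fraction": f,
                "plan": record.plan_id,
                "evaluated": evaluates,
                "triggered": record.triggered,
                "total": record.total,
                "goal_failures": "; ".join(record.goal_failures),
            }
        )
        if not keep_fraction_doses:
            record.dose = None
            record.structures = None
        records.append(record)

    cumulative = frame.with_values(running)
    eval_structures = course.evaluation_structures or course.reference_structures
    endpoints = extract_endpoints(cumulative, eval_structures, rx)
    card = score_endpoints(endpoints, goals, fns)
    return CourseSummary(
        policy=policy.kind,
        cumulative_dose=cumulative,
        endpoints=endpoints,
        scorecard=card,
        events=events,
        fraction_log=pd.DataFrame(log_rows),
        fractions=records,
    )


COURSE_ORDER = ["nominal", "offline", "online"]
DELTA_ORDER = [("offline", "nominal"), ("online", "nominal"), ("online", "offline")]


@dataclass
class ComparisonReport:
    """Per-patient course totals, pairwise deltas and cohort averages,
    laid out as the score-comparison table: three score rows, three
    delta rows, one column per patient plus the cohort average."""

    table: pd.DataFrame

    def average(self, row: str) -> float:
        return float(self.table.loc[row, "Average"])


def compare_courses(
    totals: pd.DataFrame | Mapping[int, Mapping[str, float]],
    courses: Sequence[str] = COURSE_ORDER,
) -> ComparisonReport:
    """Build the course-comparison report from per-patient totals.

    ``totals`` maps patient -> course -> total score (a DataFrame with
    patients as index and course labels as columns works as-is).
    Deltas are exact differences of totals and cohort averages are
    arithmetic means over the included patients.
    """
    if not isinstance(totals, pd.DataFrame):
        totals = pd.DataFrame.from_dict(totals, orient="index")
    missing = [c for c in courses if c not in totals.columns]
    if missing:
        raise ValueError(f"missing course columns: {missing}")
    if len(totals) < 1:
        raise ValueError("at least one patient required")
    rows = {}
    for c in courses:
        rows[f"Score {c.capitalize()}"] = totals[c]
    for a, b in DELTA_ORDER:
        if a in totals.columns and b in totals.columns:
            rows[f"ΔScore {a.capitalize()} - {b.capitalize()}"] = totals[a] - totals[b]
    table = pd.DataFrame(rows).T
    table.columns = [f"Patient {p}" for p in totals.index]
    table["Average"] = table.mean(axis=1)
    return ComparisonReport(table)
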