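"""Synthetic adaptive-course generator.

Builds a head-and-neck-like voxel phantom from analytic primitives
(ellipsoids for the CTV levels, parotids and oral cavity; capsules for
brainstem and spinal cord), drifts the anatomy fraction by fraction
(gradual volume change plus a systematic positional drift and random
per-fraction setup errors), and computes a mock conformal dose for any
anatomy so that complete adaptive courses can be simulated and the
three adaptation policies compared end-to-end.

The dose surrogate is an analytic conformal field — prescription dose
inside the margin-expanded target with a Gaussian penumbra outside —
not a proton transport calculation.  The analysis layer only ever
consumes dose grids, so this is sufficient to exercise every pipeline
stage; no claim about proton physics rests on it.

Determinism: every public entry point takes a seed, and all policies
of one simulated course consume the identical anatomy and setup-error
stream (common random numbers), so policy score differences are
attributable to the policy alone.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .course import CourseInputs, CourseSummary, Policy, run_policy
from .grids import DoseGrid, Prescription, StructureMask, TARGET_STRUCTURES
from .scoring import AnyScoringFunction, ClinicalGoal

__all__ = [
    "Ellipsoid",
    "Capsule",
    "PhantomSpec",
    "DriftModel",
    "MockPlan",
    "default_phantom_spec",
    "default_drift_model",
    "make_phantom",
    "drift_anatomy",
    "mock_plan_dose",
    "build_course_inputs",
    "simulate_course",
    "dose_for_endpoints",
]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in mm."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    @property
    def volume_cc(self) -> float:
        rx, ry, rz = self.radii
        return 4.0 / 3.0 * np.pi * rx * ry * rz / 1000.0

    def scaled(self, volume_factor: float) -> "Ellipsoid":
        s = volume_factor ** (1.0 / 3.0)
        return Ellipsoid(self.center, tuple(r * s for r in self.radii))

    def shifted(self, offset: Sequence[float]) -> "Ellipsoid":
        return Ellipsoid(tuple(c + o for c, o in zip(self.center, offset)), self.radii)

    def rasterize(self, frame: DoseGrid) -> np.ndarray:
        ax = frame.axes()
        u = [(ax[k] - self.center[k]) / self.radii[k] for k in range(3)]
        return (
            u[0][:, None, None] ** 2 + u[1][None, :, None] ** 2 + u[2][None, None, :] ** 2
        ) <= 1.0


@dataclass(frozen=True)
class Capsule:
    """A cylinder with hemispherical caps: segment endpoints and radius (mm)."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    @property
    def volume_cc(self) -> float:
        length = float(np.linalg.norm(np.subtract(self.p1, self.p0)))
        return (np.pi * self.radius**2 * length + 4.0 / 3.0 * np.pi * self.radius**3) / 1000.0

    def scaled(self, volume_factor: float) -> "Capsule":
        s = volume_factor ** (1.0 / 3.0)
        mid = 0.5 * (np.asarray(self.p0) + np.asarray(self.p1))
        p0 = mid + s * (np.asarray(self.p0) - mid)
        p1 = mid + s * (np.asarray(self.p1) - mid)
        return Capsule(tuple(p0), tuple(p1), self.radius * s)

    def shifted(self, offset: Sequence[float]) -> "Capsule":
        return Capsule(
            tuple(c + o for c, o in zip(self.p0, offset)),
            tuple(c + o for c, o in zip(self.p1, offset)),
            self.radius,
        )

    def rasterize(self, frame: DoseGrid) -> np.ndarray:
        ax = frame.axes()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        p = np.stack([X, Y, Z], axis=-1)
        a = np.asarray(self.p0, float)
        b = np.asarray(self.p1, float)
        ab = b - a
        denom = float(ab @ ab) or 1.0
        t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        dist2 = np.sum((p - closest) ** 2, axis=-1)
        return dist2 <= self.radius**2


Primitive = Ellipsoid | Capsule


@dataclass(frozen=True)
class PhantomSpec:
    """Grid geometry plus structure primitives and prescription levels."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    primitives: Mapping[str, Primitive]
    prescription: Prescription
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: warn when an OAR overlaps the highest target level by more than
    #: this fraction of the OAR volume
    oar_overlap_warn: float = 0.25

    def frame(self) -> DoseGrid:
        return DoseGrid(np.zeros(self.shape), self.spacing, self.origin)


def default_phantom_spec(seed: int | None = None) -> PhantomSpec:
    """A head-and-neck-like phantom on a 2.5 mm grid.

    Default target volumes sit inside the ranges observed across real
    adaptive courses (CTV-High of order tens of cm^3 nested inside
    mid- and low-risk volumes of one to a few hundred cm^3), with the
    parotids lateral, the oral cavity anterior, and the brainstem and
    spinal cord posterior to the target complex.  A seed adds a small
    reproducible jitter to centers and radii, giving a cohort of
    distinct but comparable anatomies.
    """
    rng = np.random.default_rng(seed)

    def jit(scale: float) -> float:
        return float(rng.uniform(-scale, scale)) if seed is not None else 0.0

    prims: dict[str, Primitive] = {
        "CTV-High": Ellipsoid(
            (80.0 + jit(4), 72.0 + jit(4), 62.0 + jit(3)),
            (28.0 * (1 + jit(0.08)), 24.0 * (1 + jit(0.08)), 22.0 * (1 + jit(0.08))),
        ),
        "CTV-Mid": Ellipsoid(
            (80.0 + jit(3), 74.0 + jit(3), 62.0 + jit(3)),
            (38.0 * (1 + jit(0.06)), 32.0 * (1 + jit(0.06)), 30.0 * (1 + jit(0.06))),
        ),
        "CTV-Low": Ellipsoid(
            (80.0 + jit(2), 77.0 + jit(2), 64.0 + jit(2)),
            (48.0 * (1 + jit(0.05)), 42.0 * (1 + jit(0.05)), 38.0 * (1 + jit(0.05))),
        ),
        "Right Parotid": Ellipsoid((21.0 + jit(2), 72.0 + jit(2), 60.0 + jit(2)), (11.0, 14.0, 19.0)),
        "Left Parotid": Ellipsoid((139.0 + jit(2), 72.0 + jit(2), 60.0 + jit(2)), (11.0, 14.0, 19.0)),
        "Oral Cavity": Ellipsoid((80.0 + jit(2), 132.0 + jit(2), 60.0 + jit(2)), (24.0, 21.0, 17.0)),
        "Brainstem": Capsule((80.0, 38.0, 104.0), (80.0, 38.0, 126.0), 9.0),
        "Spinal Cord": Capsule((80.0, 19.0, 4.0), (80.0, 21.0, 98.0), 5.5),
    }
    rx = Prescription({"CTV-High": 70.0, "CTV-Mid": 63.0, "CTV-Low": 56.0}, n_fractions=35)
    return PhantomSpec(shape=(64, 68, 56), spacing=(2.5, 2.5, 2.5), primitives=prims, prescription=rx)


@dataclass(frozen=True)
class DriftModel:
    """Gradual anatomy change over the course.

    ``volume_rate`` holds per-structure fractional volume change per
    fraction (negative = shrinkage), emulating resolving edema and
    tumor regression; cumulative shrinkage over the course is bounded
    at 30%.  ``drift_mm_per_fraction`` is a systematic whole-anatomy
    positional drift per fraction (weight loss changing the setup), and
    per-fraction setup errors are zero-mean isotropic Gaussian draws
    truncated at ``setup_max_mm``.
    """

    volume_rate: Mapping[str, float] = field(default_factory=dict)
    drift_mm_per_fraction: tuple[float, float, float] = (0.0, 0.0, 0.0)
    setup_sigma_mm: float = 1.5
    setup_max_mm: float = 5.0

    def validate(self, n_fractions: int) -> None:
        for name, rate in self.volume_rate.items():
            final = (1.0 + rate) ** n_fractions
            if final < 0.7 - 1e-9:
                raise ValueError(
                    f"{name}: cumulative shrinkage {1 - final:.1%} over "
                    f"{n_fractions} fractions exceeds the 30% bound"
                )

    def volume_factor(self, name: str, fraction_index: int) -> float:
        return (1.0 + self.volume_rate.get(name, 0.0)) ** fraction_index

    def anatomy_offset(self, fraction_index: int) -> np.ndarray:
        return fraction_index * np.asarray(self.drift_mm_per_fraction, float)

    def setup_errors(self, n_fractions: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        draws = rng.normal(0.0, self.setup_sigma_mm, size=(n_fractions, 3))
        return np.clip(draws, -self.setup_max_mm, self.setup_max_mm)


def default_drift_model() -> DriftModel:
    """Drift of the magnitude seen over real courses: targets and
    parotids shrinking by roughly 10-20% over 30-36 fractions, a slow
    systematic positional drift of a few mm total, and 1.5 mm-sigma
    daily setup errors."""
    return DriftModel(
        volume_rate={
            "CTV-High": -0.005,
            "CTV-Mid": -0.004,
            "CTV-Low": -0.003,
            "Right Parotid": -0.005,
            "Left Parotid": -0.005,
        },
        drift_mm_per_fraction=(0.10, 0.15, 0.0),
        setup_sigma_mm=1.5,
        setup_max_mm=5.0,
    )


def _role(name: str) -> str:
    return "target" if name in TARGET_STRUCTURES else "oar"


def make_phantom(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[DoseGrid, dict[str, StructureMask]]:
    """Rasterize a phantom spec to a reference frame and structure set.

    ``seed`` only matters when the spec itself was built with jitter;
    rasterization is deterministic.  Warns if an OAR overlaps CTV-High
    beyond the configured fraction of its volume.
    """
    frame = spec.frame()
    masks: dict[str, StructureMask] = {}
    for name, prim in spec.primitives.items():
        m = prim.rasterize(frame)
        if not m.any():
            raise ValueError(f"structure {name!r} rasterizes to an empty mask")
        masks[name] = StructureMask(name, m, role=_role(name))
    high = masks.get("CTV-High")
    if high is not None:
        for name, sm in masks.items():
            if sm.role != "oar":
                continue
            overlap = np.logical_and(sm.mask, high.mask).sum() / sm.mask.sum()
            if overlap > spec.oar_overlap_warn:
                warnings.warn(
                    f"OAR {name!r} overlaps CTV-High by {overlap:.0%}", stacklevel=2
                )
    return frame, masks


def drift_anatomy(
    spec: PhantomSpec, fraction_index: int, model: DriftModel
) -> dict[str, Primitive]:
    """The phantom primitives at a given fraction: volumes scaled along
    the model's analytic trajectory.  The whole-anatomy positional
    offset is reported separately by the model so that plan/anatomy
    alignment stays a pure translation."""
    out: dict[str, Primitive] = {}
    for name, prim in spec.primitives.items():
        out[name] = prim.scaled(model.volume_factor(name, fraction_index))
    return out


@dataclass(frozen=True)
class MockPlan:
    """Parameters of the analytic conformal dose surrogate.

    ``hotspot_factor`` sets the plateau dose inside the margin-expanded
    target relative to prescription.  Clinical plans carry a hot spot of
    a few percent (the endpoint tables show CTV-High Dmax around
    103-108% of prescription), which also gives daily coverage its
    realistic robustness: the 100%-isodose surface sits slightly
    outside the target rather than exactly on it.  Set it to 1 for the
    plain indicator-dose limit.
    """

    margin_mm: float = 3.0
    penumbra_mm: float = 5.0
    background_gy: float = 0.0
    hotspot_factor: float = 1.04

    def __post_init__(self) -> None:
        if self.margin_mm < 0 or self.penumbra_mm < 0 or self.background_gy < 0:
            raise ValueError("margin, penumbra and background must be non-negative")
        if self.hotspot_factor < 1.0:
            raise ValueError("hotspot_factor must be >= 1")


def _conformal_field(
    target_mask: np.ndarray, frame: DoseGrid, level: float, plan: MockPlan
) -> np.ndarray:
    """Plateau inside target+margin, Gaussian falloff outside.

    The Euclidean distance transform measures voxel center to voxel
    center; the target surface lies about half a voxel closer, so a
    half-voxel correction keeps sub-voxel margins meaningful on coarse
    grids.
    """
    outside_mm = ndimage.distance_transform_edt(~target_mask, sampling=frame.spacing)
    outside_mm = np.maximum(outside_mm - 0.5 * float(np.mean(frame.spacing)), 0.0)
    expanded = outside_mm <= plan.margin_mm
    d = np.maximum(outside_mm - plan.margin_mm, 0.0)
    plateau = plan.hotspot_factor * level
    if plan.penumbra_mm > 0:
        field = plateau * np.exp(-0.5 * (d / plan.penumbra_mm) ** 2)
    else:
        field = np.where(expanded, plateau, 0.0)
    field[expanded] = plateau
    return field


def mock_plan_dose(
    structures: Mapping[str, StructureMask],
    frame: DoseGrid,
    rx: Prescription,
    plan: MockPlan | None = None,
) -> DoseGrid:
    """Mock conformal dose for a structure set: per level, prescription
    dose inside the margin-expanded target with Gaussian penumbra
    outside; the final field is the voxel-wise maximum over levels plus
    a uniform background.  Deterministic."""
    if plan is None:
        plan = MockPlan()
    targets = [n for n in TARGET_STRUCTURES if n in structures and not structures[n].is_empty]
    if not targets:
        raise ValueError("mock plan needs at least one target structure")
    dose = np.full(frame.shape, plan.background_gy)
    for name in targets:
        field = _conformal_field(structures[name].mask, frame, rx.level_for(name), plan)
        np.maximum(dose, field, out=dose)
    return frame.with_values(dose)


def build_course_inputs(
    spec: PhantomSpec,
    model: DriftModel,
    n_fractions: int | None = None,
    seed: int = 0,
    nominal_plan: MockPlan | None = None,
) -> CourseInputs:
    """Assemble the fraction stream for one simulated course.

    All randomness (the setup-error sequence) is drawn once from
    ``seed``; policies evaluated against the returned inputs therefore
    share common random numbers.  Daily structure sets are cached per
    fraction.
    """
    if n_fractions is None:
        n_fractions = spec.prescription.n_fractions
    model.validate(n_fractions)
    if nominal_plan is None:
        nominal_plan = MockPlan()
    frame, reference = make_phantom(spec)
    errors = model.setup_errors(n_fractions, seed)
    rx = replace(spec.prescription, n_fractions=n_fractions)

    cache: dict[int, dict[str, StructureMask]] = {}

    def daily_structures(f: int) -> dict[str, StructureMask]:
        if f not in cache:
            prims = drift_anatomy(spec, f, model)
            cache[f] = {
                name: StructureMask(name, p.rasterize(frame), role=_role(name))
                for name, p in prims.items()
            }
        return cache[f]

    def offsets(f: int) -> tuple[np.ndarray, np.ndarray]:
        return model.anatomy_offset(f), errors[f - 1]

    def make_plan(f: int, margin_mm: float) -> DoseGrid:
        return mock_plan_dose(
            daily_structures(f), frame, rx, replace(nominal_plan, margin_mm=margin_mm)
        )

    nominal_dose = mock_plan_dose(reference, frame, rx, nominal_plan)
    return CourseInputs(
        frame=frame,
        prescription=rx,
        n_fractions=n_fractions,
        reference_structures=reference,
        daily_structures=daily_structures,
        offsets=offsets,
        make_plan=make_plan,
        nominal_plan=nominal_dose,
        # rigid accumulation cannot re-expand dose over regressed
        # volumes the way a deformable map would; judging the
        # cumulative dose on the course-final anatomy keeps target
        # coverage semantics consistent with deformable accumulation
        evaluation_structures=daily_structures(n_fractions),
    )


def simulate_course(
    spec: PhantomSpec,
    model: DriftModel,
    policies: Sequence[Policy],
    n_fractions: int | None = None,
    seed: int = 0,
    goals: Sequence[ClinicalGoal] | None = None,
    fns: Mapping[str, AnyScoringFunction] | None = None,
    keep_fraction_doses: bool = False,
) -> dict[str, CourseSummary]:
    """Simulate one adaptive course under several policies.

    Reproducible given the seed; every policy consumes the identical
    anatomy and setup-error stream.  Returns one course summary per
    policy, keyed by policy kind.
    """
    course = build_course_inputs(spec, model, n_fractions, seed)
    out: dict[str, CourseSummary] = {}
    for policy in policies:
        out[policy.kind] = run_policy(
            course, policy, goals=goals, fns=fns, keep_fraction_doses=keep_fraction_doses
        )
    return out


def dose_for_endpoints(
    frame: DoseGrid,
    target: StructureMask,
    rx_level: float,
    v100_pct: float,
    oar_means: Mapping[str, tuple[StructureMask, float]] | None = None,
    cold_fraction_of_rx: float = 0.95,
) -> DoseGrid:
    """Construct a dose grid that realizes requested endpoints exactly
    (up to one voxel of volume) — the inversion oracle for endpoint
    extraction.

    The first ``round(v100/100 * n)`` target voxels (in index order)
    receive the prescription, the rest ``cold_fraction_of_rx`` of it;
    each listed OAR (disjoint from the target) receives its requested
    mean uniformly.
    """
    if not 0 <= v100_pct <= 100:
        raise ValueError("v100_pct must be within [0, 100]")
    values = np.zeros(frame.shape)
    idx = np.flatnonzero(target.mask.ravel())
    k = int(round(v100_pct / 100.0 * idx.size))
    flat = values.ravel()
    flat[idx] = cold_fraction_of_rx * rx_level
    flat[idx[:k]] = rx_level
    if oar_means:
        for name, (mask, mean) in oar_means.items():
            if np.logical_and(mask.mask, target.mask).any():
                raise ValueError(f"OAR {name!r} overlaps the target; inversion not exact")
            flat[np.flatnonzero(mask.mask.ravel())] = mean
    return frame.with_values(values.reshape(frame.shape))
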