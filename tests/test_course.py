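"""Dose accumulation, rigid resampling, triggering and course comparison."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aptqa.course import (
    FractionRecord,
    Policy,
    accumulate,
    compare_courses,
    evaluate_fraction,
    resample_to_frame,
    run_policy,
)
from aptqa.grids import CongruenceError, DoseGrid, Prescription, StructureMask
from aptqa.synthetic import DriftModel, build_course_inputs, default_drift_model

from conftest import coarse_spec, random_case


def _grid(values, spacing=(2.0, 2.0, 2.0)):
    return DoseGrid(values, spacing)


class TestAccumulate:
    def test_n_identical_fractions_sum_linearly(self):
        d = _grid(np.full((4, 4, 4), 2.0))
        out = accumulate([d] * 5)
        assert np.allclose(out.values, 10.0)

    def test_zero_dose_fraction_leaves_sum_unchanged(self):
        d = _grid(np.random.default_rng(0).uniform(0, 3, (4, 4, 4)))
        base = accumulate([d, d])
        with_zero = accumulate([d, d, d.with_values(np.zeros(d.shape))])
        assert np.allclose(base.values, with_zero.values)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_elementwise_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        doses = [_grid(rng.uniform(0, 2, (3, 4, 5))) for _ in range(4)]
        weights = rng.uniform(0.2, 2.0, 4)
        out = accumulate(doses, weights)
        expected = np.zeros((3, 4, 5))
        for d, w in zip(doses, weights):
            for idx in np.ndindex(*d.shape):
                expected[idx] += w * d.values[idx]
        assert np.allclose(out.values, expected)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        doses = [_grid(rng.uniform(0, 2, (3, 3, 3))) for _ in range(5)]
        a = accumulate(doses)
        b = accumulate(doses[::-1])
        assert np.allclose(a.values, b.values)

    def test_mixed_frames_rejected(self):
        a = _grid(np.ones((3, 3, 3)))
        b = DoseGrid(np.ones((3, 3, 3)), (1.0, 1.0, 1.0))
        with pytest.raises(CongruenceError):
            accumulate([a, b])

    def test_accepts_fraction_records(self):
        d = _grid(np.ones((3, 3, 3)))
        recs = [FractionRecord(i, d, "nominal") for i in (1, 2)]
        assert np.allclose(accumulate(recs).values, 2.0)


class TestResample:
    def test_zero_shift_identity(self):
        dose, _ = random_case(3)
        out = resample_to_frame(dose, dose, shift=(0, 0, 0))
        assert np.allclose(out.values, dose.values)

    def test_one_voxel_pitch_shift_on_constant_field(self):
        d = _grid(np.full((6, 6, 6), 4.0))
        out = resample_to_frame(d, d, shift=(2.0, 0.0, 0.0))
        assert np.allclose(out.values[1:, :, :], 4.0)  # interior unchanged

    def test_half_voxel_shift_on_linear_ramp_is_analytic(self):
        # f(x) = x on a 2 mm grid; translating the field by +1 mm gives
        # f(x - 1) = x - 1 exactly under trilinear interpolation
        nx = 8
        ramp = np.tile(np.arange(nx, dtype=float)[:, None, None] * 2.0, (1, 4, 4))
        d = _grid(ramp)
        out = resample_to_frame(d, d, shift=(1.0, 0.0, 0.0))
        x = np.arange(nx) * 2.0
        expected = np.clip(x - 1.0, 0.0, None)
        assert np.allclose(out.values[1:-1, 1, 1], expected[1:-1])

    def test_degenerate_shift_rejected(self):
        dose, _ = random_case(0)
        with pytest.raises(ValueError):
            resample_to_frame(dose, dose, shift=(1.0, 2.0))


def _single_target_record(v100_frac: float, rx_level=70.0, n=10):
    """A fraction record with one CTV at a chosen V100."""
    shape = (n, n, n)
    mask = np.zeros(shape, bool)
    mask[2:8, 2:8, 2:8] = True
    k = int(round(v100_frac / 100.0 * mask.sum()))
    values = np.zeros(shape)
    idx = np.flatnonzero(mask.ravel())
    flat = values.ravel()
    flat[idx] = 0.99 * rx_level
    flat[idx[:k]] = rx_level
    dose = DoseGrid(values.reshape(shape), (2.0, 2.0, 2.0))
    structures = {"CTV-High": StructureMask("CTV-High", mask, role="target")}
    return FractionRecord(1, dose, "nominal", structures)


class TestTriggerRule:
    def test_no_trigger_when_goals_met_and_score_nominal(self, goals, fns):
        rec = _single_target_record(100.0)
        rx = Prescription({"CTV-High": 70.0})
        nominal_total = 14.0  # coverage 7 + hot spot 7
        evaluate_fraction(rec, goals, fns, rx, nominal_total)
        assert not rec.triggered and rec.goal_failures == []

    def test_coverage_just_below_goal_triggers(self, goals, fns):
        # V100 = 97.9% against the >= 98% goal
        rec = _single_target_record(97.9)
        rx = Prescription({"CTV-High": 70.0})
        evaluate_fraction(rec, goals, fns, rx, nominal_total=0.0)
        assert rec.triggered
        assert any("CTV-High V100" in f for f in rec.goal_failures)

    def test_score_drop_alone_triggers_by_disjunction(self, goals, fns):
        rec = _single_target_record(100.0)  # all goals met
        rx = Prescription({"CTV-High": 70.0})
        evaluate_fraction(rec, goals, fns, rx, nominal_total=50.0, drop_threshold=3.0)
        # goals pass but the total is far below the claimed nominal
        assert rec.goal_failures == []
        assert rec.triggered


class TestCompareCourses:
    def test_published_totals_give_published_averages(self, cohort_scores):
        totals = cohort_scores.pivot(index="patient", columns="course", values="total")
        report = compare_courses(totals)
        assert report.average("Score Nominal") == pytest.approx(41.0, abs=0.05)
        assert report.average("Score Offline") == pytest.approx(25.8, abs=0.05)
        assert report.average("Score Online") == pytest.approx(37.5, abs=0.05)
        assert report.average("ΔScore Online - Offline") == pytest.approx(11.7, abs=0.05)

    def test_deltas_are_antisymmetric_and_consistent(self, cohort_scores):
        totals = cohort_scores.pivot(index="patient", columns="course", values="total")
        t = compare_courses(totals).table
        on_off = t.loc["ΔScore Online - Offline"]
        off_nom = t.loc["ΔScore Offline - Nominal"]
        on_nom = t.loc["ΔScore Online - Nominal"]
        assert np.allclose(on_off + off_nom, on_nom)
        reversed_ = compare_courses(totals.rename(columns={"online": "offline", "offline": "online"}))
        assert np.allclose(
            reversed_.table.loc["ΔScore Online - Offline"], -on_off
        )

    def test_identical_courses_have_zero_deltas(self):
        totals = pd.DataFrame({"nominal": [40.0], "offline": [40.0], "online": [40.0]})
        t = compare_courses(totals).table
        assert np.allclose(t.loc["ΔScore Online - Offline"], 0.0)

    def test_single_patient_average_is_that_patient(self):
        totals = pd.DataFrame(
            {"nominal": [41.0], "offline": [30.0], "online": [38.0]}, index=[4]
        )
        report = compare_courses(totals)
        assert report.average("Score Nominal") == 41.0
        assert report.table.loc["ΔScore Online - Offline", "Patient 4"] == 8.0


class TestRunPolicy:
    def test_static_anatomy_all_policies_identical(self, fns):
        model = DriftModel(setup_sigma_mm=0.0)  # no drift, no setup error
        course = build_course_inputs(coarse_spec(1), model, n_fractions=8, seed=1)
        totals = {}
        for policy in (Policy.none(), Policy.offline(), Policy.online()):
            s = run_policy(course, policy, fns=fns, keep_fraction_doses=False)
            totals[policy.kind] = s.total
            assert s.events == []
        assert len(set(np.round(list(totals.values()), 9))) == 1

    def test_offline_with_zero_lag_unit_interval_equals_online(self, fns):
        model = default_drift_model()
        course = build_course_inputs(coarse_spec(2), model, n_fractions=12, seed=2)
        offline = run_policy(
            course,
            Policy.offline(qact_interval=1, replan_lag=0, replan_margin_mm=1.5),
            fns=fns,
            keep_fraction_doses=False,
        )
        online = run_policy(course, Policy.online(), fns=fns, keep_fraction_doses=False)
        assert offline.total == pytest.approx(online.total, abs=1e-9)
        assert [e["fraction"] for e in offline.events] == [
            e["fraction"] for e in online.events
        ]

    def test_online_never_below_no_adaptation_on_drift(self, fns):
        model = default_drift_model()
        for seed in (3, 4):
            course = build_course_inputs(coarse_spec(seed), model, n_fractions=15, seed=seed)
            none = run_policy(course, Policy.none(), fns=fns, keep_fraction_doses=False)
            online = run_policy(course, Policy.online(), fns=fns, keep_fraction_doses=False)
            assert online.total >= none.total - 1e-9

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            Policy("weekly")
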