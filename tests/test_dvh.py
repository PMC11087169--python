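"""DVH curve and endpoint extraction against brute-force voxel oracles."""
from __future__ import annotations

import numpy as np
import pytest

from aptqa.dvh import (
    cumulative_dvh,
    dose_at_cc,
    dose_at_volume,
    extract_endpoints,
    volume_at_dose,
)
from aptqa.grids import (
    CongruenceError,
    DoseGrid,
    Prescription,
    StructureMask,
    StructureAbsentError,
)

from conftest import random_case


# ---------------------------------------------------------------- oracles
# Independent brute-force implementations used only to check the library.


def oracle_volume_at_dose(dose, mask, threshold):
    count = total = 0
    for d, m in zip(dose.values.ravel(), mask.mask.ravel()):
        if m:
            total += 1
            if d >= threshold:
                count += 1
    return 100.0 * count / total


def oracle_dose_at_volume(dose, mask, volume_pct):
    """Linear interpolation between the anchors (k/n, k-th largest dose)."""
    e = sorted((d for d, m in zip(dose.values.ravel(), mask.mask.ravel()) if m), reverse=True)
    n = len(e)
    q = volume_pct / 100.0
    anchors = [((k + 1) / n, e[k]) for k in range(n)]
    if q <= anchors[0][0]:
        return anchors[0][1]
    for (q0, d0), (q1, d1) in zip(anchors, anchors[1:]):
        if q <= q1:
            return d0 + (d1 - d0) * (q - q0) / (q1 - q0)
    return anchors[-1][1]


def oracle_dose_at_cc(dose, mask, cc):
    e = sorted((d for d, m in zip(dose.values.ravel(), mask.mask.ravel()) if m), reverse=True)
    voxel_cc = dose.voxel_volume_cc
    acc = 0.0
    for d in e:
        acc += voxel_cc
        if acc >= cc - 1e-12:
            return d
    return e[-1]


# ----------------------------------------------------------------- curves


def test_uniform_field_dvh_is_a_step():
    dose = DoseGrid(np.full((5, 5, 5), 60.0), (2.0, 2.0, 2.0))
    mask = StructureMask("ROI", np.ones((5, 5, 5), bool))
    curve = cumulative_dvh(dose, mask, bin_width=0.5)
    assert np.all(curve.volume_pct[curve.dose <= 60.0] == 100.0)
    assert np.all(curve.volume_pct[curve.dose > 60.0] == 0.0)


def test_two_level_field_dvh_steps_at_both_levels():
    values = np.full((4, 4, 4), 35.0)
    values[:2] = 70.0
    dose = DoseGrid(values, (1.0, 1.0, 1.0))
    mask = StructureMask("ROI", np.ones((4, 4, 4), bool))
    curve = cumulative_dvh(dose, mask, bin_width=0.5)
    assert curve.volume_at(0.0) == 100.0
    assert curve.volume_at(35.0) == 100.0
    assert curve.volume_at(35.5) == 50.0
    assert curve.volume_at(70.0) == 50.0
    assert curve.volume_at(70.5) == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_dvh_curve_matches_threshold_counting(seed):
    dose, mask = random_case(seed)
    curve = cumulative_dvh(dose, mask, bin_width=0.5)
    for edge, vol in zip(curve.dose[::7], curve.volume_pct[::7]):
        assert vol == pytest.approx(oracle_volume_at_dose(dose, mask, edge), abs=1e-9)


@pytest.mark.parametrize("seed", range(3))
def test_dvh_curve_invariants(seed):
    dose, mask = random_case(seed)
    curve = cumulative_dvh(dose, mask)
    assert curve.volume_pct[0] == 100.0
    assert np.all(np.diff(curve.volume_pct) <= 0)
    assert curve.volume_pct[-1] >= 0


# ---------------------------------------------------------------- metrics


def test_volume_at_dose_is_inclusive_and_bounded():
    dose = DoseGrid(np.full((3, 3, 3), 50.0), (1.0, 1.0, 1.0))
    mask = StructureMask("ROI", np.ones((3, 3, 3), bool))
    assert volume_at_dose(dose, mask, 50.0) == 100.0  # >= is inclusive
    assert volume_at_dose(dose, mask, 50.01) == 0.0


def test_dose_at_volume_uniform_and_limits():
    dose = DoseGrid(np.full((3, 3, 3), 42.0), (1.0, 1.0, 1.0))
    mask = StructureMask("ROI", np.ones((3, 3, 3), bool))
    for pct in (2.0, 50.0, 98.0, 100.0):
        assert dose_at_volume(dose, mask, pct) == pytest.approx(42.0)


def test_dose_at_volume_hundred_equal_voxels():
    # 100 equal-volume voxels with doses 1..100 Gy; the 98%-volume anchor
    # falls exactly on the 98th-largest dose, i.e. 3 Gy.
    values = np.arange(1.0, 101.0).reshape(10, 10, 1)
    dose = DoseGrid(values, (1.0, 1.0, 1.0))
    mask = StructureMask("ROI", np.ones((10, 10, 1), bool))
    assert dose_at_volume(dose, mask, 98.0) == pytest.approx(3.0)
    assert dose_at_volume(dose, mask, 100.0) == pytest.approx(1.0)  # minimum


def test_dose_at_cc_partial_voxel_rule():
    # one hot voxel of 0.027 cc in a 30 Gy background: the 0.03 cc
    # boundary splits the second-hottest voxel, whose dose is reported
    values = np.full((4, 4, 4), 30.0)
    values[0, 0, 0] = 70.0
    dose = DoseGrid(values, (3.0, 3.0, 3.0))  # 0.027 cc voxels
    mask = StructureMask("ROI", np.ones((4, 4, 4), bool))
    assert dose_at_cc(dose, mask, 0.027) == pytest.approx(70.0)
    assert dose_at_cc(dose, mask, 0.03) == pytest.approx(30.0)


def test_dose_at_cc_full_volume_is_minimum():
    dose, mask = random_case(11)
    full = mask.voxel_count * dose.voxel_volume_cc
    assert dose_at_cc(dose, mask, full) == pytest.approx(dose.values[mask.mask].min())


@pytest.mark.parametrize("seed", range(8))
def test_metrics_match_bruteforce_oracles(seed):
    dose, mask = random_case(seed)
    rng = np.random.default_rng(seed + 1000)
    for threshold in rng.uniform(0, 85, size=4):
        assert volume_at_dose(dose, mask, threshold) == pytest.approx(
            oracle_volume_at_dose(dose, mask, threshold)
        )
    for pct in rng.uniform(1, 100, size=4):
        assert dose_at_volume(dose, mask, pct) == pytest.approx(
            oracle_dose_at_volume(dose, mask, pct)
        )
    full = mask.voxel_count * dose.voxel_volume_cc
    for cc in rng.uniform(0.01, full, size=4):
        assert dose_at_cc(dose, mask, cc) == pytest.approx(
            oracle_dose_at_cc(dose, mask, cc)
        )


@pytest.mark.parametrize("seed", range(3))
def test_metric_monotonicity(seed):
    dose, mask = random_case(seed)
    thresholds = np.linspace(0, 85, 40)
    volumes = [volume_at_dose(dose, mask, t) for t in thresholds]
    assert np.all(np.diff(volumes) <= 1e-12)
    pcts = np.linspace(1, 100, 40)
    doses = [dose_at_volume(dose, mask, p) for p in pcts]
    assert np.all(np.diff(doses) <= 1e-12)
    assert volume_at_dose(dose, mask, 0.0) == 100.0


@pytest.mark.parametrize("seed", range(3))
def test_endpoints_invariant_to_voxel_order_and_zero_padding(seed):
    dose, mask = random_case(seed)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dose.values.size)
    dose_p = DoseGrid(dose.values.ravel()[perm].reshape(dose.shape), dose.spacing)
    mask_p = StructureMask("ROI", mask.mask.ravel()[perm].reshape(mask.mask.shape))
    # pad with zero-dose voxels outside the mask
    pad_vals = np.pad(dose.values, ((0, 2), (1, 0), (0, 3)))
    pad_mask = np.pad(mask.mask, ((0, 2), (1, 0), (0, 3)))
    dose_z = DoseGrid(pad_vals, dose.spacing)
    mask_z = StructureMask("ROI", pad_mask)
    for d, m in ((dose_p, mask_p), (dose_z, mask_z)):
        assert volume_at_dose(d, m, 40.0) == pytest.approx(volume_at_dose(dose, mask, 40.0))
        assert dose_at_volume(d, m, 98.0) == pytest.approx(dose_at_volume(dose, mask, 98.0))
        assert dose_at_cc(d, m, 0.05) == pytest.approx(dose_at_cc(dose, mask, 0.05))
        assert d.values[m.mask].max() == pytest.approx(dose.values[mask.mask].max())
        assert d.values[m.mask].mean() == pytest.approx(dose.values[mask.mask].mean())


# ------------------------------------------------------------- extraction


def test_extract_endpoints_uniform_prescription():
    shape = (8, 8, 8)
    ctv = np.zeros(shape, bool)
    ctv[2:6, 2:6, 2:6] = True
    values = np.where(ctv, 70.0, 0.0)
    dose = DoseGrid(values, (2.0, 2.0, 2.0))
    structures = [
        StructureMask("CTV-High", ctv, role="target"),
        StructureMask("Spinal Cord", ~ctv, role="oar"),  # fully outside the beam
    ]
    rx = Prescription({"CTV-High": 70.0})
    table = extract_endpoints(dose, structures, rx)
    assert table.loc["CTV-High", "V100"] == 100.0
    assert table.loc["CTV-High", "D98"] == pytest.approx(100.0)
    assert table.loc["CTV-High", "Dmax"] == pytest.approx(100.0)
    assert table.loc["Spinal Cord", "Dmean"] == 0.0
    assert table.loc["Spinal Cord", "D0.03cc"] == 0.0
    assert np.isnan(table.loc["CTV-High", "Dmean"])


def test_extract_endpoints_recovers_constructed_values():
    """Construction-by-inversion oracle: a dose built to hit requested
    endpoints is read back to those values within one voxel of volume."""
    from aptqa.synthetic import default_phantom_spec, dose_for_endpoints, make_phantom

    spec = default_phantom_spec()
    frame, masks = make_phantom(spec)
    target = masks["CTV-High"]
    requested_v100 = 92.5
    dose = dose_for_endpoints(
        frame,
        target,
        rx_level=70.0,
        v100_pct=requested_v100,
        oar_means={"Right Parotid": (masks["Right Parotid"], 21.5)},
    )
    table = extract_endpoints(
        dose, [target, masks["Right Parotid"]], Prescription({"CTV-High": 70.0})
    )
    half_voxel_pct = 100.0 / target.voxel_count
    assert table.loc["CTV-High", "V100"] == pytest.approx(requested_v100, abs=half_voxel_pct)
    assert table.loc["Right Parotid", "Dmean"] == pytest.approx(21.5)


def test_absent_structure_emits_missing_row():
    dose = DoseGrid(np.full((4, 4, 4), 10.0), (1.0, 1.0, 1.0))
    absent = StructureMask("CTV-Mid", np.zeros((4, 4, 4), bool), role="target")
    table = extract_endpoints(dose, [absent], Prescription({"CTV-Mid": 60.0}))
    assert table.loc["CTV-Mid"].isna().all()


def test_error_cases():
    dose, mask = random_case(0)
    empty = StructureMask("ROI", np.zeros(dose.shape, bool))
    with pytest.raises(StructureAbsentError):
        volume_at_dose(dose, empty, 10.0)
    wrong = StructureMask("ROI", np.ones((2, 2, 2), bool))
    with pytest.raises(CongruenceError):
        dose_at_volume(dose, wrong, 50.0)
    with pytest.raises(ValueError):
        dose_at_cc(dose, mask, mask.voxel_count * dose.voxel_volume_cc + 1.0)
    with pytest.raises(ValueError):
        dose_at_volume(dose, mask, 0.0)
    target = StructureMask("CTV-High", mask.mask, role="target")
    with pytest.raises(ValueError):
        extract_endpoints(dose, [target], Prescription({"CTV-Mid": 60.0}))
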