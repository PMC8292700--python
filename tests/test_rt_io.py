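"""Interchange round trips: DICOM-RT Plan/Dose, the log dialect, HDF5."""

import numpy as np
import pydicom
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import ARC_SECONDS
from vmatqa import (DeliveryLog, DoseGrid, JitterSpec, load_case, log_to_plan,
                    read_dose, read_log, read_rtplan, save_case,
                    simulate_delivery, write_dose, write_log, write_rtplan)
from vmatqa.exceptions import FormatError, ValidationError
from vmatqa.plan import ArcBeam, ControlPoint, VmatPlan, plans_equal


def _plan_with_weights(weights, meterset=100.0):
    la = np.round(np.linspace(-30.0, -10.0, 80), 6)
    lb = np.round(np.linspace(10.0, 30.0, 80), 6)
    jaws = np.array([-35.0, 35.0, -40.0, 40.0])
    cps = [ControlPoint(round(-180.0 + 360.0 * w, 6), 15.0,
                        np.round(la + w, 6), np.round(lb - w, 6), jaws,
                        round(w * meterset, 6))
           for w in weights]
    return VmatPlan(beams=[ArcBeam(control_points=cps, meterset_mu=meterset)])


class TestRtPlanRoundTrip:
    def test_three_point_plan_round_trips_bit_exactly(self, tmp_path):
        plan = _plan_with_weights([0.0, 0.5, 1.0])
        path = tmp_path / "plan.dcm"
        write_rtplan(plan, path)
        back = read_rtplan(path)
        assert back.n_control_points == 3
        assert np.array_equal(back.beams[0].weights, [0.0, 0.5, 1.0])
        assert plans_equal(plan, back)

    def test_hundred_point_plan_round_trips(self, tmp_path):
        w = np.round(np.linspace(0, 1, 100), 6)
        plan = _plan_with_weights(w)
        path = tmp_path / "plan.dcm"
        write_rtplan(plan, path)
        assert plans_equal(plan, read_rtplan(path))

    def test_synthetic_dual_arc_spans_full_gantry_range(self, tmp_path,
                                                        demo_plan):
        path = tmp_path / "demo.dcm"
        write_rtplan(demo_plan, path)
        back = read_rtplan(path)
        assert len(back.beams) == 2
        gantry = np.concatenate([b.gantry_deg for b in back.beams])
        assert gantry.min() == -180.0 and gantry.max() == 180.0
        assert plans_equal(demo_plan, back)

    def test_reconstructed_log_plan_round_trips_losslessly(self, tmp_path,
                                                           demo_plan):
        log = simulate_delivery(demo_plan, JitterSpec(seed=1), ARC_SECONDS)
        recon = log_to_plan(log, demo_plan)
        path = tmp_path / "recon.dcm"
        write_rtplan(recon, path)
        back = read_rtplan(path)
        assert back.n_control_points == len(log)
        assert plans_equal(recon, back)
        # leaf positions recovered to far better than a micrometre
        assert np.allclose(back.beams[0].leaves_a_mm,
                           recon.beams[0].leaves_a_mm, atol=1e-3)

    def test_missing_mlc_sequence_is_a_format_error(self, tmp_path):
        plan = _plan_with_weights([0.0, 1.0])
        path = tmp_path / "nomlc.dcm"
        write_rtplan(plan, path)
        ds = pydicom.dcmread(path)
        for beam in ds.BeamSequence:
            beam.BeamLimitingDeviceSequence = [
                b for b in beam.BeamLimitingDeviceSequence
                if b.RTBeamLimitingDeviceType != "MLCX"]
        ds.save_as(path, enforce_file_format=True)
        with pytest.raises(FormatError):
            read_rtplan(path)

    def test_non_monotonic_meterset_is_a_validation_error(self, tmp_path):
        plan = _plan_with_weights([0.0, 0.5, 1.0])
        path = tmp_path / "bad.dcm"
        write_rtplan(plan, path)
        ds = pydicom.dcmread(path)
        cps = ds.BeamSequence[0].ControlPointSequence
        cps[1].CumulativeMetersetWeight = "80.0"
        cps[2].CumulativeMetersetWeight = "50.0"
        ds.save_as(path, enforce_file_format=True)
        with pytest.raises(ValidationError):
            read_rtplan(path)

    def test_non_dicom_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "junk.dcm"
        path.write_text("not dicom at all")
        with pytest.raises(FormatError):
            read_rtplan(path)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_randomized_plans_round_trip(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        w = np.round(np.sort(np.concatenate(
            [[0.0, 1.0], rng.uniform(0, 1, n - 2)])), 6)
        plan = _plan_with_weights(w, meterset=float(rng.integers(50, 900)))
        path = tmp_path_factory.mktemp("rt") / "r.dcm"
        write_rtplan(plan, path)
        assert plans_equal(plan, read_rtplan(path))


class TestRtDoseRoundTrip:
    def test_uniform_grid_quantization_bound(self, tmp_path):
        grid = DoseGrid(dose=np.full((10, 12, 8), 2.0), spacing_mm=3.0,
                        origin_mm=np.zeros(3))
        path = tmp_path / "dose.dcm"
        write_dose(grid, path)
        back = read_dose(path)
        assert np.abs(back.dose - grid.dose).max() < 1e-4
        # the clinical verification grid spacing survives exactly
        assert np.array_equal(back.spacing_mm, [3.0, 3.0, 3.0])
        assert np.array_equal(back.origin_mm, grid.origin_mm)

    def test_computed_dose_round_trips_with_label(self, tmp_path, demo_dose):
        path = tmp_path / "d.dcm"
        write_dose(demo_dose, path)
        back = read_dose(path)
        assert np.abs(back.dose - demo_dose.dose).max() < 1e-6
        assert back.uncertainty_label == demo_dose.uncertainty_label

    def test_empty_grid_is_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            DoseGrid(dose=np.zeros((0, 0, 0)), spacing_mm=3.0,
                     origin_mm=np.zeros(3))

    def test_non_uniform_slice_spacing_is_a_format_error(self, tmp_path):
        grid = DoseGrid(dose=np.ones((4, 4, 4)), spacing_mm=3.0,
                        origin_mm=np.zeros(3))
        path = tmp_path / "dose.dcm"
        write_dose(grid, path)
        ds = pydicom.dcmread(path)
        ds.GridFrameOffsetVector = ["0.0", "3.0", "7.0", "9.0"]
        ds.save_as(path, enforce_file_format=True)
        with pytest.raises(FormatError):
            read_dose(path)


class TestLogDialect:
    def test_simulated_log_round_trips_losslessly(self, tmp_path, demo_plan):
        log = simulate_delivery(demo_plan, JitterSpec(seed=7), ARC_SECONDS)
        path = tmp_path / "delivery.log"
        write_log(log, path)
        back = read_log(path)
        assert len(back) == len(log)
        assert back.rate_hz == 4.0
        for attr in ("time_s", "gantry_deg", "collimator_deg", "mu",
                     "jaws_mm", "leaves_a_mm", "leaves_b_mm"):
            assert np.array_equal(getattr(back, attr), getattr(log, attr)), attr

    def test_empty_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "empty.log"
        path.write_text("")
        with pytest.raises(FormatError):
            read_log(path)

    def test_decreasing_mu_is_a_validation_error(self, tmp_path, demo_plan):
        log = simulate_delivery(demo_plan, JitterSpec.zero(), ARC_SECONDS)
        path = tmp_path / "bad.log"
        write_log(log, path)
        text = path.read_text().splitlines()
        header_rows = 5  # metadata + column header
        row = text[header_rows + 10].split(",")
        row[3] = "-1.0"
        text[header_rows + 10] = ",".join(row)
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(ValidationError):
            read_log(path)

    def test_tolerance_metadata_survives(self, tmp_path, demo_plan):
        log = simulate_delivery(demo_plan, JitterSpec.zero(), ARC_SECONDS,
                                leaf_tolerance_mm=1.5,
                                gantry_tolerance_deg=0.7)
        path = tmp_path / "meta.log"
        write_log(log, path)
        back = read_log(path)
        assert back.leaf_tolerance_mm == 1.5
        assert back.gantry_tolerance_deg == 0.7


class TestFixtureContainer:
    def test_full_case_round_trips(self, tmp_path, phantom, structures,
                                   demo_plan, demo_dose):
        path = tmp_path / "case.h5"
        save_case(path, phantom=phantom, structures=structures,
                  plan=demo_plan, dose=demo_dose)
        case = load_case(path)
        assert np.array_equal(case["phantom"].density, phantom.density)
        assert set(case["structures"].masks) == set(structures.masks)
        assert np.array_equal(case["structures"].masks["PTV"],
                              structures.masks["PTV"])
        assert plans_equal(case["plan"], demo_plan)
        assert np.array_equal(case["dose"].dose, demo_dose.dose)

    def test_partial_case(self, tmp_path, phantom):
        path = tmp_path / "partial.h5"
        save_case(path, phantom=phantom)
        case = load_case(path)
        assert list(case) == ["phantom"]
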