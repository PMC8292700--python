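"""Gamma analysis, DVH curves and Dx/Vx metric operations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vmatqa import (DoseGrid, GammaCriteria, MetricSpec, dvh, dvh_metric,
                    gamma_index, metric_difference, passing_rate)
from vmatqa.exceptions import UndefinedResultError, ValidationError


def _grid(arr, spacing=2.0, origin=(0.0, 0.0, 0.0)):
    return DoseGrid(dose=np.asarray(arr, dtype=float), spacing_mm=spacing,
                    origin_mm=np.asarray(origin, dtype=float))


def _smooth_field(rng, shape, spacing=2.0, level=2.0):
    from scipy.ndimage import gaussian_filter
    base = gaussian_filter(rng.normal(0.0, 1.0, shape), 2.0)
    base = level * (0.4 + 0.6 * (base - base.min())
                    / max(float(np.ptp(base)), 1e-9))
    return _grid(base, spacing=spacing)


class TestGammaIndex:
    def test_identical_grids_give_zero_gamma_and_full_pass(self, rng):
        ref = _smooth_field(rng, (9, 9, 5))
        gmap = gamma_index(ref, ref)
        assert np.nanmax(gmap.gamma) < 1e-9
        assert passing_rate(gmap) == 100.0

    def test_uniform_three_percent_offset_gives_gamma_1p5(self):
        ref = _grid(np.full((7, 7, 4), 1.000))
        ev = _grid(np.full((7, 7, 4), 1.030))
        gmap = gamma_index(ref, ev, GammaCriteria(dose_pct=2.0, dta_mm=1.0,
                                                  threshold_pct=20.0))
        # a uniform offset has no spatial remedy: gamma = 3% / 2% everywhere
        assert np.allclose(gmap.gamma[gmap.mask], 1.5, atol=1e-9)
        assert passing_rate(gmap) == 0.0

    def test_scaling_both_grids_leaves_gamma_unchanged(self, rng):
        ref = _smooth_field(rng, (8, 8, 4))
        ev = _grid(ref.dose * (1 + 0.015 * rng.standard_normal(ref.dose.shape)))
        g1 = gamma_index(ref, ev)
        ref2 = _grid(ref.dose * 3.7)
        ev2 = _grid(ev.dose * 3.7)
        g2 = gamma_index(ref2, ev2)
        assert np.allclose(g1.gamma[g1.mask], g2.gamma[g2.mask], atol=1e-9)

    @pytest.mark.parametrize("loosen", [
        # wider dose criterion, identical probe lattice
        dict(dose_pct=3.0),
        # wider DTA at the same 0.1 mm probe step (step_factor halved), so
        # the loose search lattice contains the tight one; monotonicity of
        # the minimum is then exact, matching the continuum property
        dict(dta_mm=2.0, step_factor=0.05),
    ])
    def test_looser_criteria_never_raise_gamma(self, rng, loosen):
        ref = _smooth_field(rng, (8, 8, 4))
        ev = _grid(np.roll(ref.dose, 1, axis=0)
                   * (1 + 0.01 * rng.standard_normal(ref.dose.shape)))
        tight = gamma_index(ref, ev, GammaCriteria())
        loose = gamma_index(ref, ev, GammaCriteria(**loosen))
        assert np.all(loose.gamma[loose.mask]
                      <= tight.gamma[tight.mask] + 1e-9)

    def test_low_dose_failure_is_excluded_by_threshold(self):
        ref = np.full((6, 6, 4), 2.0)
        ev = np.full((6, 6, 4), 2.0)
        ref[0, :, :] = 0.1           # below 20% of 2 Gy
        ev[0, :, :] = 0.3            # grossly wrong, but sub-threshold
        gmap = gamma_index(_grid(ref), _grid(ev))
        assert not gmap.mask[0].any()
        assert passing_rate(gmap) == 100.0

    def test_disjoint_grids_raise(self):
        a = _grid(np.ones((4, 4, 4)), origin=(0, 0, 0))
        b = _grid(np.ones((4, 4, 4)), origin=(1000, 1000, 1000))
        with pytest.raises(ValidationError):
            gamma_index(a, b)

    def test_prescription_normalization_requires_dose(self):
        ref = _grid(np.ones((4, 4, 4)))
        with pytest.raises(ValidationError):
            gamma_index(ref, ref,
                        GammaCriteria(normalization="prescription"))


class TestPassingRate:
    def test_half_pass_half_fail_gives_fifty_percent(self):
        ref = _grid(np.ones((4, 4, 4)))
        gmap = gamma_index(ref, ref)
        gmap.gamma[:2] = 0.5
        gmap.gamma[2:] = 2.0
        assert passing_rate(gmap) == 50.0

    def test_roi_restriction_and_empty_intersection(self):
        ref = _grid(np.ones((4, 4, 4)))
        gmap = gamma_index(ref, ref)
        roi = np.zeros((4, 4, 4), dtype=bool)
        roi[0, 0, 0] = True
        assert passing_rate(gmap, roi) == 100.0
        with pytest.raises(UndefinedResultError):
            passing_rate(gmap, np.zeros((4, 4, 4), dtype=bool))


class TestDvh:
    def test_uniform_dose_step_curve(self):
        dose = _grid(np.full((5, 5, 2), 2.0))
        mask = np.ones((5, 5, 2), dtype=bool)
        curve = dvh(dose, mask, bin_width_gy=0.1)
        assert curve.volume_pct[0] == 100.0
        assert np.interp(1.95, curve.dose_gy, curve.volume_pct) == 100.0
        assert curve.volume_pct[-1] == 0.0
        assert np.all(np.diff(curve.volume_pct) <= 0)

    def test_two_level_curve_midpoint(self):
        arr = np.full((4, 4, 2), 1.0)
        arr[:2] = 2.0
        curve = dvh(_grid(arr), np.ones_like(arr, dtype=bool),
                    bin_width_gy=0.01)
        v_at = np.interp(1.5, curve.dose_gy, curve.volume_pct)
        assert v_at == pytest.approx(50.0, abs=1e-9)

    def test_empty_roi_raises(self):
        dose = _grid(np.ones((3, 3, 3)))
        with pytest.raises(ValidationError):
            dvh(dose, np.zeros((3, 3, 3), dtype=bool))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_curve_non_increasing_for_random_doses(self, seed):
        r = np.random.default_rng(seed)
        arr = r.uniform(0, 3, size=(6, 6, 3))
        curve = dvh(_grid(arr), np.ones_like(arr, dtype=bool))
        assert np.all(np.diff(curve.volume_pct) <= 0)


class TestDvhMetrics:
    def _two_level(self):
        arr = np.full((4, 4, 2), 1.0)
        arr[:2] = 2.0
        return _grid(arr), np.ones_like(arr, dtype=bool)

    def test_two_level_analytic_values(self):
        dose, mask = self._two_level()
        assert dvh_metric((dose, mask), MetricSpec("Dmean")) == 1.5
        assert dvh_metric((dose, mask), MetricSpec("Dx", x=2)) == 2.0
        assert dvh_metric((dose, mask), MetricSpec("Dx", x=98)) == 1.0

    def test_uniform_vx_values(self):
        dose = _grid(np.full((4, 4, 2), 2.0))
        mask = np.ones((4, 4, 2), dtype=bool)
        v95 = MetricSpec("Vx", x=95, prescription_gy=2.0)
        v107 = MetricSpec("Vx", x=107, prescription_gy=2.0)
        assert dvh_metric((dose, mask), v95) == 100.0
        assert dvh_metric((dose, mask), v107) == 0.0

    def test_curve_and_voxel_routes_agree_within_one_bin(self, rng):
        arr = rng.uniform(0.5, 2.5, size=(8, 8, 4))
        mask = rng.uniform(size=arr.shape) < 0.6
        grid = _grid(arr)
        curve = dvh(grid, mask, bin_width_gy=0.01)
        for x in (2, 50, 98):
            spec = MetricSpec("Dx", x=x)
            direct = dvh_metric((grid, mask), spec)
            from_curve = dvh_metric(curve, spec)
            assert abs(direct - from_curve) <= 0.01 + 1e-12

    def test_metrics_invariant_under_voxel_permutation(self, rng):
        arr = rng.uniform(0, 3, size=(6, 6, 2))
        mask = np.ones_like(arr, dtype=bool)
        perm = rng.permutation(arr.size).reshape(arr.shape)
        shuffled = arr.ravel()[perm.ravel()].reshape(arr.shape)
        for spec in (MetricSpec("Dmean"), MetricSpec("Dmax"),
                     MetricSpec("Dx", x=30),
                     MetricSpec("Vx", x=50, prescription_gy=2.0)):
            assert dvh_metric((_grid(arr), mask), spec) == pytest.approx(
                dvh_metric((_grid(shuffled), mask), spec), rel=1e-12)

    def test_vx_without_prescription_raises(self):
        dose, mask = self._two_level()
        with pytest.raises(ValidationError):
            dvh_metric((dose, mask), MetricSpec("Vx", x=95))

    def test_spec_parsing_and_validation(self):
        assert MetricSpec.parse("D15").kind == "Dx"
        assert MetricSpec.parse("V95").x == 95.0
        assert MetricSpec.parse("Dmean").kind == "Dmean"
        with pytest.raises(ValidationError):
            MetricSpec("Dx", x=0)
        with pytest.raises(ValidationError):
            MetricSpec.parse("Q15")


class TestMetricDifference:
    def test_sign_convention_matches_under_and_over_delivery(self):
        assert metric_difference(2.0, 2.0, 2.0) == 0.0
        # under-delivery (closing-type error) is positive
        assert metric_difference(2.0, 1.925, 2.0) == pytest.approx(3.75)
        # over-delivery (opening-type error) is negative
        assert metric_difference(2.0, 2.0466, 2.0) == pytest.approx(-2.33)

    def test_zero_normalization_raises(self):
        with pytest.raises(UndefinedResultError):
            metric_difference(1.0, 1.0, 0.0)
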