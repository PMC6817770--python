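"""Morphometric estimators against analytic and construction oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselmorph import (
    DomainError,
    MeasurementError,
    PixelCalibration,
    SegmentedVessel,
    SyntheticVesselSpec,
    compute_areas,
    equivalent_diameter,
    make_vessel,
    mean_wall_thickness,
    measure,
)
from vesselmorph.morphometry import _distance_transform_thickness

from conftest import rectangular_vessel


class TestAreas:
    def test_pixel_counting(self):
        labels = np.zeros((8, 8), dtype=np.uint8)
        labels[3:5, 3:5] = 1  # 4 lumen px
        labels[2:6, 2:6][labels[2:6, 2:6] == 0] = 2  # 12 wall px
        v = SegmentedVessel("counts", labels, PixelCalibration(0.5))
        assert compute_areas(v) == (1.0, 3.0)

    def test_annulus_areas_within_one_percent(self, annulus_5_8):
        vessel, _ = annulus_5_8
        lumen, wall = compute_areas(vessel)
        assert lumen == pytest.approx(math.pi * 25, rel=0.01)
        assert wall == pytest.approx(math.pi * 39, rel=0.01)

    def test_calibration_rescaling_scales_areas_not_ratio(self, annulus_1_2):
        vessel, _ = annulus_1_2
        k = 3.0
        rescaled = SegmentedVessel(
            vessel.vessel_id, vessel.labels,
            PixelCalibration(vessel.calibration.microns_per_pixel * k),
        )
        a0 = compute_areas(vessel)
        a1 = compute_areas(rescaled)
        assert a1[0] == pytest.approx(a0[0] * k * k, rel=1e-12)
        assert a1[1] == pytest.approx(a0[1] * k * k, rel=1e-12)
        assert a1[0] / a1[1] == pytest.approx(a0[0] / a0[1], rel=1e-12)

    def test_missing_compartment_is_an_error(self):
        labels = np.zeros((6, 6), dtype=np.uint8)
        labels[2:4, 2:4] = 1
        v = SegmentedVessel("nowall", labels, PixelCalibration(0.1))
        with pytest.raises(MeasurementError, match="no wall"):
            compute_areas(v)

    def test_label_counts_conserve_grid(self, annulus_5_8):
        vessel, _ = annulus_5_8
        counts = vessel.label_counts()
        assert sum(counts.values()) == vessel.labels.size


class TestEquivalentDiameter:
    def test_unit_circle(self):
        assert equivalent_diameter(math.pi) == pytest.approx(2.0, rel=1e-12)

    def test_ellipse_closed_form(self):
        # lumen of a 2x1 ellipse has area 2π and equivalent diameter 2√2
        assert equivalent_diameter(2 * math.pi) == pytest.approx(2 * math.sqrt(2), rel=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1e4))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_doubling_area_scales_diameter_by_sqrt2(self, area):
        assert equivalent_diameter(2 * area) == pytest.approx(
            equivalent_diameter(area) * math.sqrt(2), rel=1e-9
        )

    def test_nonpositive_area_rejected(self):
        with pytest.raises(DomainError):
            equivalent_diameter(0.0)


class TestWallThickness:
    def test_constant_ring(self, annulus_1_2):
        vessel, _ = annulus_1_2
        t, method, frac = mean_wall_thickness(vessel)
        assert method == "ray_mean"
        assert t == pytest.approx(1.0, rel=0.02)
        assert frac == 1.0

    def test_elliptical_lumen_constant_wall_matches_truth(self):
        spec = SyntheticVesselSpec(lumen_semi_axes=(4.0, 2.0), wall_thickness_base=0.5)
        vessel, truth = make_vessel(spec, 0.02, 560)
        t, _, _ = mean_wall_thickness(vessel)
        assert t == pytest.approx(truth.true_mean_thickness, rel=0.05)

    def test_modulated_wall_mean_matches_truth(self):
        spec = SyntheticVesselSpec(
            lumen_semi_axes=(3.0, 3.0), wall_thickness_base=1.0,
            thickness_modulation=0.5, thickness_order=1,
        )
        vessel, truth = make_vessel(spec, 0.02, 560)
        t, _, _ = mean_wall_thickness(vessel)
        assert truth.true_mean_thickness == pytest.approx(1.0, rel=1e-12)
        assert t == pytest.approx(1.0, rel=0.05)

    def test_quarter_rotation_changes_estimate_under_one_percent(self):
        base = dict(
            lumen_semi_axes=(4.0, 2.5), wall_thickness_base=1.0,
            thickness_modulation=0.2, thickness_order=2,
        )
        v0, _ = make_vessel(SyntheticVesselSpec(**base, rotation=0.0), 0.05, 300)
        v90 = SegmentedVessel(
            "rot90", np.rot90(v0.labels).copy(), v0.calibration
        )
        t0, _, _ = mean_wall_thickness(v0)
        t90, _, _ = mean_wall_thickness(v90)
        assert abs(t90 - t0) / t0 < 0.01

    def test_distance_transform_agrees_on_circular_ring(self, annulus_1_2):
        vessel, _ = annulus_1_2
        assert _distance_transform_thickness(vessel) == pytest.approx(1.0, rel=0.05)

    def test_crescent_lumen_falls_back_to_distance_transform(self):
        """A C-shaped lumen puts its centroid outside itself."""
        h = w = 120
        yy, xx = np.mgrid[:h, :w]
        cy = cx = 60.0
        rr = np.hypot(yy - cy, xx - cx)
        ang = np.arctan2(yy - cy, xx - cx)
        ring = (rr > 25) & (rr < 40)
        lumen = ring & (np.cos(ang) < 0.55)  # open the ring into a crescent
        shell = (rr >= 15) & (rr <= 50)
        labels = np.zeros((h, w), dtype=np.uint8)
        labels[shell] = 2
        labels[lumen] = 1
        v = SegmentedVessel("crescent", labels, PixelCalibration(0.1))
        with pytest.warns(UserWarning, match="falling back|distance-transform"):
            t, method, _ = mean_wall_thickness(v)
        assert method == "distance_transform"
        assert t > 0

    def test_too_few_rays_rejected(self, annulus_1_2):
        with pytest.raises(DomainError):
            mean_wall_thickness(annulus_1_2[0], n_rays=4)


class TestMeasure:
    def test_annulus_record_closed_forms(self, annulus_1_2):
        rec = measure(annulus_1_2[0])
        assert rec.area_ratio == pytest.approx(1 / 3, rel=0.01)
        assert rec.diameter_ratio == pytest.approx(2.0, rel=0.02)
        assert rec.total_area == pytest.approx(rec.lumen_area + rec.wall_area, abs=1e-9)

    def test_exclusion_boundary_is_strict_less_than(self):
        # total areas: 69.90, 70.00 and 250.00 μm² at 0.1 μm/px
        just_below = rectangular_vessel((40, 60), (70, 100), 0.1,
                                        vessel_id="below", trim_wall_px=10)
        exactly_at = rectangular_vessel((40, 60), (70, 100), 0.1, vessel_id="at")
        well_above = rectangular_vessel((80, 120), (125, 200), 0.1, vessel_id="above")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records = [measure(v) for v in (just_below, exactly_at, well_above)]
        assert [r.total_area for r in records] == pytest.approx([69.9, 70.0, 250.0])
        assert [r.excluded for r in records] == [True, False, False]
        assert records[0].exclusion_reason == "too_small"

    def test_exclusion_priority_pathology_then_plane_then_size(self, annulus_1_2):
        vessel, _ = annulus_1_2  # total area ~12.6 μm², under the floor
        small = measure(vessel)
        assert small.exclusion_reason == "too_small"
        oblique = SegmentedVessel(
            "o", vessel.labels, vessel.calibration, transverse_plane=False
        )
        assert measure(oblique).exclusion_reason == "not_transverse"
        sick = SegmentedVessel(
            "p", vessel.labels, vessel.calibration,
            transverse_plane=False, pathology_flag=True,
        )
        assert measure(sick).exclusion_reason == "pathology"

    def test_excluded_vessels_still_carry_measurements(self, annulus_1_2):
        rec = measure(annulus_1_2[0])
        assert rec.excluded
        assert rec.area_ratio > 0 and rec.diameter_ratio > 0

    def test_growing_wall_decreases_area_ratio(self):
        ratios = []
        for wall in (0.5, 1.0, 2.0, 3.0):
            spec = SyntheticVesselSpec(lumen_semi_axes=(4.0, 4.0),
                                       wall_thickness_base=wall)
            _, truth = make_vessel(spec, 0.1, 260)
            ratios.append(truth.true_area_ratio)
        assert ratios == sorted(ratios, reverse=True)

    def test_feret_diameters_bracket_equivalent_diameter(self):
        spec = SyntheticVesselSpec(lumen_semi_axes=(4.0, 2.0), wall_thickness_base=1.0)
        vessel, _ = make_vessel(spec, 0.05, 300)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_eq = measure(vessel, diameter_method="equivalent")
            r_max = measure(vessel, diameter_method="feret_max")
            r_min = measure(vessel, diameter_method="feret_min")
        assert r_max.equiv_diameter == pytest.approx(8.0, rel=0.03)
        assert r_min.equiv_diameter == pytest.approx(4.0, rel=0.05)
        assert r_min.equiv_diameter < r_eq.equiv_diameter < r_max.equiv_diameter

    def test_measured_values_recover_generator_truth(self, default_measurements):
        """Oracle equivalence on the default population.

        Areas recover within 1 %.  The ray estimator averages about the
        lumen centroid while the truth averages about the construction
        centre, so strongly eccentric walls (large thickness modulation)
        shift the angular weighting: near-uniform walls recover within
        5 %, heavily modulated ones within 12 %.
        """
        for rec, truth in default_measurements:
            assert rec.lumen_area == pytest.approx(truth.true_lumen_area, rel=0.01)
            assert rec.wall_area == pytest.approx(truth.true_wall_area, rel=0.01)
            tol = 0.05 if truth.spec.thickness_modulation < 0.25 else 0.12
            assert rec.mean_thickness == pytest.approx(
                truth.true_mean_thickness, rel=tol
            )
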