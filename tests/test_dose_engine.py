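"""WEPL tracing, aperture/compensator design, and broad-beam dose assembly."""

import numpy as np
import pytest

from protonmotion.beam_model import DEPTH_STEP_CM, find_distal_90
from protonmotion.dose_engine import (
    BeamGeometry,
    compute_field_dose,
    compute_plan_dose,
    design_aperture,
    design_compensator,
    fit_field,
    trace_wepl,
)
from protonmotion.errors import (
    GeometryError,
    InfeasibleCompensatorError,
    UnsupportedGeometryError,
)
from protonmotion.volumes import RSPVolume


def water(shape=(48, 48, 48), spacing=2.0, rsp=1.0):
    return RSPVolume(np.full(shape, float(rsp)), (spacing,) * 3)


def box_ptv(shape, lo, hi):
    m = np.zeros(shape, bool)
    m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return m


def brute_force_wepl(rsp: RSPVolume, geometry: BeamGeometry, idx, step_cm=0.01):
    """March a ray in 0.1 mm steps from the entry face to the voxel center."""
    axis, direction = geometry.axis, geometry.direction
    sp = rsp.spacing_cm[axis]
    n = rsp.shape[axis]
    if direction > 0:
        target = (idx[axis] + 0.5) * sp
        def voxel_at(t):
            return int(t / sp)
    else:
        target = (n - idx[axis] - 0.5) * sp
        def voxel_at(t):
            return n - 1 - int(t / sp)
    total, t = 0.0, 0.0
    while t < target:
        dt = min(step_cm, target - t)
        j = list(idx)
        j[axis] = min(voxel_at(t + dt / 2), n - 1)
        total += rsp.values[tuple(j)] * dt
        t += dt
    return total


class TestTraceWepl:
    def test_water_identity(self):
        rsp = water((10, 10, 10), spacing=2.0)
        w = trace_wepl(rsp, BeamGeometry(0))
        # voxel centers at 0.1, 0.3, ... cm
        assert np.allclose(w[3, :, :], 0.7)

    def test_two_slab_phantom(self):
        vals = np.full((100, 4, 4), 0.3)
        vals[50:] = 1.05
        rsp = RSPVolume(vals, (1.0, 1.0, 1.0))
        w = trace_wepl(rsp, BeamGeometry(0))
        # center of voxel 99 sits at depth 9.95 cm: 5*0.3 + 4.95*1.05
        assert w[99, 0, 0] == pytest.approx(5 * 0.3 + 4.95 * 1.05, abs=1e-9)

    def test_matches_fine_step_ray_marcher(self, rng):
        rsp = RSPVolume(rng.uniform(0.05, 1.8, (32, 32, 32)), (2.0, 2.0, 2.0))
        for angle in (0, 180, 90, 270):
            g = BeamGeometry(angle)
            w = trace_wepl(rsp, g)
            for idx in [(3, 7, 11), (16, 16, 16), (30, 2, 25), (0, 31, 5)]:
                oracle = brute_force_wepl(rsp, g, idx)
                assert w[idx] == pytest.approx(oracle, rel=0.01, abs=1e-3)

    def test_monotone_along_rays(self, rng):
        rsp = RSPVolume(rng.uniform(0.0, 2.0, (16, 16, 16)), (2.0, 2.0, 2.0))
        w = trace_wepl(rsp, BeamGeometry(180))
        assert np.all(np.diff(np.flip(w, axis=0), axis=0) >= -1e-12)

    def test_unsupported_angle(self):
        with pytest.raises(UnsupportedGeometryError):
            BeamGeometry(45)


class TestAperture:
    def test_sphere_projection_with_margin_matches_disk_area(self):
        shape, sp = (48, 48, 48), 2.0
        x, y, z = np.indices(shape) * sp
        ptv = (x - 48) ** 2 + (y - 48) ** 2 + (z - 48) ** 2 <= 20**2
        rsp = water(shape, sp)
        ap = design_aperture(ptv, BeamGeometry(0), rsp, margin_cm=1.0)
        area_cm2 = ap.sum() * (sp / 10) ** 2
        assert area_cm2 == pytest.approx(np.pi * 3.0**2, rel=0.05)

    def test_zero_margin_is_projection(self):
        ptv = box_ptv((12, 12, 12), (4, 4, 4), (8, 8, 8))
        rsp = water((12, 12, 12))
        ap = design_aperture(ptv, BeamGeometry(0), rsp, margin_cm=0.0)
        assert np.array_equal(ap, ptv.any(axis=0))

    def test_aperture_contains_projection(self, rng):
        ptv = rng.random((16, 16, 16)) > 0.9
        ptv[8, 8, 8] = True
        rsp = water((16, 16, 16))
        ap = design_aperture(ptv, BeamGeometry(90), rsp, margin_cm=1.0)
        assert np.all(ap | ~ptv.any(axis=1))


class TestCompensator:
    def test_flat_distal_face_gives_uniform_thickness(self):
        shape = (60, 20, 20)
        rsp = water(shape, 2.0)
        ptv = box_ptv(shape, (20, 5, 5), (50, 15, 15))  # distal exit at 10 cm
        comp = design_compensator(ptv, rsp, BeamGeometry(0), R=12.0)
        proj = ptv.any(axis=0)
        assert np.allclose(comp[proj], 2.0, atol=1e-9)

    def test_stepped_distal_face_steps_in_thickness(self):
        shape = (60, 20, 20)
        rsp = water(shape, 2.0)
        ptv = box_ptv(shape, (20, 2, 2), (50, 18, 18))
        ptv[50:55, 2:10, 2:18] = True  # one half extends to 11 cm
        comp = design_compensator(ptv, rsp, BeamGeometry(0), R=12.0)
        assert np.allclose(comp[3, 5], 1.0, atol=1e-6)
        assert np.allclose(comp[15, 5], 2.0, atol=1e-6)

    def test_compensated_rays_sum_to_range(self, small_study):
        # per-ray WEPL at the distal PTV surface plus thickness equals R
        from protonmotion.ct_ops import hu_to_rsp
        from protonmotion.dose_engine import _surface_wepl

        plan = small_study.plans["AVG"]
        rsp = hu_to_rsp(plan.planning_volume)
        for field in plan.fields:
            _, distal, rays = _surface_wepl(
                plan.structures.ptv, rsp, field.geometry
            )
            residual = distal[rays] + field.compensator[rays]
            assert np.allclose(residual, field.distal_range_cm, atol=1e-6)

    def test_too_small_range_is_infeasible(self):
        shape = (60, 20, 20)
        rsp = water(shape, 2.0)
        ptv = box_ptv(shape, (20, 5, 5), (50, 15, 15))
        with pytest.raises(InfeasibleCompensatorError):
            design_compensator(ptv, rsp, BeamGeometry(0), R=9.0)


class TestFitField:
    def test_water_box(self):
        shape = (60, 24, 24)
        rsp = water(shape, 2.0)
        ptv = box_ptv(shape, (30, 8, 8), (60 - 0, 16, 16))
        ptv = box_ptv(shape, (30, 8, 8), (60, 16, 16))
        # box spans depths 6..12 cm for a beam entering at index 0
        field = fit_field(ptv, rsp, BeamGeometry(0))
        assert field.distal_range_cm == pytest.approx(12.0, abs=0.1)
        assert field.modulation_cm == pytest.approx(6.0, abs=0.15)

    def test_water_sphere(self):
        shape, sp = (70, 48, 48), 2.0
        x, y, z = np.indices(shape) * sp
        ptv = (x - 100) ** 2 + (y - 48) ** 2 + (z - 48) ** 2 <= 20**2
        rsp = water(shape, sp)
        field = fit_field(ptv, rsp, BeamGeometry(0))
        # sphere of diameter 4 cm centred at depth 10 cm
        assert field.distal_range_cm == pytest.approx(12.0, abs=0.25)
        assert field.modulation_cm == pytest.approx(4.0, abs=0.3)

    def test_upstream_slab_shifts_range_not_modulation(self):
        shape = (70, 24, 24)
        vals = np.ones(shape)
        ptv = box_ptv(shape, (30, 8, 8), (55, 16, 16))
        f0 = fit_field(ptv, RSPVolume(vals.copy(), (2.0,) * 3), BeamGeometry(0))
        vals[:5] = 2.0  # adds 1 cm WEPL upstream of the target
        f1 = fit_field(ptv, RSPVolume(vals, (2.0,) * 3), BeamGeometry(0))
        assert f1.distal_range_cm - f0.distal_range_cm == pytest.approx(1.0, abs=0.02)
        assert f1.modulation_cm == pytest.approx(f0.modulation_cm, abs=0.02)

    def test_empty_ptv_rejected(self):
        with pytest.raises(GeometryError):
            fit_field(np.zeros((8, 8, 8), bool), water((8, 8, 8)), BeamGeometry(0))


class TestFieldDose:
    def test_on_axis_matches_sobp_curve(self, water_field):
        field, rsp = water_field
        dose = compute_field_dose(field, rsp)
        depths_cm = (np.arange(80) + 0.5) * 0.2
        comp = field.compensator[12, 12]
        expected = 100 * field.sobp_curve(depths_cm + comp)
        assert np.allclose(dose.values[:, 12, 12], expected, rtol=0.01, atol=0.1)

    def test_zero_outside_aperture(self, water_field):
        field, rsp = water_field
        dose = compute_field_dose(field, rsp)
        outside = ~field.aperture
        assert np.all(dose.values[:, outside] == 0.0)

    def test_weight_linearity(self, water_field):
        field, rsp = water_field
        from dataclasses import replace

        half = replace(field, weight=0.5)
        d1 = compute_field_dose(field, rsp)
        d2 = compute_field_dose(half, rsp)
        assert np.allclose(d1.values, 2 * d2.values)

    def test_distal_90_conforms_to_ptv_surface(self, water_field):
        # the design goal: the per-ray 90% depth sits at the distal PTV
        # surface (within a voxel) in a static homogeneous phantom
        field, rsp = water_field
        dose = compute_field_dose(field, rsp)
        for jk in [(12, 12), (9, 14), (15, 9)]:
            profile = dose.values[:, jk[0], jk[1]]
            above = np.where(profile >= 0.9 * profile.max())[0]
            distal_depth_cm = (above.max() + 1) * 0.2
            assert distal_depth_cm == pytest.approx(11.0, abs=0.21)

    def test_density_scaling_shrinks_range(self, water_field):
        field, rsp = water_field
        denser = rsp.with_values(rsp.values * 1.05)
        d0 = compute_field_dose(field, rsp).values[:, 12, 12]
        d1 = compute_field_dose(field, denser).values[:, 12, 12]
        def distal_idx(p):
            return np.where(p >= 0.9 * p.max())[0].max()
        shrink = (distal_idx(d0) - distal_idx(d1) + 0.5) * 0.2
        expected = field.distal_range_cm * (1 - 1 / 1.05)
        assert shrink == pytest.approx(expected, abs=0.25)


class TestPlanDose:
    def test_single_field_identity(self, water_field_pair):
        field, rsp = water_field_pair
        from dataclasses import replace

        f = replace(field, weight=1.0)
        assert np.allclose(
            compute_plan_dose([f], rsp).values,
            compute_field_dose(f, rsp).values,
        )

    def test_opposed_fields_symmetric(self):
        shape = (60, 24, 24)
        rsp = water(shape, 2.0)
        ptv = box_ptv(shape, (24, 8, 8), (36, 16, 16))
        from dataclasses import replace

        f0 = replace(fit_field(ptv, rsp, BeamGeometry(0)), weight=0.5)
        f180 = replace(fit_field(ptv, rsp, BeamGeometry(180)), weight=0.5)
        dose = compute_plan_dose([f0, f180], rsp)
        assert np.allclose(dose.values, np.flip(dose.values, axis=0), atol=0.2)

    def test_sum_matches_brute_force_accumulation(self, water_field_pair):
        field, rsp = water_field_pair
        from dataclasses import replace

        fields = [replace(field, weight=0.5), replace(field, weight=0.5)]
        total = compute_plan_dose(fields, rsp)
        brute = sum(compute_field_dose(f, rsp).values for f in fields)
        assert np.allclose(total.values, brute)

    def test_weight_sum_enforced(self, water_field_pair):
        field, rsp = water_field_pair
        from dataclasses import replace

        with pytest.raises(ValueError):
            compute_plan_dose([replace(field, weight=0.7)] * 2, rsp)


@pytest.fixture(scope="module")
def water_field_pair():
    shape = (80, 24, 24)
    rsp = water(shape, 2.0)
    ptv = box_ptv(shape, (30, 8, 8), (55, 16, 16))
    return fit_field(ptv, rsp, BeamGeometry(0)), rsp


@pytest.fixture(scope="module")
def water_field(water_field_pair):
    return water_field_pair
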