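import numpy as np
import pytest
from scipy import ndimage

from sctdosim import (
    Beam,
    BeamPlan,
    BinaryMask,
    DensityCalibration,
    Grid,
    Volume,
    compute_dose,
    hu_to_density,
    normalization_constant,
    radiological_depth,
    recalculate_on_sct,
)
from sctdosim.dose import MU_EFF_PER_MM
from sctdosim.phantom import LABELS


class TestDensityCalibration:
    def test_water_and_air_anchors(self):
        cal = DensityCalibration()
        assert cal(np.array([0.0]))[0] == pytest.approx(1.000)
        assert cal(np.array([-1000.0]))[0] == pytest.approx(0.001)

    def test_linear_interpolation_between_knots(self):
        # midpoint of (0 → 1.000, 942 → 1.512)
        cal = DensityCalibration()
        assert cal(np.array([471.0]))[0] == pytest.approx(1.256)

    def test_clamped_at_end_knots(self):
        cal = DensityCalibration()
        assert cal(np.array([-2000.0]))[0] == pytest.approx(0.001)
        assert cal(np.array([5000.0]))[0] == pytest.approx(2.2)

    def test_invalid_knots_rejected(self):
        with pytest.raises(ValueError):
            DensityCalibration(knots_hu=(0.0, 0.0), knots_density=(1.0, 1.0))
        with pytest.raises(ValueError):
            DensityCalibration(knots_hu=(0.0, 100.0), knots_density=(1.0, 0.5))

    def test_hu_to_density_volume(self):
        g = Grid((4, 4, 4), (1.0, 1.0, 1.0))
        v = Volume(g, np.zeros(g.shape), unit="HU")
        d = hu_to_density(v)
        assert d.unit == "density"
        assert np.allclose(d.values, 1.0)


class TestRadiologicalDepth:
    def test_uniform_density_gives_geometric_length(self):
        g = Grid((120, 20, 20), (1.0, 1.0, 1.0))
        dens = Volume(g, np.ones(g.shape), unit="density")
        d = radiological_depth(dens, (0.0, 10.0, 10.0), (100.0, 10.0, 10.0))
        assert d == pytest.approx(100.0, rel=1e-9)

    def test_zero_density_gives_zero(self):
        g = Grid((20, 20, 20), (1.0, 1.0, 1.0))
        dens = Volume(g, np.zeros(g.shape), unit="density")
        assert radiological_depth(dens, (0.0, 0.0, 0.0), (19.0, 19.0, 19.0)) == 0.0

    def test_zero_length_ray(self):
        g = Grid((5, 5, 5), (1.0, 1.0, 1.0))
        dens = Volume(g, np.ones(g.shape), unit="density")
        assert radiological_depth(dens, (2.0, 2.0, 2.0), (2.0, 2.0, 2.0)) == 0.0

    def test_matches_dense_quadrature(self, rng):
        # Siddon traversal vs 0.01 mm nearest-voxel quadrature on random rays
        g = Grid((20, 20, 20), (1.0, 1.3, 2.0), origin=(0.0, 0.0, 0.0))
        dens = Volume(g, rng.random(g.shape) + 0.1, unit="density")
        for _ in range(5):
            p0 = rng.uniform(-5, 25, 3)
            p1 = rng.uniform(-5, 25, 3)
            exact = radiological_depth(dens, p0, p1)
            length = np.linalg.norm(p1 - p0)
            if length == 0:
                continue
            ts = (np.arange(int(length / 0.01)) + 0.5) * 0.01 / length
            pts = p0 + np.outer(ts, p1 - p0)
            idx = np.floor(g.index_coordinates(pts) + 0.5).astype(int)
            inside = np.all((idx >= 0) & (idx < np.array(g.shape)), axis=1)
            vals = np.zeros(len(idx))
            ii = idx[inside]
            vals[inside] = np.asarray(dens.values)[ii[:, 0], ii[:, 1], ii[:, 2]]
            approx = vals.sum() * 0.01
            assert exact == pytest.approx(approx, rel=0.005, abs=0.01)


def _water_setup(ny=100, lateral=21, spacing=2.0):
    g = Grid((lateral, ny, lateral), (spacing, spacing, spacing))
    dens = Volume(g, np.ones(g.shape), unit="density")
    body = BinaryMask(g, np.ones(g.shape, bool))
    lo, hi = g.extent()
    iso = (lo + hi) / 2.0
    beam = Beam(gantry_deg=0.0, sad_mm=1000.0, isocenter_mm=tuple(iso),
                field_size_mm=60.0, weight=1.0)
    return g, dens, body, BeamPlan(prescription_gy=30.0, beams=(beam,))


class TestComputeDose:
    def test_central_axis_falloff_matches_closed_form(self):
        # homogeneous water: dose(z1)/dose(z2) = exp(−μ(z1−z2))·(r2/r1)²
        g, dens, body, plan = _water_setup()
        dose = compute_dose(dens, plan, body)
        ci = g.shape[0] // 2
        src = plan.beams[0].source_mm
        ys = g.coordinate_arrays()[1]
        # skip entrance voxels; compare pairs well inside the medium
        for j1, j2 in [(10, 40), (20, 70), (30, 85)]:
            d1, d2 = dose.values[ci, j1, ci], dose.values[ci, j2, ci]
            r1 = abs(src[1] - ys[j1])
            r2 = abs(src[1] - ys[j2])
            depth_diff = r1 - r2  # j1 is farther from the +y source
            expected = np.exp(-MU_EFF_PER_MM * depth_diff) * (r2 / r1) ** 2
            assert d1 / d2 == pytest.approx(expected, rel=0.01)

    def test_monotone_falloff_with_depth(self):
        g, dens, body, plan = _water_setup()
        dose = compute_dose(dens, plan, body)
        ci = g.shape[0] // 2
        axis = dose.values[ci, :, ci]
        # beam enters from +y: dose decreases from entrance to exit
        interior = axis[3:-3]
        assert np.all(np.diff(interior) > 0)  # increasing toward the +y source

    def test_deterministic(self):
        g, dens, body, plan = _water_setup(ny=40, lateral=11)
        a = compute_dose(dens, plan, body)
        b = compute_dose(dens, plan, body)
        assert np.array_equal(a.values, b.values)

    def test_beam_linearity(self):
        g, dens, body, _ = _water_setup(ny=40, lateral=15)
        lo, hi = g.extent()
        iso = tuple((lo + hi) / 2.0)
        b0 = Beam(0.0, 1000.0, iso, 40.0, 1.0)
        b90 = Beam(90.0, 1000.0, iso, 40.0, 1.0)
        single0 = compute_dose(dens, BeamPlan(30.0, (b0,)), body)
        single90 = compute_dose(dens, BeamPlan(30.0, (b90,)), body)
        combo = compute_dose(
            dens,
            BeamPlan(30.0, (Beam(0.0, 1000.0, iso, 40.0, 0.3),
                            Beam(90.0, 1000.0, iso, 40.0, 0.7))),
            body,
        )
        assert np.allclose(
            combo.values, 0.3 * single0.values + 0.7 * single90.values, rtol=1e-12
        )

    def test_equal_weight_invariance(self):
        # two ways of writing the same normalized plan give identical dose
        g, dens, body, _ = _water_setup(ny=40, lateral=11)
        lo, hi = g.extent()
        iso = tuple((lo + hi) / 2.0)
        beams_a = tuple(Beam(a, 1000.0, iso, 40.0, 0.25) for a in (0, 90, 180, 270))
        beams_b = tuple(Beam(a, 1000.0, iso, 40.0, 1.0 / 4.0) for a in (0, 90, 180, 270))
        da = compute_dose(dens, BeamPlan(30.0, beams_a), body)
        db = compute_dose(dens, BeamPlan(30.0, beams_b), body)
        assert np.array_equal(da.values, db.values)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            BeamPlan(30.0, (Beam(0.0, 1000.0, (0, 0, 0), 40.0, 0.5),
                            Beam(90.0, 1000.0, (0, 0, 0), 40.0, 1.0)))

    def test_bone_shadowing_reduces_distal_dose(self):
        g, dens, body, plan = _water_setup(ny=60, lateral=15)
        bone = np.asarray(dens.values).copy()
        bone[:, 40:45, :] = 1.512  # cortical-bone slab across the beam
        shadowed = compute_dose(Volume(g, bone, unit="density"), plan, body)
        open_field = compute_dose(dens, plan, body)
        ci = g.shape[0] // 2
        # distal side of the slab (smaller y, farther from the +y source)
        assert np.all(shadowed.values[ci, 5:35, ci] < open_field.values[ci, 5:35, ci])
        # proximal side unchanged
        assert np.allclose(shadowed.values[ci, 50:, ci], open_field.values[ci, 50:, ci])

    def test_dose_zero_outside_body(self):
        g, dens, _, plan = _water_setup(ny=40, lateral=11)
        member = np.zeros(g.shape, bool)
        member[:, 10:30, :] = True
        dose = compute_dose(dens, plan, BinaryMask(g, member))
        assert np.all(dose.values[~member] == 0.0)
        assert np.all(dose.values >= 0.0)


class TestRecalculateOnSct:
    def test_identical_images_give_identical_dose(self, noiseless_case):
        case = noiseless_case
        d_ct, d_sct = recalculate_on_sct(
            case.ct, case.ct, case.plan,
            body=case.structures["BODY"], ptv=case.structures["PTV"],
        )
        assert np.array_equal(d_ct.values, d_sct.values)
        ptv_med = np.median(np.asarray(d_ct.values)[case.structures["PTV"].member])
        assert ptv_med == pytest.approx(case.plan.prescription_gy, rel=1e-9)

    def test_fixed_point_sct_matches_ct_dose(self, noiseless_case):
        from sctdosim import run_sct_pipeline

        case = noiseless_case
        sct = run_sct_pipeline(case.mr, seed=0)
        d_ct, d_sct = recalculate_on_sct(
            case.ct, sct, case.plan,
            body=case.structures["BODY"], ptv=case.structures["PTV"],
        )
        dosed = np.asarray(d_ct.values) > 0
        rel = np.abs(d_sct.values - d_ct.values)[dosed] / np.asarray(d_ct.values)[dosed]
        assert rel.max() < 1e-3

    def test_dilated_body_outline_underdoses_ptv(self, noiseless_case):
        # overestimating the sCT body outline by 10 mm of soft tissue adds
        # attenuation on every beam path and lowers the PTV dose
        case = noiseless_case
        body = case.structures["BODY"]
        grow = ndimage.distance_transform_edt(
            ~body.member, sampling=case.ct.grid.spacing
        ) <= 10.0
        dilated_vals = np.asarray(case.ct.values).copy()
        dilated_vals[grow & ~body.member] = 40.0  # soft tissue shell
        sct_dilated = Volume(case.ct.grid, dilated_vals, unit="HU")
        d_ct, d_sct = recalculate_on_sct(
            case.ct, sct_dilated, case.plan,
            body=body, ptv=case.structures["PTV"],
        )
        ptv = case.structures["PTV"].member
        mean_ct = float(np.asarray(d_ct.values)[ptv].mean())
        mean_sct = float(np.asarray(d_sct.values)[ptv].mean())
        assert 100.0 * (mean_sct - mean_ct) / mean_ct < -2.0

    def test_normalization_constant_requires_dosed_ptv(self):
        g = Grid((6, 6, 6), (1.0, 1.0, 1.0))
        zero = Volume(g, np.zeros(g.shape), unit="Gy")
        ptv = BinaryMask(g, np.ones(g.shape, bool))
        with pytest.raises(ValueError, match="no dose|normalize"):
            normalization_constant(zero, ptv, 30.0)
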