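"""Scenario generation, voxel-wise minimum, warping and course accumulation."""

import numpy as np
import pytest

from arceval.dose import compute_dvh, dose_at_volume
from arceval.grid import DeformationField, DoseGrid, GeometryError, RoiMask
from arceval.robustness import (
    NOMINAL,
    Scenario,
    accumulate_course,
    fraction_robustness,
    generate_scenarios,
    scenario_dose,
    voxelwise_min,
    warp_dose,
)
from arceval.synthetic import make_dose


class TestScenarioGeneration:
    def test_standard_set_has_28_unit_shifts(self):
        ss = generate_scenarios(1.0, 0.03)
        assert len(ss) == 28
        for s in ss:
            assert s.shift_magnitude == pytest.approx(1.0)
            assert s.density_scale in (0.97, 1.03)
        assert sum(1 for s in ss if s.density_scale == 0.97) == 14
        # deterministic order
        assert [s.setup_shift for s in ss.scenarios] == [
            s.setup_shift for s in generate_scenarios(1.0, 0.03).scenarios
        ]

    def test_planning_setting_three_mm(self):
        ss = generate_scenarios(3.0, 0.03)
        assert len(ss) == 28
        assert all(s.shift_magnitude == pytest.approx(3.0) for s in ss)

    def test_degenerate_zero_settings_all_nominal(self):
        ss = generate_scenarios(0.0, 0.0)
        assert len(ss) == 28
        assert all(s.shift_magnitude == 0.0 and s.density_scale == 1.0 for s in ss)

    def test_negative_settings_rejected(self):
        with pytest.raises(ValueError):
            generate_scenarios(-1.0, 0.03)


def grid(values, spacing=(2.0, 2.0, 2.0)):
    return DoseGrid(values=np.asarray(values, dtype=float), spacing=spacing)


class TestVoxelwiseMin:
    def test_identical_inputs_identity(self):
        rng = np.random.default_rng(0)
        g = grid(rng.uniform(0, 70, (5, 5, 5)))
        assert np.array_equal(voxelwise_min([g, g, g]).values, g.values)

    def test_dominated_grid_wins(self):
        rng = np.random.default_rng(1)
        hi = grid(rng.uniform(10, 70, (5, 5, 5)))
        lo = grid(hi.values * 0.5)
        assert np.array_equal(voxelwise_min([hi, lo]).values, lo.values)

    def test_random_grids_match_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        gs = [grid(rng.uniform(0, 70, (6, 6, 6))) for _ in range(5)]
        got = voxelwise_min(gs).values
        brute = np.empty((6, 6, 6))
        for i in np.ndindex(6, 6, 6):
            brute[i] = min(g.values[i] for g in gs)
        assert np.array_equal(got, brute)

    def test_adding_scenarios_never_raises_vwmin(self):
        rng = np.random.default_rng(3)
        gs = [grid(rng.uniform(0, 70, (6, 6, 6))) for _ in range(4)]
        vw4 = voxelwise_min(gs)
        vw5 = voxelwise_min(gs + [grid(rng.uniform(0, 70, (6, 6, 6)))])
        assert np.all(vw5.values <= vw4.values)
        for g in gs:
            assert np.all(vw4.values <= g.values)

    def test_geometry_mismatch_and_empty_rejected(self):
        g = grid(np.zeros((4, 4, 4)))
        other = grid(np.zeros((4, 4, 4)), spacing=(3.0, 3.0, 3.0))
        with pytest.raises(GeometryError):
            voxelwise_min([g, other])
        with pytest.raises(ValueError):
            voxelwise_min([])


class TestWarpDose:
    def test_identity_field_unchanged(self):
        rng = np.random.default_rng(4)
        g = grid(rng.uniform(0, 70, (6, 6, 6)))
        f = DeformationField(values=np.zeros((6, 6, 6, 3)), spacing=g.spacing)
        assert np.allclose(warp_dose(g, f).values, g.values)

    def test_constant_dose_stays_constant_in_interior(self):
        g = grid(np.full((8, 8, 8), 42.0))
        f = DeformationField(values=np.full((8, 8, 8, 3), 1.0), spacing=g.spacing)
        assert np.allclose(warp_dose(g, f).values[1:-1, 1:-1, 1:-1], 42.0)

    def test_integer_voxel_translation_matches_index_shift(self):
        rng = np.random.default_rng(5)
        g = grid(rng.uniform(0, 70, (6, 6, 6)))
        shift_vox = np.array([1, 0, 2])
        f = DeformationField(
            values=np.broadcast_to(shift_vox * 2.0, (6, 6, 6, 3)).copy(), spacing=g.spacing
        )
        got = warp_dose(g, f).values
        expected = np.zeros_like(g.values)
        expected[:5, :, :4] = g.values[1:, :, 2:]
        assert np.allclose(got, expected)

    def test_geometry_mismatch_rejected(self):
        g = grid(np.zeros((4, 4, 4)))
        f = DeformationField(values=np.zeros((5, 5, 5, 3)), spacing=g.spacing)
        with pytest.raises(GeometryError):
            warp_dose(g, f)


class ShiftEngine:
    """Translation-equivariant toy engine over a fixed base grid."""

    def __init__(self, base: DoseGrid, extra_shift=(0.0, 0.0, 0.0)):
        self.base = base
        self.extra = np.asarray(extra_shift)

    def dose(self, scenario: Scenario = NOMINAL) -> DoseGrid:
        from scipy import ndimage

        shift = np.asarray(scenario.setup_shift) + self.extra
        sp = np.asarray(self.base.spacing)
        out = ndimage.shift(
            self.base.values, -shift / sp, order=1, mode="constant", cval=0.0
        )
        return DoseGrid(values=np.maximum(out, 0), origin=self.base.origin, spacing=self.base.spacing)


def blob_dose(n=24, spacing=4.0, radius=30.0, dp=70.0):
    c = (n - 1) / 2 * spacing
    ax = np.arange(n) * spacing
    xs, ys, zs = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt((xs - c) ** 2 + (ys - c) ** 2 + (zs - c) ** 2)
    vals = dp / (1 + np.exp((r - radius) / 4.0))
    return DoseGrid(values=vals, spacing=(spacing,) * 3), (xs, ys, zs, c)


class TestFractionRobustness:
    def test_scenario_blind_engine_keeps_nominal_d98(self):
        base, (xs, ys, zs, c) = blob_dose()

        class Blind:
            def dose(self, scenario=NOMINAL):
                return base

        roi = RoiMask(values=np.sqrt((xs - c) ** 2 + (ys - c) ** 2 + (zs - c) ** 2) < 20.0,
                      spacing=base.spacing, name="ctv")
        res = fraction_robustness(Blind(), generate_scenarios(2.0, 0.03), [roi], {"ctv": 70.0})
        nominal_d98 = dose_at_volume(compute_dvh(base, roi), 98.0) / 70.0 * 100.0
        assert res.target_metrics["ctv"]["D98_pctDp"] == pytest.approx(nominal_d98)
        assert res.n_scenarios == 28

    def test_uniform_dose_keeps_full_coverage(self):
        shape = (8, 8, 8)
        uni = DoseGrid(values=np.full(shape, 70.0), spacing=(4.0,) * 3)

        class Uniform:
            def dose(self, scenario=NOMINAL):
                return uni

        roi = RoiMask(values=np.ones(shape, bool), spacing=(4.0,) * 3, name="ctv")
        res = fraction_robustness(Uniform(), generate_scenarios(1.0, 0.03), [roi], {"ctv": 70.0})
        assert res.target_metrics["ctv"]["D98_pctDp"] == pytest.approx(100.0)
        assert res.target_metrics["ctv"]["V95_pct"] == pytest.approx(100.0)

    def test_vwmin_below_every_scenario_dose(self, small_phantom):
        engine = make_dose(small_phantom, technique="elf_30b", seed=2)
        scen = generate_scenarios(2.0, 0.03)
        doses = [scenario_dose(engine, s) for s in scen]
        vw = voxelwise_min(doses)
        for d in doses:
            assert np.all(vw.values <= d.values + 1e-12)

    def test_dominating_worst_scenario_sets_vwmin_d98(self):
        base, (xs, ys, zs, c) = blob_dose()
        roi = RoiMask(values=np.sqrt((xs - c) ** 2 + (ys - c) ** 2 + (zs - c) ** 2) < 20.0,
                      spacing=base.spacing, name="ctv")
        engine = ShiftEngine(base)
        # custom two-scenario comparison: one large shift dominates
        s_small = Scenario((1.0, 0.0, 0.0), 1.0)
        s_big = Scenario((10.0, 0.0, 0.0), 1.0)
        d_small, d_big = engine.dose(s_small), engine.dose(s_big)
        vw = voxelwise_min([d_small, d_big])
        d98_vw = dose_at_volume(compute_dvh(vw, roi), 98.0)
        d98_big = dose_at_volume(compute_dvh(d_big, roi), 98.0)
        # the heavily shifted scenario is (near-)everywhere the lower one
        # on the target, so it alone determines D98 of the vwmin
        assert d98_vw == pytest.approx(d98_big, rel=5e-3)


class TestCourseAccumulation:
    def _setup(self):
        base, (xs, ys, zs, c) = blob_dose()
        roi = RoiMask(values=np.sqrt((xs - c) ** 2 + (ys - c) ** 2 + (zs - c) ** 2) < 20.0,
                      spacing=base.spacing, name="ctv")
        return base, roi

    def test_single_rct_equals_fraction_result(self):
        base, roi = self._setup()
        engine = ShiftEngine(base)
        scen = generate_scenarios(2.0, 0.03)
        fr = fraction_robustness(engine, scen, [roi], {"ctv": 70.0})
        doses = [engine.dose(s) for s in scen]
        course = accumulate_course([doses], [1.0], [roi], {"ctv": 70.0})
        assert course.target_metrics == fr.target_metrics
        assert np.allclose(course.vwmin.values, fr.vwmin.values)

    def test_identical_weeks_idempotent(self):
        base, roi = self._setup()
        engine = ShiftEngine(base)
        scen = generate_scenarios(1.0, 0.03)
        doses = [engine.dose(s) for s in scen]
        course = accumulate_course([doses, doses, doses], [1 / 3] * 3, [roi], {"ctv": 70.0})
        single = accumulate_course([doses], [1.0], [roi], {"ctv": 70.0})
        assert np.allclose(course.vwmin.values, single.vwmin.values)

    def test_opposite_perturbations_average_out(self):
        base, roi = self._setup()
        scen = generate_scenarios(1.0, 0.0)
        week_plus = ShiftEngine(base, extra_shift=(6.0, 0.0, 0.0))
        week_minus = ShiftEngine(base, extra_shift=(-6.0, 0.0, 0.0))
        d_plus = [week_plus.dose(s) for s in scen]
        d_minus = [week_minus.dose(s) for s in scen]
        course = accumulate_course([d_plus, d_minus], [0.5, 0.5], [roi], {"ctv": 70.0})
        fr_d98 = [
            dose_at_volume(compute_dvh(voxelwise_min(ds), roi), 98.0)
            for ds in (d_plus, d_minus)
        ]
        assert course.target_metrics["ctv"]["D98_pctDp"] * 0.70 >= min(fr_d98) - 1e-9

    def test_course_beats_mean_fraction_for_zero_mean_shifts(self):
        """Random-error averaging: course-wise D98,vwmin is at least the mean
        fraction-wise D98,vwmin for zero-mean weekly translations of a
        smooth dose."""
        base, roi = self._setup()
        rng = np.random.default_rng(10)
        scen = generate_scenarios(1.0, 0.0)
        shifts = rng.normal(0.0, 4.0, (4, 3))
        shifts -= shifts.mean(axis=0)  # exactly zero-mean
        weeks = [ShiftEngine(base, extra_shift=s) for s in shifts]
        per_week = [[w.dose(s) for s in scen] for w in weeks]
        frac = [
            dose_at_volume(compute_dvh(voxelwise_min(ds), roi), 98.0) for ds in per_week
        ]
        course = accumulate_course(per_week, [0.25] * 4, [roi], {"ctv": 70.0})
        course_d98 = course.target_metrics["ctv"]["D98_pctDp"] * 0.70
        assert course_d98 >= np.mean(frac) - 1e-9

    def test_ragged_and_bad_weights_rejected(self):
        base, roi = self._setup()
        d = [base, base]
        with pytest.raises(ValueError, match="same number"):
            accumulate_course([d, [base]], [0.5, 0.5], [roi], {"ctv": 70.0})
        with pytest.raises(ValueError, match="sum to 1"):
            accumulate_course([d], [0.5], [roi], {"ctv": 70.0})


class TestEngineHooks:
    def test_nominal_scenario_returns_nominal_dose(self, small_phantom):
        engine = make_dose(small_phantom, seed=0)
        d1 = engine.dose()
        d2 = engine.dose(Scenario((0.0, 0.0, 0.0), 1.0))
        assert d1 is d2  # cached, bit-exact

    def test_translation_equivariance_integer_voxel(self, small_phantom):
        engine = make_dose(small_phantom, seed=0)
        sp = small_phantom.density.spacing[0]
        nominal = engine.dose().values
        shifted = engine.dose(Scenario((sp, 0.0, 0.0), 1.0)).values
        assert np.allclose(shifted[1:, :, :], nominal[:-1, :, :], atol=1e-9)

    def test_density_scale_moves_falloff_monotonically(self, small_phantom):
        engine = make_dose(small_phantom, seed=0)
        # continuous distal falloff position (35 Gy crossing) along +x
        # through the target centre, found by linear interpolation
        def edge_position(scale):
            d = engine.dose(Scenario((0.0, 0.0, 0.0), scale)).values
            profile = d[:, d.shape[1] // 2, d.shape[2] // 2]
            k = int(np.nonzero(profile >= 35.0)[0].max())
            hi, lo = profile[k], profile[k + 1]
            return k + (hi - 35.0) / (hi - lo)

        e_low, e_nom, e_high = (edge_position(s) for s in (0.95, 1.0, 1.05))
        assert e_low > e_nom > e_high
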