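"""Delivery-time simulation: beam-on model, kinematics, static and dynamic."""

import math

import numpy as np
import pytest

from arceval.delivery import (
    dynamic_delivery_time,
    energy_switch_time,
    gantry_move_time,
    layer_beam_on_time,
    static_delivery_time,
)
from arceval.machine import MachineModel
from arceval.plan import (
    ControlPoint,
    DeliverySequence,
    EnergyLayer,
    Spot,
    TreatmentPlan,
    sequence_layers,
)
from .conftest import make_dynamic_cp, make_layer, make_static_beam


def gantry_oracle(delta, a=0.6, vmax=6.0, dt=1e-4):
    """Independent bang-bang time-stepping integrator: accelerate unless the
    stopping distance exceeds what remains; trapezoidal position update; the
    residual stopping ramp after the final step is added analytically."""
    x = v = t = 0.0
    while x < delta - 1e-12:
        rem = delta - x
        v_new = v - a * dt if (v * v) / (2 * a) >= rem else min(v + a * dt, vmax)
        v_new = max(v_new, 0.0)
        x += 0.5 * (v + v_new) * dt
        v = v_new
        t += dt
    return t + v / a


class TestLayerBeamOn:
    def test_ten_unit_spots(self, machine):
        layer = make_layer(100.0, [1.0] * 10)
        # 10 x 5 ms beam-on + 9 x 2 ms switches = 68 ms
        assert layer_beam_on_time(layer, machine) == pytest.approx(0.068)

    def test_single_spot_has_no_switch_term(self, machine):
        layer = make_layer(100.0, [2.0])
        assert layer_beam_on_time(layer, machine) == pytest.approx(0.010)

    def test_floor_applies_to_small_mu(self, machine):
        layer = make_layer(100.0, [0.1])  # 0.5 ms < 2 ms floor
        assert layer_beam_on_time(layer, machine) == pytest.approx(0.002)

    def test_random_layer_matches_per_spot_summation(self, machine):
        rng = np.random.default_rng(5)
        mus = rng.uniform(0.0, 3.0, 200)
        layer = make_layer(100.0, mus)
        brute = sum(max(m * 5.0, 2.0) for m in mus) / 1000.0 + 199 * 2.0 / 1000.0
        assert layer_beam_on_time(layer, machine) == pytest.approx(brute, abs=1e-12)


class TestEnergySwitch:
    def test_directions(self, machine):
        assert energy_switch_time(100.0, 110.0, machine) == 6.0
        assert energy_switch_time(110.0, 100.0, machine) == 0.8
        assert energy_switch_time(100.0, 100.0, machine) == 0.0


class TestGantryMove:
    def test_zero(self, machine):
        assert gantry_move_time(0.0, machine) == 0.0

    def test_negative_rejected(self, machine):
        with pytest.raises(ValueError):
            gantry_move_time(-1.0, machine)

    def test_triangular_12_degrees(self, machine):
        assert gantry_move_time(12.0, machine) == pytest.approx(2 * math.sqrt(12 / 0.6), abs=1e-9)
        assert gantry_move_time(12.0, machine) == pytest.approx(8.944, abs=1e-3)

    def test_trapezoidal_full_turn(self, machine):
        # 30 deg accel + 300 deg cruise + 30 deg decel
        assert gantry_move_time(360.0, machine) == pytest.approx(70.0, abs=1e-9)

    @pytest.mark.parametrize("delta", [0.5, 2.0, 12.0, 59.9, 60.0, 60.1, 200.0, 360.0])
    def test_matches_time_stepping_integrator(self, machine, delta):
        assert gantry_move_time(delta, machine) == pytest.approx(gantry_oracle(delta), abs=1e-2)


class TestStaticDelivery:
    def test_single_beam_is_beam_time_only(self, machine):
        plan = TreatmentPlan("static_fields", [make_static_beam(0.0, [150.0, 120.0], [1.0, 1.0])])
        bd = static_delivery_time(plan, sequence_layers(plan), machine)
        assert bd.gantry_motion_s == 0.0
        assert bd.range_shifter_s == 0.0
        # 2 layers x (2 x 5 ms + 1 x 2 ms) + one down switch
        assert bd.total_s == pytest.approx(2 * 0.012 + 0.8)
        assert bd.total_s == pytest.approx(
            bd.beam_on_s + bd.spot_switch_s + bd.energy_switch_s
        )

    def test_two_beams_hand_computed_components(self, machine):
        plan = TreatmentPlan(
            "static_fields",
            [
                make_static_beam(10.0, [150.0, 120.0], [1.0]),
                make_static_beam(22.0, [160.0, 110.0], [1.0]),
            ],
        )
        bd = static_delivery_time(plan, sequence_layers(plan), machine)
        assert bd.beam_on_s == pytest.approx(4 * 0.005)
        assert bd.spot_switch_s == 0.0
        # within beam 1: down; 120 -> 160 up; within beam 2: down
        assert bd.energy_switch_s == pytest.approx(0.8 + 6.0 + 0.8)
        assert bd.gantry_motion_s == pytest.approx(2 * math.sqrt(12 / 0.6))
        assert bd.total_s == pytest.approx(
            bd.beam_on_s + bd.energy_switch_s + bd.gantry_motion_s
        )

    @pytest.mark.parametrize("technique,penalty", [("static_fields", 120.0), ("static_arc", 60.0)])
    def test_range_shifter_penalty_by_technique(self, machine, technique, penalty):
        plan = TreatmentPlan(
            technique,
            [
                make_static_beam(0.0, [150.0], rs=True, snout=technique == "static_fields"),
                make_static_beam(40.0, [160.0], rs=True),
                make_static_beam(80.0, [140.0]),
            ],
        )
        bd = static_delivery_time(plan, sequence_layers(plan), machine)
        assert bd.range_shifter_s == penalty

    def test_sequence_plan_mismatch_rejected(self, machine, two_beam_plan):
        bad = DeliverySequence([(0, 0, 150.0)])
        with pytest.raises(ValueError, match="sequence"):
            static_delivery_time(two_beam_plan, bad, machine)

    def test_dynamic_plan_rejected(self, machine):
        plan = TreatmentPlan("dynamic_arc", [make_dynamic_cp(0.0, 1.0, [100.0])])
        with pytest.raises(ValueError, match="static"):
            static_delivery_time(plan, None, machine)

    def test_monotone_in_timing_constants_and_mu(self, two_beam_plan):
        base = MachineModel()
        t0 = static_delivery_time(two_beam_plan, None, base).total_s
        for kwargs in (
            {"spot_time_per_mu": 6.0},
            {"spot_switch_time": 3.0},
            {"energy_up_switch_time": 7.0},
            {"energy_down_switch_time": 1.0},
        ):
            t1 = static_delivery_time(two_beam_plan, None, MachineModel(**kwargs)).total_s
            assert t1 >= t0
        import copy

        heavier = copy.deepcopy(two_beam_plan)
        for cp in heavier.control_points:
            for layer in cp.layers:
                layer.spots = [Spot(s.x, s.y, s.mu * 2) for s in layer.spots]
        assert static_delivery_time(heavier, None, base).total_s >= t0

    def test_up_for_down_swap_costs_exactly_the_difference(self, machine):
        down_plan = TreatmentPlan("static_fields", [make_static_beam(0.0, [150.0, 120.0])])
        up_plan = TreatmentPlan("static_fields", [make_static_beam(0.0, [120.0, 150.0])])
        seq_down = DeliverySequence([(0, 0, 150.0), (0, 1, 120.0)])
        seq_up = DeliverySequence([(0, 0, 120.0), (0, 1, 150.0)])
        t_down = static_delivery_time(down_plan, seq_down, machine).total_s
        t_up = static_delivery_time(up_plan, seq_up, machine).total_s
        assert t_up - t_down == pytest.approx(6.0 - 0.8, abs=1e-12)

    def test_merging_layers_never_increases_switch_component(self, machine):
        split = TreatmentPlan(
            "static_fields", [make_static_beam(0.0, [150.0, 150.0, 120.0], [1.0])]
        )
        merged = TreatmentPlan(
            "static_fields", [make_static_beam(0.0, [150.0, 120.0], [1.0, 1.0])]
        )
        t_split = static_delivery_time(split, sequence_layers(split), machine)
        t_merged = static_delivery_time(merged, sequence_layers(merged), machine)
        assert t_merged.energy_switch_s <= t_split.energy_switch_s


def dyn_plan(windows, mu_for_seconds=None):
    """Dynamic plan from (angle, width, beam_seconds); one spot per layer whose
    MU reproduces the requested beam-on seconds (all same energy: no switches)."""
    cps = []
    for ang, width, secs in windows:
        mu = secs * 1000.0 / 5.0
        cps.append(make_dynamic_cp(ang, width, [150.0], [max(mu, 0.4)]))
    return TreatmentPlan("dynamic_arc", cps)


class TestDynamicDelivery:
    def test_slow_crawl_window(self, machine):
        # 1 deg window needing 5 s: gantry crawls at 0.2 deg/s, plus short
        # entry/exit ramps from and to rest
        plan = dyn_plan([(10.0, 1.0, 5.0)])
        bd = dynamic_delivery_time(plan, machine)
        assert 5.0 <= bd.total_s <= 5.5

    def test_pure_motion_two_windows(self, machine):
        plan = dyn_plan([(10.0, 1.0, 0.002), (11.0, 1.0, 0.002)])
        bd = dynamic_delivery_time(plan, machine)
        assert bd.total_s == pytest.approx(2 * math.sqrt(2 / 0.6), abs=1e-6)

    def test_negligible_beam_time_reduces_to_full_arc_move(self, machine):
        plan = dyn_plan([((i + 0.5) * 1.0, 1.0, 0.002) for i in range(360)])
        bd = dynamic_delivery_time(plan, machine)
        assert bd.total_s == pytest.approx(gantry_move_time(360.0, machine), abs=1e-6)

    def test_total_at_least_beam_and_motion_bounds(self, machine):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(3, 15))
            spacing = 360.0 / n
            windows = [
                ((i + 0.5) * spacing, min(2.5, spacing), float(rng.uniform(0.0, 4.0)))
                for i in range(n)
            ]
            plan = dyn_plan(windows)
            bd = dynamic_delivery_time(plan, machine)
            beam = bd.beam_on_s + bd.spot_switch_s + bd.energy_switch_s
            span = windows[-1][0] + windows[-1][1] / 2 - (windows[0][0] - windows[0][1] / 2)
            assert bd.total_s >= max(beam, gantry_move_time(span, machine)) - 1e-9
            assert bd.gantry_motion_s == pytest.approx(bd.total_s - beam, abs=1e-9)

    def test_matches_independent_space_marching_controller(self, machine):
        """Cross-check the closed-form segment algebra against a fine
        space-discretised velocity-limit integrator."""
        windows = [(20.0, 2.0, 3.0), (40.0, 1.0, 0.5), (90.0, 2.5, 6.0)]
        plan = dyn_plan(windows)
        bd = dynamic_delivery_time(plan, machine)

        a, vmax = machine.gantry_acceleration, machine.gantry_vmax
        start = windows[0][0] - windows[0][1] / 2
        end = windows[-1][0] + windows[-1][1] / 2
        n = 400000
        s = np.linspace(start, end, n + 1)
        ds = (end - start) / n
        cap = np.full(n + 1, vmax)
        for ang, width, secs in windows:
            inside = (s >= ang - width / 2 - 1e-12) & (s <= ang + width / 2 + 1e-12)
            cap[inside] = np.minimum(cap[inside], width / secs)
        v = cap.copy()
        v[0] = 0.0
        for i in range(n):  # forward accel limit
            v[i + 1] = min(v[i + 1], math.sqrt(v[i] ** 2 + 2 * a * ds))
        v[-1] = 0.0
        for i in range(n - 1, -1, -1):  # backward decel limit
            v[i] = min(v[i], math.sqrt(v[i + 1] ** 2 + 2 * a * ds))
        t = float(np.sum(2 * ds / (v[1:] + v[:-1])))
        assert bd.total_s == pytest.approx(t, abs=5e-2)

    def test_overlapping_windows_rejected(self, machine):
        plan = TreatmentPlan(
            "dynamic_arc",
            [make_dynamic_cp(10.0, 3.0, [100.0]), make_dynamic_cp(12.0, 3.0, [90.0])],
        )
        with pytest.raises(ValueError, match="overlap"):
            dynamic_delivery_time(plan, machine)

    def test_static_plan_rejected(self, machine, two_beam_plan):
        with pytest.raises(ValueError, match="dynamic"):
            dynamic_delivery_time(two_beam_plan, machine)
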