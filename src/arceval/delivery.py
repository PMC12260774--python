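"""Delivery-time simulation for static and dynamic PBS proton plans.

Static (auto-sequenced) delivery adds up four serialized components:
beam-on time per spot (linear in MU with a per-spot floor), spot-switch
time, direction-dependent energy-switch time, and rest-to-rest gantry
moves between control points, plus a per-field range-shifter penalty.

Dynamic delivery simulates the arc controller: the gantry rotates
continuously, starting at rest at the first angular window and stopping at
rest after the last. Each control point's window must be traversed no
faster than its required beam time allows; the controller enforces this as
a per-window velocity cap (so traversal time >= required time holds for
any profile under the cap), and the minimum-time profile under piecewise
caps, the global velocity limit and the acceleration limit is computed
with a forward feasibility pass and a backward smoothing pass in closed
form per segment. Acceleration during dose delivery is allowed and no
buffer window is added around control points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .machine import MachineModel
from .plan import (
    DeliverySequence,
    EnergyLayer,
    TreatmentPlan,
    arc_deltas,
    sequence_layers,
)

__all__ = [
    "TimeBreakdown",
    "layer_beam_on_time",
    "energy_switch_time",
    "gantry_move_time",
    "static_delivery_time",
    "dynamic_delivery_time",
]


@dataclass
class TimeBreakdown:
    """Per-cause delivery time in seconds.

    For static delivery ``total_s`` is the plain sum of the components.
    For dynamic delivery ``total_s`` comes from the controller simulation
    and ``gantry_motion_s`` is the *excess* of the total over the beam
    components, so nothing is double-counted.
    """

    beam_on_s: float = 0.0
    spot_switch_s: float = 0.0
    energy_switch_s: float = 0.0
    gantry_motion_s: float = 0.0
    range_shifter_s: float = 0.0
    total_s: float = 0.0

    @property
    def total_excluding_gantry_s(self) -> float:
        return self.beam_on_s + self.spot_switch_s + self.energy_switch_s + self.range_shifter_s

    def as_dict(self) -> dict:
        return {
            "beam_on_s": self.beam_on_s,
            "spot_switch_s": self.spot_switch_s,
            "energy_switch_s": self.energy_switch_s,
            "gantry_motion_s": self.gantry_motion_s,
            "range_shifter_s": self.range_shifter_s,
            "total_s": self.total_s,
        }


def _layer_components(layer: EnergyLayer, machine: MachineModel) -> Tuple[float, float]:
    """(beam-on seconds, spot-switch seconds) for one layer."""
    beam_on_ms = sum(
        max(s.mu * machine.spot_time_per_mu, machine.spot_time_min) for s in layer.spots
    )
    switch_ms = (layer.n_spots - 1) * machine.spot_switch_time
    return beam_on_ms / 1000.0, switch_ms / 1000.0


def layer_beam_on_time(layer: EnergyLayer, machine: MachineModel) -> float:
    """Seconds to deliver one layer: per-spot beam-on plus spot switches."""
    beam_on, switch = _layer_components(layer, machine)
    return beam_on + switch


def energy_switch_time(e_from: float, e_to: float, machine: MachineModel) -> float:
    """Seconds to switch between two energies; 0 if equal."""
    if e_to > e_from:
        return machine.energy_up_switch_time
    if e_to < e_from:
        return machine.energy_down_switch_time
    return 0.0


def gantry_move_time(delta: float, machine: MachineModel) -> float:
    """Rest-to-rest rotation time over ``delta`` degrees.

    Triangular velocity profile when the move is too short to reach
    ``gantry_vmax``, trapezoidal otherwise.
    """
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    if delta == 0:
        return 0.0
    a = machine.gantry_acceleration
    vmax = machine.gantry_vmax
    if delta <= vmax * vmax / a:
        return 2.0 * math.sqrt(delta / a)
    return delta / vmax + vmax / a


def static_delivery_time(
    plan: TreatmentPlan,
    seq: Optional[DeliverySequence],
    machine: MachineModel,
) -> TimeBreakdown:
    """Auto-sequenced static delivery: all components serialized.

    The range-shifter penalty per flagged field is 60 s for multi-field
    plans (range shifter inserted and snout moved to the patient) and 30 s
    for static arcs (range shifter moved in/out only).
    """
    if plan.technique not in ("static_fields", "static_arc"):
        raise ValueError(f"static_delivery_time requires a static plan, got {plan.technique}")
    if seq is None:
        seq = sequence_layers(plan)
    expected = {(i, j) for i, cp in enumerate(plan.control_points) for j in range(len(cp.layers))}
    got = {(i, j) for i, j, _ in seq.entries}
    if got != expected:
        raise ValueError("delivery sequence does not cover the plan's layers exactly once")

    bd = TimeBreakdown()
    for i, j, _ in seq.entries:
        beam_on, sw = _layer_components(plan.control_points[i].layers[j], machine)
        bd.beam_on_s += beam_on
        bd.spot_switch_s += sw
    e = seq.energies
    bd.energy_switch_s = sum(energy_switch_time(a, b, machine) for a, b in zip(e, e[1:]))
    bd.gantry_motion_s = sum(gantry_move_time(d, machine) for d in arc_deltas(plan))
    per_field = (
        machine.rs_field_time_static_fields
        if plan.technique == "static_fields"
        else machine.rs_field_time_static_arc
    )
    bd.range_shifter_s = per_field * plan.n_range_shifter_fields
    bd.total_s = (
        bd.beam_on_s + bd.spot_switch_s + bd.energy_switch_s + bd.gantry_motion_s + bd.range_shifter_s
    )
    return bd


# ---------------------------------------------------------------------------
# Dynamic arc controller


@dataclass
class _Segment:
    length: float      # deg
    cap: float         # deg/s velocity cap inside the segment
    required_s: float  # beam time that must fit in the segment (windows only)


def _plan_windows(plan: TreatmentPlan, machine: MachineModel):
    """Unwrapped window intervals [(start, end, required_s), ...] along the arc."""
    deltas = arc_deltas(plan)
    centers = [0.0]
    for d in deltas:
        centers.append(centers[-1] + d)

    windows = []
    prev_energy: Optional[float] = None
    prev_end = -math.inf
    for i, cp in enumerate(plan.control_points):
        if cp.angular_window <= 0:
            raise ValueError(f"control point {i}: dynamic delivery requires angular_window > 0")
        start = centers[i] - cp.angular_window / 2.0
        end = centers[i] + cp.angular_window / 2.0
        if start < prev_end - 1e-9:
            raise ValueError(f"control point {i}: angular windows overlap")
        prev_end = end
        required = 0.0
        for layer in cp.layers:
            if prev_energy is not None:
                required += energy_switch_time(prev_energy, layer.energy, machine)
            required += layer_beam_on_time(layer, machine)
            prev_energy = layer.energy
        windows.append((start, end, required))
    return windows


def _build_segments(windows, machine: MachineModel) -> List[_Segment]:
    segs: List[_Segment] = []
    vmax = machine.gantry_vmax
    pos = windows[0][0]
    for start, end, required in windows:
        if start > pos + 1e-12:
            segs.append(_Segment(start - pos, vmax, 0.0))
        width = end - start
        cap = vmax if required <= 0 else min(vmax, width / required)
        segs.append(_Segment(width, cap, required))
        pos = end
    return segs


def _segment_time(v0: float, v1: float, cap: float, length: float, a: float) -> float:
    """Minimum traversal time of one segment entering at v0, leaving at v1,
    with velocity <= cap and |acceleration| <= a. Entry/exit velocities are
    assumed feasible (guaranteed by the forward/backward passes)."""
    if length <= 1e-15:
        return 0.0
    v_peak_sq = (2.0 * a * length + v0 * v0 + v1 * v1) / 2.0
    v_peak = math.sqrt(max(v_peak_sq, 0.0))
    if v_peak <= cap + 1e-15:
        return (2.0 * v_peak - v0 - v1) / a
    d_acc = (cap * cap - v0 * v0) / (2.0 * a)
    d_dec = (cap * cap - v1 * v1) / (2.0 * a)
    cruise = length - d_acc - d_dec
    return (cap - v0) / a + (cap - v1) / a + cruise / cap


def dynamic_delivery_time(plan: TreatmentPlan, machine: MachineModel) -> TimeBreakdown:
    """Continuous-rotation delivery time from the arc-controller simulation.

    The gantry is at rest at the start of the first window and again after
    the last; within each window the velocity is capped at
    ``window_width / required_beam_time`` so the window cannot be crossed
    faster than its layers (including the energy switch into the window)
    can be delivered. The total is the minimum-time profile under these
    caps — always >= max(total beam time, pure rest-to-rest motion time
    over the arc span), with equality in the respective degenerate limits.
    """
    if plan.technique != "dynamic_arc":
        raise ValueError(f"dynamic_delivery_time requires a dynamic_arc plan, got {plan.technique}")

    windows = _plan_windows(plan, machine)
    segs = _build_segments(windows, machine)
    a = machine.gantry_acceleration
    n = len(segs)

    # Boundary velocity limits: a boundary between two segments cannot be
    # crossed faster than either neighbour's cap; the ends are at rest.
    bound = [0.0] * (n + 1)
    bound[0] = 0.0
    bound[n] = 0.0
    for k in range(1, n):
        bound[k] = min(segs[k - 1].cap, segs[k].cap)

    fwd = [0.0] * (n + 1)
    fwd[0] = 0.0
    for k in range(n):
        fwd[k + 1] = min(bound[k + 1], math.sqrt(fwd[k] ** 2 + 2.0 * a * segs[k].length))
    bwd = [0.0] * (n + 1)
    bwd[n] = 0.0
    for k in range(n - 1, -1, -1):
        bwd[k] = min(bound[k], math.sqrt(bwd[k + 1] ** 2 + 2.0 * a * segs[k].length))
    v = [min(f, b) for f, b in zip(fwd, bwd)]

    total = sum(
        _segment_time(v[k], v[k + 1], segs[k].cap, segs[k].length, a) for k in range(n)
    )

    bd = TimeBreakdown()
    for cp in plan.control_points:
        for layer in cp.layers:
            beam_on, sw = _layer_components(layer, machine)
            bd.beam_on_s += beam_on
            bd.spot_switch_s += sw
    bd.energy_switch_s = sum(w[2] for w in windows) - bd.beam_on_s - bd.spot_switch_s
    bd.total_s = total
    bd.gantry_motion_s = max(total - (bd.beam_on_s + bd.spot_switch_s + bd.energy_switch_s), 0.0)
    return bd
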