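"""Treatment-plan data model and energy-layer sequencing.

A pencil-beam-scanning plan is an ordered list of control points. For
static delivery (multi-field IMPT or a static arc) each control point is a
fixed gantry angle with ``angular_window == 0``; for dynamic arc delivery
each control point owns an angular window (full width, centred on the
gantry angle) traversed while its energy layers are delivered.

Energy layers hold spots with monitor units (MU). On cyclotron-based
systems switching to a *higher* proton energy is much slower than switching
down, so the number of energy up-switches in the delivery sequence is a
first-order driver of delivery time; :func:`count_energy_up_switches`
counts them on a :class:`DeliverySequence`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Sequence, Tuple

__all__ = [
    "Spot",
    "EnergyLayer",
    "ControlPoint",
    "TreatmentPlan",
    "DeliverySequence",
    "TECHNIQUES",
    "validate_plan",
    "sequence_layers",
    "count_energy_up_switches",
    "read_plan",
    "write_plan",
    "plan_to_dict",
    "plan_from_dict",
]

TECHNIQUES = ("static_fields", "static_arc", "dynamic_arc")
ARC_TECHNIQUES = ("static_arc", "dynamic_arc")


@dataclass(frozen=True)
class Spot:
    """One scanned spot: position (mm) in the layer's scanning plane and MU."""

    x: float
    y: float
    mu: float


@dataclass
class EnergyLayer:
    """All spots delivered at one proton energy (MeV), in delivery order."""

    energy: float
    spots: List[Spot]

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def total_mu(self) -> float:
        return sum(s.mu for s in self.spots)


@dataclass
class ControlPoint:
    """A gantry position (static) or angular window (dynamic).

    ``angular_window`` is the full width in degrees of the arc segment,
    centred on ``gantry_angle``, over which this control point's layers are
    delivered; it is 0 for static delivery. ``range_shifter`` marks fields
    delivered through a range shifter; ``snout_motion_required`` marks
    fields where the snout additionally has to be moved (clinical
    multi-field practice), which determines the per-field time penalty.
    """

    gantry_angle: float
    angular_window: float
    layers: List[EnergyLayer]
    range_shifter: bool = False
    snout_motion_required: bool = False


@dataclass
class TreatmentPlan:
    technique: str
    control_points: List[ControlPoint]
    arc_direction: int = 1
    metadata: dict = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return sum(len(cp.layers) for cp in self.control_points)

    @property
    def n_spots(self) -> int:
        return sum(layer.n_spots for cp in self.control_points for layer in cp.layers)

    @property
    def n_range_shifter_fields(self) -> int:
        return sum(1 for cp in self.control_points if cp.range_shifter)


@dataclass
class DeliverySequence:
    """Flattened delivery order: (control_point_index, layer_index, energy)."""

    entries: List[Tuple[int, int, float]]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Tuple[int, int, float]]:
        return iter(self.entries)

    @property
    def energies(self) -> List[float]:
        return [e for _, _, e in self.entries]


def _finite(x: float) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


def validate_plan(plan: TreatmentPlan) -> List[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the plan is well formed. Violations name the
    offending control point / layer / spot; nothing is raised.
    """
    v: List[str] = []
    if plan.technique not in TECHNIQUES:
        v.append(f"unknown technique {plan.technique!r}")
    if plan.arc_direction not in (1, -1):
        v.append(f"arc_direction must be +1 or -1, got {plan.arc_direction!r}")
    if not plan.control_points:
        v.append("plan has no control points")

    for i, cp in enumerate(plan.control_points):
        if not _finite(cp.gantry_angle) or not (0.0 <= cp.gantry_angle < 360.0):
            v.append(f"control point {i}: gantry_angle {cp.gantry_angle!r} outside [0, 360)")
        if not _finite(cp.angular_window) or cp.angular_window < 0:
            v.append(f"control point {i}: angular_window {cp.angular_window!r} invalid")
        elif plan.technique == "dynamic_arc" and cp.angular_window == 0:
            v.append(f"control point {i}: dynamic plan requires angular_window > 0")
        elif plan.technique in ("static_fields", "static_arc") and cp.angular_window > 0:
            v.append(f"control point {i}: static plan requires angular_window = 0")
        if not cp.layers:
            v.append(f"control point {i}: no energy layers")
        for j, layer in enumerate(cp.layers):
            if not _finite(layer.energy) or layer.energy <= 0:
                v.append(f"control point {i} layer {j}: energy {layer.energy!r} must be > 0")
            if not layer.spots:
                v.append(f"control point {i} layer {j}: empty spot list")
            for k, s in enumerate(layer.spots):
                if not _finite(s.mu) or s.mu < 0:
                    v.append(f"control point {i} layer {j} spot {k}: mu {s.mu!r} must be >= 0")
                if not (_finite(s.x) and _finite(s.y)):
                    v.append(f"control point {i} layer {j} spot {k}: non-finite position")

    if plan.technique in ARC_TECHNIQUES and len(plan.control_points) > 1:
        ok_angles = all(
            _finite(cp.gantry_angle) and 0.0 <= cp.gantry_angle < 360.0
            for cp in plan.control_points
        )
        if ok_angles:
            total = 0.0
            for i in range(1, len(plan.control_points)):
                a0 = plan.control_points[i - 1].gantry_angle
                a1 = plan.control_points[i].gantry_angle
                d = (plan.arc_direction * (a1 - a0)) % 360.0
                if d == 0.0:
                    v.append(
                        f"control point {i}: duplicate gantry angle {a1}° on an arc"
                    )
                total += d
            if total > 360.0 + 1e-9:
                v.append(
                    f"arc traversal spans {total:.3f}° > 360°: control points not "
                    "monotone along arc_direction"
                )
    return v


def arc_deltas(plan: TreatmentPlan) -> List[float]:
    """Angular travel (deg, >= 0) between consecutive control points.

    Arc techniques travel along ``arc_direction`` (wrapping across 0°);
    static multi-field plans take the shorter rotation either way.
    """
    out = []
    for i in range(1, len(plan.control_points)):
        a0 = plan.control_points[i - 1].gantry_angle
        a1 = plan.control_points[i].gantry_angle
        if plan.technique in ARC_TECHNIQUES:
            out.append((plan.arc_direction * (a1 - a0)) % 360.0)
        else:
            d = abs(a1 - a0) % 360.0
            out.append(min(d, 360.0 - d))
    return out


def sequence_layers(plan: TreatmentPlan, rule: str = "descending_within_beam") -> DeliverySequence:
    """Build the delivery sequence, ordering layers within each control point.

    ``descending_within_beam`` sorts each control point's layers by strictly
    decreasing energy (cheap down-switches inside a beam), the fast default
    on machines where up-switching dominates. Ties keep input order;
    control-point order is never changed.
    """
    if rule != "descending_within_beam":
        raise ValueError(f"unknown sequencing rule {rule!r}")
    entries: List[Tuple[int, int, float]] = []
    for i, cp in enumerate(plan.control_points):
        order = sorted(range(len(cp.layers)), key=lambda j: -cp.layers[j].energy)
        entries.extend((i, j, cp.layers[j].energy) for j in order)
    return DeliverySequence(entries)


def count_energy_up_switches(seq: DeliverySequence) -> int:
    """Number of adjacent transitions to a strictly higher energy."""
    if not seq.entries:
        raise ValueError("empty delivery sequence")
    e = seq.energies
    return sum(1 for a, b in zip(e, e[1:]) if b > a)


def count_energy_down_switches(seq: DeliverySequence) -> int:
    e = seq.energies
    return sum(1 for a, b in zip(e, e[1:]) if b < a)


# ---------------------------------------------------------------------------
# JSON round trip


def plan_to_dict(plan: TreatmentPlan) -> dict:
    return {
        "technique": plan.technique,
        "arc_direction": plan.arc_direction,
        "metadata": dict(plan.metadata),
        "control_points": [
            {
                "gantry_angle": cp.gantry_angle,
                "angular_window": cp.angular_window,
                "range_shifter": cp.range_shifter,
                "snout_motion_required": cp.snout_motion_required,
                "layers": [
                    {
                        "energy": layer.energy,
                        "spots": [{"x": s.x, "y": s.y, "mu": s.mu} for s in layer.spots],
                    }
                    for layer in cp.layers
                ],
            }
            for cp in plan.control_points
        ],
    }


def plan_from_dict(d: dict) -> TreatmentPlan:
    technique = d.get("technique")
    if technique not in TECHNIQUES:
        raise ValueError(f"unknown technique {technique!r}")
    cps = [
        ControlPoint(
            gantry_angle=float(c["gantry_angle"]),
            angular_window=float(c["angular_window"]),
            range_shifter=bool(c.get("range_shifter", False)),
            snout_motion_required=bool(c.get("snout_motion_required", False)),
            layers=[
                EnergyLayer(
                    energy=float(l["energy"]),
                    spots=[Spot(float(s["x"]), float(s["y"]), float(s["mu"])) for s in l["spots"]],
                )
                for l in c["layers"]
            ],
        )
        for c in d["control_points"]
    ]
    return TreatmentPlan(
        technique=technique,
        control_points=cps,
        arc_direction=int(d.get("arc_direction", 1)),
        metadata=dict(d.get("metadata", {})),
    )


def write_plan(plan: TreatmentPlan, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(plan_to_dict(plan), fh, indent=1)


def read_plan(path) -> TreatmentPlan:
    with open(path, encoding="utf-8") as fh:
        return plan_from_dict(json.load(fh))
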