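"""Machine timing constants and gantry kinematic limits.

The default timing constants below are illustrative placeholders for
simulation and round-trip testing only — they are NOT calibrated to any
clinical delivery system (calibrated vendor constants are unpublished).
The gantry kinematics defaults (0.6 deg/s^2, 6.0 deg/s) are the published
limits of the modelled gantry class.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

__all__ = ["MachineModel"]


@dataclass
class MachineModel:
    spot_time_per_mu: float = 5.0      # ms per MU (linear beam-on time)
    spot_time_min: float = 2.0         # ms, per-spot floor
    spot_switch_time: float = 2.0      # ms between spots within a layer
    energy_up_switch_time: float = 6.0     # s, switch to higher energy
    energy_down_switch_time: float = 0.8   # s, switch to lower energy
    gantry_acceleration: float = 0.6   # deg/s^2
    gantry_vmax: float = 6.0           # deg/s
    rs_field_time_static_fields: float = 60.0  # s per range-shifter field (snout moved)
    rs_field_time_static_arc: float = 30.0     # s per range-shifter field (no snout motion)

    def __post_init__(self) -> None:
        strictly_positive = (
            "spot_time_per_mu",
            "spot_switch_time",
            "energy_up_switch_time",
            "energy_down_switch_time",
            "gantry_acceleration",
            "gantry_vmax",
            "rs_field_time_static_fields",
            "rs_field_time_static_arc",
        )
        for name in strictly_positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.spot_time_min < 0:
            raise ValueError(f"spot_time_min must be >= 0, got {self.spot_time_min!r}")
        if self.energy_up_switch_time < self.energy_down_switch_time:
            raise ValueError("energy_up_switch_time must be >= energy_down_switch_time")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MachineModel":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown machine config fields: {sorted(unknown)}")
        return cls(**data)
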