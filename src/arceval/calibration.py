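"""Estimate machine timing constants from timestamped delivery logs.

The log is a CSV event stream (``timestamp, event_type, energy, mu,
control_point_index``) with paired ``spot_start``/``spot_end``,
``layer_start``/``layer_end`` and ``energy_switch_start``/``end`` events.
From it we estimate the five timing constants of the beam-time model:

* ``spot_time_per_mu`` and ``spot_time_min`` — spot duration is
  ``max(slope * MU, floor)``, a hinge in MU. The two are disentangled by an
  iterative hinge fit: classify each spot as floor-limited or MU-limited
  under the current estimates, refit the slope (through-origin least
  squares on MU-limited spots) and the floor (mean duration of
  floor-limited spots), and repeat to a fixed point. This is exact on
  noiseless logs and unbiased when timestamp jitter is comparable to the
  floor itself, where a fixed censoring window around the minimum observed
  duration is not.
* ``spot_switch_time`` — mean gap between consecutive spots in a layer.
* ``energy_up_switch_time`` / ``energy_down_switch_time`` — 10% trimmed
  mean of switch durations, split by direction (destination energy vs. the
  preceding layer's energy). A direction never observed is reported absent
  rather than guessed.

`DeliveryTimingModel(events).fit()` returns a
:class:`TimingCalibrationResults` with ``params`` (same names and units as
:class:`~arceval.machine.MachineModel`), standard errors ``bse``, and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .machine import MachineModel

__all__ = [
    "DeliveryLogEvent",
    "parse_delivery_log",
    "DeliveryTimingModel",
    "TimingCalibrationResults",
    "calibrate_timing_model",
]

EVENT_TYPES = (
    "spot_start",
    "spot_end",
    "layer_start",
    "layer_end",
    "energy_switch_start",
    "energy_switch_end",
)
_PAIRS = {
    "spot_end": "spot_start",
    "layer_end": "layer_start",
    "energy_switch_end": "energy_switch_start",
}


@dataclass(frozen=True)
class DeliveryLogEvent:
    timestamp: float
    event_type: str
    energy: float
    mu: float  # NaN for non-spot events
    control_point_index: int


class LogFormatError(ValueError):
    pass


def parse_delivery_log(path) -> List[DeliveryLogEvent]:
    """Read and validate a delivery-log CSV; errors carry the 1-based line."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    required = ["timestamp", "event_type", "energy", "mu", "control_point_index"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LogFormatError(f"log is missing columns {missing}")
    events: List[DeliveryLogEvent] = []
    open_stack: List[str] = []
    prev_ts = -math.inf
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        etype = row.event_type
        if etype not in EVENT_TYPES:
            raise LogFormatError(f"line {line}: unknown event type {etype!r}")
        ts = float(row.timestamp)
        if ts < prev_ts:
            raise LogFormatError(f"line {line}: timestamp {ts} decreases")
        prev_ts = ts
        if etype in _PAIRS:
            if not open_stack or open_stack[-1] != _PAIRS[etype]:
                raise LogFormatError(f"line {line}: {etype} without matching {_PAIRS[etype]}")
            open_stack.pop()
        elif etype.endswith("_start"):
            open_stack.append(etype)
        events.append(
            DeliveryLogEvent(
                timestamp=ts,
                event_type=etype,
                energy=float(row.energy),
                mu=float(row.mu) if not pd.isna(row.mu) else math.nan,
                control_point_index=int(row.control_point_index),
            )
        )
    if open_stack:
        raise LogFormatError(f"log ends with unclosed {open_stack[-1]} event")
    return events


def events_to_frame(events: Sequence[DeliveryLogEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": [e.timestamp for e in events],
            "event_type": [e.event_type for e in events],
            "energy": [e.energy for e in events],
            "mu": [e.mu for e in events],
            "control_point_index": [e.control_point_index for e in events],
        }
    )


@dataclass
class TimingCalibrationResults:
    """Fit results; ``params``/``bse`` use MachineModel field names and units."""

    params: Dict[str, Optional[float]]
    bse: Dict[str, Optional[float]]
    nobs: Dict[str, int]
    n_events: int

    def to_machine_model(self, **overrides) -> MachineModel:
        """Build a MachineModel from the estimates. A parameter the fit
        reported absent must be supplied via ``overrides`` — it is never
        silently replaced by a default."""
        missing = [k for k, v in self.params.items() if v is None and k not in overrides]
        if missing:
            raise ValueError(
                f"calibration left parameters absent: {missing}; supply them explicitly"
            )
        kwargs = {k: v for k, v in self.params.items() if v is not None}
        kwargs.update(overrides)
        return MachineModel(**kwargs)

    def summary(self) -> str:
        lines = [
            "Delivery timing calibration",
            f"{'parameter':28s}{'estimate':>12s}{'std err':>12s}{'n':>8s}",
        ]
        units = {
            "spot_time_per_mu": "ms/MU",
            "spot_time_min": "ms",
            "spot_switch_time": "ms",
            "energy_up_switch_time": "s",
            "energy_down_switch_time": "s",
        }
        for name, unit in units.items():
            est = self.params.get(name)
            se = self.bse.get(name)
            n = self.nobs.get(name, 0)
            est_s = "absent" if est is None else f"{est:.6g}"
            se_s = "" if se is None else f"{se:.3g}"
            lines.append(f"{name + ' (' + unit + ')':28s}{est_s:>12s}{se_s:>12s}{n:>8d}")
        lines.append(f"events used: {self.n_events}")
        return "\n".join(lines)


class DeliveryTimingModel:
    """Timing-constant estimation problem built from a delivery-log event list."""

    def __init__(self, events: Sequence[DeliveryLogEvent]):
        self.events = list(events)

    @classmethod
    def from_csv(cls, path) -> "DeliveryTimingModel":
        return cls(parse_delivery_log(path))

    # -- observation extraction -------------------------------------------

    def _observations(self):
        spot_durations: List[float] = []   # ms
        spot_mus: List[float] = []
        spot_gaps: List[float] = []        # ms
        up_durations: List[float] = []     # s
        down_durations: List[float] = []   # s

        spot_open: Optional[DeliveryLogEvent] = None
        switch_open: Optional[DeliveryLogEvent] = None
        last_spot_end: Optional[float] = None
        last_layer_energy: Optional[float] = None

        for e in self.events:
            if e.event_type == "spot_start":
                if last_spot_end is not None:
                    spot_gaps.append((e.timestamp - last_spot_end) * 1000.0)
                spot_open = e
            elif e.event_type == "spot_end":
                assert spot_open is not None
                spot_durations.append((e.timestamp - spot_open.timestamp) * 1000.0)
                spot_mus.append(spot_open.mu)
                last_spot_end = e.timestamp
                spot_open = None
            elif e.event_type == "layer_start":
                last_spot_end = None  # gaps only within a layer
            elif e.event_type == "layer_end":
                last_layer_energy = e.energy
                last_spot_end = None
            elif e.event_type == "energy_switch_start":
                switch_open = e
            elif e.event_type == "energy_switch_end":
                assert switch_open is not None
                dur = e.timestamp - switch_open.timestamp
                if last_layer_energy is not None:
                    if e.energy > last_layer_energy:
                        up_durations.append(dur)
                    elif e.energy < last_layer_energy:
                        down_durations.append(dur)
                switch_open = None
        return (
            np.asarray(spot_durations),
            np.asarray(spot_mus),
            np.asarray(spot_gaps),
            np.asarray(up_durations),
            np.asarray(down_durations),
        )

    @staticmethod
    def _hinge_fit(mu: np.ndarray, dur: np.ndarray, max_iter: int = 50):
        """Fit dur = max(slope*mu, floor); returns (slope, floor, se_slope,
        se_floor, n_slope, n_floor). floor is None if no spot is floor-limited."""
        order = np.argsort(mu)
        mu, dur = mu[order], dur[order]
        n = len(mu)
        hi = mu >= np.quantile(mu, 0.5)
        slope = float(np.sum(mu[hi] * dur[hi]) / np.sum(mu[hi] ** 2))
        floor = float(np.mean(dur[mu <= np.quantile(mu, 0.1)]))
        is_floor = np.zeros(n, dtype=bool)
        for _ in range(max_iter):
            new_floor_mask = mu * slope < floor
            if new_floor_mask.sum() == 0 or (~new_floor_mask).sum() == 0:
                is_floor = new_floor_mask
                break
            if np.array_equal(new_floor_mask, is_floor):
                break
            is_floor = new_floor_mask
            m, d = mu[~is_floor], dur[~is_floor]
            slope = float(np.sum(m * d) / np.sum(m * m))
            floor = float(np.mean(dur[is_floor]))
        n_floor = int(is_floor.sum())
        n_slope = n - n_floor
        m, d = mu[~is_floor], dur[~is_floor]
        resid = d - slope * m
        se_slope = (
            float(np.sqrt(np.sum(resid**2) / max(n_slope - 1, 1) / np.sum(m * m)))
            if n_slope > 1
            else 0.0
        )
        if n_floor == 0:
            return slope, None, se_slope, None, n_slope, 0
        floor_d = dur[is_floor]
        se_floor = float(np.std(floor_d, ddof=1) / math.sqrt(n_floor)) if n_floor > 1 else 0.0
        return slope, floor, se_slope, se_floor, n_slope, n_floor

    @staticmethod
    def _trimmed(x: np.ndarray, trim: float = 0.1):
        est = float(stats.trim_mean(x, trim))
        se = float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
        return est, se

    def fit(self) -> TimingCalibrationResults:
        dur, mu, gaps, ups, downs = self._observations()
        if len(dur) < 2:
            raise ValueError("calibration requires at least 2 delivered spots")

        params: Dict[str, Optional[float]] = {}
        bse: Dict[str, Optional[float]] = {}
        nobs: Dict[str, int] = {}

        slope, floor, se_s, se_f, n_s, n_f = self._hinge_fit(mu, dur)
        params["spot_time_per_mu"] = slope
        bse["spot_time_per_mu"] = se_s
        nobs["spot_time_per_mu"] = n_s
        params["spot_time_min"] = floor
        bse["spot_time_min"] = se_f
        nobs["spot_time_min"] = n_f

        if len(gaps):
            est = float(np.mean(gaps))
            se = float(np.std(gaps, ddof=1) / math.sqrt(len(gaps))) if len(gaps) > 1 else 0.0
            params["spot_switch_time"], bse["spot_switch_time"] = est, se
        else:
            params["spot_switch_time"] = bse["spot_switch_time"] = None
        nobs["spot_switch_time"] = len(gaps)

        for name, arr in (("energy_up_switch_time", ups), ("energy_down_switch_time", downs)):
            if len(arr):
                params[name], bse[name] = self._trimmed(arr)
            else:
                params[name] = bse[name] = None
            nobs[name] = len(arr)

        return TimingCalibrationResults(
            params=params, bse=bse, nobs=nobs, n_events=len(self.events)
        )


def calibrate_timing_model(events: Sequence[DeliveryLogEvent]) -> TimingCalibrationResults:
    """Functional wrapper around :class:`DeliveryTimingModel`."""
    return DeliveryTimingModel(events).fit()
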