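"""Scenario-based robust dose evaluation.

The standard evaluation set crosses 14 setup-shift directions (the 6 face
and 8 corner directions of the setup sphere, scaled to the setup
magnitude) with the two density scalings {1 - f, 1 + f}, giving 28
scenarios. Robust coverage is read off the voxel-wise minimum over the
scenario doses (D98 as %Dp and V95 of the prescribed dose per target).
Fraction-wise evaluation repeats this per weekly anatomy; course-wise
evaluation warps each repeat-CT scenario dose to the planning frame,
accumulates matching scenarios across weeks with fraction weights, and
takes the voxel-wise minimum of the accumulated doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Protocol, Sequence

import numpy as np
from scipy import ndimage

from .dose import compute_dvh, dose_at_volume, volume_at_dose
from .grid import DeformationField, DoseGrid, GeometryError, RoiMask

__all__ = [
    "Scenario",
    "ScenarioSet",
    "VwMinResult",
    "generate_scenarios",
    "scenario_dose",
    "voxelwise_min",
    "fraction_robustness",
    "warp_dose",
    "accumulate_course",
]


@dataclass(frozen=True)
class Scenario:
    setup_shift: tuple  # mm, 3-vector
    density_scale: float

    @property
    def shift_magnitude(self) -> float:
        return float(np.linalg.norm(self.setup_shift))


NOMINAL = Scenario(setup_shift=(0.0, 0.0, 0.0), density_scale=1.0)


@dataclass
class ScenarioSet:
    scenarios: List[Scenario]
    setup_mm: float
    density_fraction: float

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)


_FACE_DIRECTIONS = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
]
_CORNER_DIRECTIONS = [
    (sx, sy, sz) for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)
]


def generate_scenarios(setup_mm: float, density_fraction: float) -> ScenarioSet:
    """The 28-scenario evaluation set: (6 faces + 8 corners) x 2 densities.

    Every shift has magnitude ``setup_mm`` (corner directions are
    normalised); order is deterministic (faces then corners, low density
    scale before high within each direction).
    """
    if setup_mm < 0 or density_fraction < 0:
        raise ValueError("setup_mm and density_fraction must be >= 0")
    dirs = [np.asarray(d, dtype=float) for d in _FACE_DIRECTIONS] + [
        np.asarray(d, dtype=float) / np.sqrt(3.0) for d in _CORNER_DIRECTIONS
    ]
    scenarios = [
        Scenario(setup_shift=tuple(setup_mm * d), density_scale=scale)
        for d in dirs
        for scale in (1.0 - density_fraction, 1.0 + density_fraction)
    ]
    return ScenarioSet(scenarios=scenarios, setup_mm=setup_mm, density_fraction=density_fraction)


class PerturbableDoseSource(Protocol):
    """Anything that can produce a dose grid under a setup/density scenario."""

    def dose(self, scenario: Scenario) -> DoseGrid: ...


def scenario_dose(engine: PerturbableDoseSource, scenario: Scenario) -> DoseGrid:
    """Dose under one scenario (the nominal scenario returns the nominal dose)."""
    return engine.dose(scenario)


def voxelwise_min(doses: Sequence[DoseGrid]) -> DoseGrid:
    """Element-wise minimum over >= 1 dose grids on a common geometry."""
    if not doses:
        raise ValueError("voxelwise_min requires at least one dose grid")
    first = doses[0]
    for d in doses[1:]:
        first.require_same_geometry(d, "scenario dose grids")
    vals = np.minimum.reduce([d.values for d in doses])
    return DoseGrid(values=vals, origin=first.origin, spacing=first.spacing)


@dataclass
class VwMinResult:
    """Voxel-wise minimum dose with per-target coverage metrics.

    ``target_metrics`` maps target name -> {"D98_pctDp": D98 of the vwmin
    dose as % of that target's prescription, "V95_pct": % of the target
    receiving >= 95% of its prescription in the vwmin dose}.
    """

    vwmin: DoseGrid
    target_metrics: Dict[str, Dict[str, float]]
    n_scenarios: int
    metadata: dict = field(default_factory=dict)


def _coverage_metrics(
    vwmin: DoseGrid, targets: Sequence[RoiMask], dp: Mapping[str, float]
) -> Dict[str, Dict[str, float]]:
    out: Dict[str, Dict[str, float]] = {}
    for roi in targets:
        prescription = dp[roi.name]
        dvh = compute_dvh(vwmin, roi)
        out[roi.name] = {
            "D98_pctDp": dose_at_volume(dvh, 98.0) / prescription * 100.0,
            "V95_pct": volume_at_dose(dvh, 0.95 * prescription),
        }
    return out


def fraction_robustness(
    engine: PerturbableDoseSource,
    scenarios: ScenarioSet,
    targets: Sequence[RoiMask],
    dp: Mapping[str, float],
) -> VwMinResult:
    """Evaluate all scenarios on one anatomy and summarise the vwmin dose."""
    doses = [scenario_dose(engine, s) for s in scenarios]
    vw = voxelwise_min(doses)
    return VwMinResult(
        vwmin=vw,
        target_metrics=_coverage_metrics(vw, targets, dp),
        n_scenarios=len(scenarios),
    )


def warp_dose(dose: DoseGrid, dfield: DeformationField) -> DoseGrid:
    """Pull a repeat-anatomy dose back onto the planning grid.

    result(x) = dose(x + u(x)), trilinear interpolation, 0 Gy outside the
    grid; the number of out-of-grid samples is recorded on the result's
    ``metadata`` attribute by callers that need it.
    """
    dose.require_same_geometry(dfield, "dose grid and deformation field")
    nx, ny, nz = dose.shape
    idx = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    spacing = np.asarray(dose.spacing)
    coords = [
        idx[k] + dfield.values[..., k] / spacing[k] for k in range(3)
    ]
    warped = ndimage.map_coordinates(
        dose.values, coords, order=1, mode="constant", cval=0.0
    )
    return DoseGrid(values=warped, origin=dose.origin, spacing=dose.spacing)


def accumulate_course(
    per_rct_scenario_doses: Sequence[Sequence[DoseGrid]],
    weights: Sequence[float],
    targets: Sequence[RoiMask],
    dp: Mapping[str, float],
) -> VwMinResult:
    """Course-wise evaluation from already-warped per-rCT scenario doses.

    Scenario s of week k is matched with scenario s of every other week
    (worst-case-correlated pairing): accumulated_s = Σ_k w_k · dose[k][s];
    the voxel-wise minimum is taken over the accumulated scenarios.
    Weights are per-rCT fraction shares and must sum to 1.
    """
    if not per_rct_scenario_doses:
        raise ValueError("accumulate_course requires at least one rCT")
    n_scen = len(per_rct_scenario_doses[0])
    if any(len(week) != n_scen for week in per_rct_scenario_doses):
        raise ValueError("all rCTs must contribute the same number of scenario doses")
    if len(weights) != len(per_rct_scenario_doses):
        raise ValueError("one weight per rCT required")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {sum(weights)}")

    ref = per_rct_scenario_doses[0][0]
    accumulated = []
    for s in range(n_scen):
        acc = np.zeros_like(ref.values)
        for w, week in zip(weights, per_rct_scenario_doses):
            ref.require_same_geometry(week[s], "accumulated scenario doses")
            acc += w * week[s].values
        accumulated.append(DoseGrid(values=acc, origin=ref.origin, spacing=ref.spacing))
    vw = voxelwise_min(accumulated)
    return VwMinResult(
        vwmin=vw,
        target_metrics=_coverage_metrics(vw, targets, dp),
        n_scenarios=n_scen,
    )
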