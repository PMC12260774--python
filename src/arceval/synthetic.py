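"""Synthetic phantoms, plans, dose engines, weekly anatomies and logs.

Everything the evaluation pipeline consumes can be generated here as a
pure function of (config, seed): a head-and-neck-like digital phantom with
nested targets and the standard OAR inventory; technique-specific plans
whose layer/spot structure matches the magnitudes of published
static/dynamic arc and IMPT plans; a parametric-geometric dose engine
(sigmoid falloff around the target surfaces — not a physics dose model)
with exact response hooks for setup shifts and density scaling; weekly
perturbed anatomies with known ground-truth deformation fields; and
timestamped delivery logs generated from known timing constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .delivery import energy_switch_time
from .grid import DeformationField, DoseGrid, RoiMask
from .machine import MachineModel
from .plan import ControlPoint, EnergyLayer, Spot, TreatmentPlan, sequence_layers
from .robustness import NOMINAL, Scenario

__all__ = [
    "PhantomConfig",
    "Phantom",
    "make_phantom",
    "PLAN_TECHNIQUES",
    "make_plan",
    "EngineConfig",
    "SyntheticDoseEngine",
    "make_dose",
    "AnatomySeries",
    "WeeklyAnatomy",
    "make_anatomy_series",
    "make_delivery_log",
    "make_delivery_events",
]


# ---------------------------------------------------------------------------
# Phantom


@dataclass
class PhantomConfig:
    shape: Tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 3.0
    ctv7000_radius_mm: float = 25.0
    ctv7000_center_mm: Tuple[float, float, float] = (10.0, 0.0, 0.0)
    ctv5425_semiaxes_mm: Tuple[float, float, float] = (45.0, 35.0, 55.0)
    ctv5425_center_mm: Tuple[float, float, float] = (5.0, 0.0, 0.0)
    body_semiaxes_mm: Tuple[float, float, float] = (90.0, 80.0, 1e6)
    density_noise_sd: float = 0.02


@dataclass
class Phantom:
    density: DoseGrid  # relative density (water = 1), reusing the grid container
    masks: Dict[str, RoiMask]
    config: PhantomConfig
    seed: int

    @property
    def grid_shape(self):
        return self.density.shape


def _coordinate_grids(config: PhantomConfig):
    """Voxel-centre physical coordinates (mm), origin at the grid centre."""
    sp = config.spacing_mm
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * sp for n in config.shape
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(xs, ys, zs, center, semiaxes) -> np.ndarray:
    return (
        ((xs - center[0]) / semiaxes[0]) ** 2
        + ((ys - center[1]) / semiaxes[1]) ** 2
        + ((zs - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _sphere(xs, ys, zs, center, radius) -> np.ndarray:
    return _ellipsoid(xs, ys, zs, center, (radius, radius, radius))


def make_phantom(config: Optional[PhantomConfig] = None, seed: int = 0) -> Phantom:
    """Deterministic head-and-neck-like phantom with nested target masks.

    Guarantees CTV7000 ⊂ CTV5425 ⊂ body and all OARs ⊂ body by
    construction (set operations after voxelisation).
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    xs, ys, zs = _coordinate_grids(config)
    sp = config.spacing_mm
    origin = tuple((-(n - 1) / 2.0) * sp for n in config.shape)
    spacing = (sp, sp, sp)

    body = _ellipsoid(xs, ys, zs, (0, 0, 0), config.body_semiaxes_mm)
    ctv7000 = _sphere(xs, ys, zs, config.ctv7000_center_mm, config.ctv7000_radius_mm)
    ctv5425 = _ellipsoid(xs, ys, zs, config.ctv5425_center_mm, config.ctv5425_semiaxes_mm)
    ctv5425 |= ctv7000
    ctv7000 &= body
    ctv5425 &= body

    oars = {
        "spinal_cord": (np.hypot(xs - 0.0, ys - 55.0) <= 5.0),
        "brainstem": (np.hypot(xs - 0.0, ys - 45.0) <= 8.0) & (zs > 60.0),
        "parotid_ipsi": _sphere(xs, ys, zs, (60.0, 10.0, 20.0), 12.0),
        "parotid_contra": _sphere(xs, ys, zs, (-60.0, 10.0, 20.0), 12.0),
        "submandibular_ipsi": _sphere(xs, ys, zs, (32.0, -25.0, -15.0), 8.0),
        "submandibular_contra": _sphere(xs, ys, zs, (-32.0, -25.0, -15.0), 8.0),
        "pcm_superior": (np.hypot(xs - 0.0, ys - 30.0) <= 10.0) & (zs > 25.0) & (zs <= 60.0),
        "pcm_medius": (np.hypot(xs - 0.0, ys - 30.0) <= 10.0) & (zs > -10.0) & (zs <= 25.0),
        "pcm_inferior": (np.hypot(xs - 0.0, ys - 30.0) <= 10.0) & (zs > -45.0) & (zs <= -10.0),
        "oral_cavity": _sphere(xs, ys, zs, (0.0, -45.0, 15.0), 18.0),
    }

    masks = {
        "body": RoiMask(values=body, origin=origin, spacing=spacing, name="body"),
        "ctv7000": RoiMask(values=ctv7000, origin=origin, spacing=spacing, name="ctv7000"),
        "ctv5425": RoiMask(values=ctv5425, origin=origin, spacing=spacing, name="ctv5425"),
    }
    for name, m in oars.items():
        masks[name] = RoiMask(values=m & body, origin=origin, spacing=spacing, name=name)

    noise = ndimage.gaussian_filter(rng.standard_normal(config.shape), sigma=2.0)
    noise *= config.density_noise_sd / max(noise.std(), 1e-12)
    density = np.where(body, np.clip(1.0 + noise, 0.5, 1.5), 0.0)
    return Phantom(
        density=DoseGrid(values=density, origin=origin, spacing=spacing),
        masks=masks,
        config=config,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Plans


PLAN_TECHNIQUES = ("impt", "elf_30b", "elf_10b", "elf_30b_rs", "elsa", "sparc")

_DEFAULT_LAYERS = {
    "impt": 194,
    "elf_30b": 360,
    "elf_10b": 240,
    "elf_30b_rs": 360,  # arc layers; +60 range-shifter layers appended
    "elsa": 360,
    "sparc": 360,
}
_SPOTS_PER_LAYER = {
    "impt": 47,
    "elf_30b": 44,
    "elf_10b": 49,
    "elf_30b_rs": 42,
    "elsa": 31,
    "sparc": 40,
}


def _make_layer(rng: np.random.Generator, energy: float, mean_spots: int) -> EnergyLayer:
    n = max(1, int(rng.poisson(mean_spots)))
    xs = rng.normal(0.0, 30.0, n)
    ys = rng.normal(0.0, 30.0, n)
    mus = np.clip(rng.lognormal(-0.4, 0.8, n), 0.02, 6.0)
    return EnergyLayer(energy=energy, spots=[Spot(float(x), float(y), float(m)) for x, y, m in zip(xs, ys, mus)])


def _descending_energies(rng, n_layers: int) -> np.ndarray:
    e_max = rng.uniform(200.0, 230.0)
    e_min = rng.uniform(80.0, 110.0)
    return np.linspace(e_max, e_min, n_layers)


def _static_beam(rng, angle: float, n_layers: int, mean_spots: int, rs: bool = False,
                 snout: bool = False) -> ControlPoint:
    energies = _descending_energies(rng, n_layers)
    return ControlPoint(
        gantry_angle=angle,
        angular_window=0.0,
        layers=[_make_layer(rng, float(e), mean_spots) for e in energies],
        range_shifter=rs,
        snout_motion_required=snout,
    )


def make_plan(technique: str, n_layers: Optional[int] = None, seed: int = 0,
              up_switch_target: Optional[int] = None) -> TreatmentPlan:
    """Generate a synthetic plan with the structure of one technique.

    * ``impt`` — 6 static fields (45/160/160/200/200/315°), range shifter
      with snout motion on 4 of them.
    * ``elf_30b`` / ``elf_10b`` — 30/10 equispaced static-arc beams with
      descending energies per beam; every inter-beam transition rises.
    * ``elf_30b_rs`` — the 30-beam arc plus two anterior-oblique
      range-shifter fields (36° and 324°, 30 layers each, no snout motion)
      inserted in monotone arc order; total layers = n_layers + 60.
    * ``elsa`` — dynamic arc, one layer per control point, 1.0° windows
      (>=300 layers) or 1.5° (fewer); ``up_switch_target`` controls how
      many upward energy jumps are placed (default 11).
    * ``sparc`` — dynamic arc, 2.5° windows, 1–5 layers each (descending
      within a window) until ``n_layers`` are placed.
    """
    if technique not in PLAN_TECHNIQUES:
        raise ValueError(f"unknown technique {technique!r}; expected one of {PLAN_TECHNIQUES}")
    rng = np.random.default_rng(seed)
    n_layers = n_layers or _DEFAULT_LAYERS[technique]
    mean_spots = _SPOTS_PER_LAYER[technique]
    meta = {"generator": "arceval.synthetic", "technique": technique, "seed": seed}

    if technique == "impt":
        fields = [(45.0, True), (160.0, True), (160.0, False), (200.0, True), (200.0, False), (315.0, True)]
        per = _split_layers(n_layers, len(fields))
        cps = [
            _static_beam(rng, ang, k, mean_spots, rs=rs, snout=rs)
            for (ang, rs), k in zip(fields, per)
        ]
        return TreatmentPlan("static_fields", cps, metadata=meta)

    if technique in ("elf_30b", "elf_10b", "elf_30b_rs"):
        n_beams = 10 if technique == "elf_10b" else 30
        per = _split_layers(n_layers, n_beams)
        angles = [(6.0 + 12.0 * i) % 360.0 if n_beams == 30 else 36.0 * i for i in range(n_beams)]
        beams = [
            (ang, _static_beam(rng, ang, k, mean_spots)) for ang, k in zip(angles, per)
        ]
        if technique == "elf_30b_rs":
            for ang in (36.0, 324.0):
                beams.append(
                    (ang, _static_beam(rng, ang, 30, mean_spots, rs=True, snout=False))
                )
        beams.sort(key=lambda t: t[0])
        return TreatmentPlan("static_arc", [cp for _, cp in beams], metadata=meta)

    if technique == "elsa":
        window = 1.0 if n_layers >= 300 else 1.5
        n_up = 11 if up_switch_target is None else up_switch_target
        energies = _piecewise_descending(rng, n_layers, n_up)
        spacing = 360.0 / n_layers
        cps = [
            ControlPoint(
                gantry_angle=(i + 0.5) * spacing % 360.0,
                angular_window=window,
                layers=[_make_layer(rng, float(energies[i]), mean_spots)],
            )
            for i in range(n_layers)
        ]
        return TreatmentPlan("dynamic_arc", cps, metadata=meta)

    # sparc
    counts: List[int] = []
    remaining = n_layers
    while remaining > 0:
        c = int(min(rng.integers(1, 6), remaining))
        counts.append(c)
        remaining -= c
    n_cp = len(counts)
    if 360.0 / n_cp < 2.5:
        raise ValueError(f"{n_layers} layers need {n_cp} windows; 2.5° windows would overlap")
    spacing = 360.0 / n_cp
    n_up = 17 if up_switch_target is None else up_switch_target
    # up-jumps only at window boundaries, so every window stays internally
    # descending and the up-switch count is exactly the configured target
    starts = np.cumsum(counts)[:-1]
    n_up = min(n_up, len(starts))
    cuts = np.sort(rng.choice(starts, size=n_up, replace=False))
    energies = _piecewise_descending_at(rng, n_layers, cuts)
    cps = []
    pos = 0
    for i, c in enumerate(counts):
        cps.append(
            ControlPoint(
                gantry_angle=(i + 0.5) * spacing % 360.0,
                angular_window=2.5,
                layers=[_make_layer(rng, float(e), mean_spots) for e in energies[pos : pos + c]],
            )
        )
        pos += c
    return TreatmentPlan("dynamic_arc", cps, metadata=meta)


def _split_layers(total: int, parts: int) -> List[int]:
    base = total // parts
    rem = total - base * parts
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _piecewise_descending_at(rng, n: int, cut_positions: np.ndarray) -> np.ndarray:
    """n energies forming descending runs split at ``cut_positions``."""
    runs = np.split(np.arange(n), cut_positions)
    energies = np.empty(n)
    for run in runs:
        e_hi = rng.uniform(190.0, 230.0)
        e_lo = rng.uniform(80.0, 120.0)
        energies[run] = np.linspace(e_hi, e_lo, len(run))
    return energies


def _piecewise_descending(rng, n: int, n_up: int) -> np.ndarray:
    """n energies forming n_up+1 descending runs (exactly n_up up-jumps)."""
    n_up = max(0, min(n_up, n - 1))
    cuts = (
        np.sort(rng.choice(np.arange(1, n), size=n_up, replace=False))
        if n_up
        else np.array([], dtype=int)
    )
    return _piecewise_descending_at(rng, n, cuts)


# ---------------------------------------------------------------------------
# Dose engine


@dataclass
class EngineConfig:
    prescription_gy: Dict[str, float] = field(
        default_factory=lambda: {"ctv7000": 70.0, "ctv5425": 54.25}
    )
    coverage_margin_mm: float = 8.0     # falloff midpoint distance outside the target
    falloff_mm: float = 2.0             # sigmoid falloff scale
    bath_amplitude: float = 0.12        # low-dose bath peak as a fraction of Dp
    bath_range_mm: float = 60.0         # bath decay length
    ripple_amplitude: float = 0.01      # homogeneity ripple (relative)
    density_range_mm: float = 30.0      # falloff shift per unit density-scale deviation
    # density_scale > 1 (denser patient) pulls the falloff inward: the
    # effective margin is coverage_margin_mm - (scale - 1) * density_range_mm.


_TECHNIQUE_ENGINE_PRESETS = {
    # (bath_amplitude, bath_range_mm, falloff_mm, coverage_margin_mm):
    # arcs spread a lower bath and fall off faster (more conformal) than
    # few-field IMPT; margins keep the 95% isodose past the first voxel
    # shell so conformity is resolved on the default 3 mm grid.
    "impt": (0.25, 80.0, 3.0, 13.0),
    "elf_30b": (0.12, 60.0, 2.0, 9.5),
    "elf_10b": (0.14, 62.0, 2.2, 10.0),
    "elf_30b_rs": (0.13, 60.0, 2.0, 9.5),
    "elsa": (0.13, 62.0, 2.1, 9.8),
    "sparc": (0.12, 61.0, 2.0, 9.5),
}


class SyntheticDoseEngine:
    """Parametric-geometric dose source with exact scenario response hooks.

    The nominal dose is a logistic falloff of each target's prescription
    around its surface (plus a technique-dependent low-dose bath and a
    smooth seeded ripple), evaluated from precomputed signed Euclidean
    distance maps. Scenario hooks: a setup shift translates the dose
    (trilinear resampling; exact for integer-voxel shifts) and a density
    scaling displaces the falloff radially by
    ``(scale - 1) * density_range_mm``. An anatomical (weekly) rigid shift
    and margin offset can be superimposed for repeat-CT emulation.
    """

    def __init__(
        self,
        phantom: Phantom,
        technique: str = "elf_30b",
        config: Optional[EngineConfig] = None,
        seed: int = 0,
        anatomical_shift_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0),
        anatomical_margin_delta_mm: float = 0.0,
    ):
        if config is None:
            config = EngineConfig()
            if technique in _TECHNIQUE_ENGINE_PRESETS:
                bath, rng_mm, falloff, margin = _TECHNIQUE_ENGINE_PRESETS[technique]
                config = replace(
                    config,
                    bath_amplitude=bath,
                    bath_range_mm=rng_mm,
                    falloff_mm=falloff,
                    coverage_margin_mm=margin,
                )
        self.phantom = phantom
        self.technique = technique
        self.config = config
        self.seed = seed
        self.anatomical_shift_mm = tuple(anatomical_shift_mm)
        self.anatomical_margin_delta_mm = float(anatomical_margin_delta_mm)

        sp = phantom.density.spacing
        self._signed_dist = {}
        for name in config.prescription_gy:
            m = phantom.masks[name].values
            outside = ndimage.distance_transform_edt(~m, sampling=sp)
            inside = ndimage.distance_transform_edt(m, sampling=sp)
            self._signed_dist[name] = outside - inside  # >0 outside the target
        body = phantom.masks["body"].values
        self._body = body
        rng = np.random.default_rng(seed)
        ripple = ndimage.gaussian_filter(rng.standard_normal(phantom.grid_shape), sigma=4.0)
        self._ripple = 1.0 + config.ripple_amplitude * ripple / max(ripple.std(), 1e-12)
        self._nominal_cache: Optional[DoseGrid] = None

    # -- internals ---------------------------------------------------------

    def _field_values(self, margin_delta_mm: float) -> np.ndarray:
        c = self.config
        m_eff = c.coverage_margin_mm + margin_delta_mm
        dose = np.zeros(self.phantom.grid_shape)
        dp_max = max(c.prescription_gy.values())
        for name, dp in c.prescription_gy.items():
            d = self._signed_dist[name]
            term = dp / (1.0 + np.exp((d - m_eff) / c.falloff_mm))
            bath = c.bath_amplitude * dp_max * np.exp(-np.maximum(d, 0.0) / c.bath_range_mm)
            dose = np.maximum(dose, np.maximum(term, bath))
        dose *= self._ripple
        dose[~self._body] *= 0.05  # residual transmission outside the body contour
        return dose

    def _translate(self, values: np.ndarray, shift_mm: np.ndarray) -> np.ndarray:
        if not np.any(shift_mm):
            return values
        sp = np.asarray(self.phantom.density.spacing)
        nx, ny, nz = values.shape
        idx = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        coords = [idx[k] - shift_mm[k] / sp[k] for k in range(3)]
        return ndimage.map_coordinates(values, coords, order=1, mode="constant", cval=0.0)

    # -- public API --------------------------------------------------------

    def dose(self, scenario: Scenario = NOMINAL) -> DoseGrid:
        """Dose under a setup/density scenario (nominal is cached, bit-exact)."""
        nominal = (
            not np.any(np.asarray(scenario.setup_shift))
            and scenario.density_scale == 1.0
            and not np.any(np.asarray(self.anatomical_shift_mm))
            and self.anatomical_margin_delta_mm == 0.0
        )
        if nominal and self._nominal_cache is not None:
            return self._nominal_cache
        margin_delta = (
            -(scenario.density_scale - 1.0) * self.config.density_range_mm
            + self.anatomical_margin_delta_mm
        )
        values = self._field_values(margin_delta)
        shift = np.asarray(scenario.setup_shift) + np.asarray(self.anatomical_shift_mm)
        values = self._translate(values, shift)
        grid = DoseGrid(
            values=np.maximum(values, 0.0),
            origin=self.phantom.density.origin,
            spacing=self.phantom.density.spacing,
        )
        if nominal:
            self._nominal_cache = grid
        return grid

    def with_anatomy(self, shift_mm, margin_delta_mm: float) -> "SyntheticDoseEngine":
        """Derived engine for a perturbed weekly anatomy (shares distance maps)."""
        clone = SyntheticDoseEngine.__new__(SyntheticDoseEngine)
        clone.__dict__.update(self.__dict__)
        clone.anatomical_shift_mm = tuple(shift_mm)
        clone.anatomical_margin_delta_mm = float(margin_delta_mm)
        clone._nominal_cache = None
        return clone


def make_dose(
    phantom: Phantom,
    technique: str = "elf_30b",
    config: Optional[EngineConfig] = None,
    seed: int = 0,
) -> SyntheticDoseEngine:
    return SyntheticDoseEngine(phantom, technique=technique, config=config, seed=seed)


# ---------------------------------------------------------------------------
# Weekly anatomy series


@dataclass
class WeeklyAnatomy:
    week: int
    shoulder_shift_mm: Tuple[float, float, float]
    surface_regression_mm: float
    density_delta: float
    deformation: DeformationField

    def margin_delta_mm(self, engine_config: EngineConfig) -> float:
        # density increase and surface regression both pull the falloff inward
        return (
            -self.density_delta * engine_config.density_range_mm
            - self.surface_regression_mm
        )


@dataclass
class AnatomySeriesConfig:
    n_weeks: int = 7
    shoulder_shift_sd_mm: Tuple[float, float, float] = (2.0, 0.5, 2.0)
    surface_regression_mm_per_week: float = 0.3
    density_delta_sd: float = 0.005


@dataclass
class AnatomySeries:
    planning: Phantom
    weeks: List[WeeklyAnatomy]

    def engines(self, base_engine: SyntheticDoseEngine) -> List[SyntheticDoseEngine]:
        return [
            base_engine.with_anatomy(w.shoulder_shift_mm, w.margin_delta_mm(base_engine.config))
            for w in self.weeks
        ]


def make_anatomy_series(
    phantom: Phantom,
    n_weeks: int = 7,
    config: Optional[AnatomySeriesConfig] = None,
    seed: int = 0,
) -> AnatomySeries:
    """Weekly repeat anatomies as perturbation parameters plus ground-truth
    deformation fields (constant vector fields for the rigid shoulder-like
    shifts modelled here). Week numbering starts at 1; the planning anatomy
    itself (week 0, identity field) is the ``planning`` phantom.
    """
    config = config or AnatomySeriesConfig(n_weeks=n_weeks)
    n_weeks = config.n_weeks
    rng = np.random.default_rng(seed)
    origin, spacing = phantom.density.origin, phantom.density.spacing
    shape = phantom.grid_shape
    weeks = []
    for w in range(1, n_weeks + 1):
        shift = tuple(rng.normal(0.0, sd) for sd in config.shoulder_shift_sd_mm)
        regression = config.surface_regression_mm_per_week * w
        ddelta = float(rng.normal(0.0, config.density_delta_sd))
        fld = np.empty(shape + (3,))
        fld[...] = np.asarray(shift)
        weeks.append(
            WeeklyAnatomy(
                week=w,
                shoulder_shift_mm=shift,
                surface_regression_mm=regression,
                density_delta=ddelta,
                deformation=DeformationField(values=fld, origin=origin, spacing=spacing),
            )
        )
    return AnatomySeries(planning=phantom, weeks=weeks)


# ---------------------------------------------------------------------------
# Delivery logs


def make_delivery_events(
    plan: TreatmentPlan,
    machine: MachineModel,
    jitter_sd_ms: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Timestamped event stream for auto-sequenced delivery of ``plan``.

    Jitter is drawn independently per interval (truncated at 0 so
    timestamps stay monotone) and the cumulative sum forms the clock. With
    zero jitter the total elapsed time equals the static simulator's
    beam-on + spot-switch + energy-switch components exactly (the log
    contains no gantry-motion or range-shifter intervals).
    """
    rng = np.random.default_rng(seed)
    seq = sequence_layers(plan)

    def dur(ms: float) -> float:
        if jitter_sd_ms > 0:
            ms = max(0.0, ms + rng.normal(0.0, jitter_sd_ms))
        return ms / 1000.0

    rows = []
    t = 0.0
    prev_energy: Optional[float] = None
    for cp_idx, layer_idx, energy in seq.entries:
        layer = plan.control_points[cp_idx].layers[layer_idx]
        if prev_energy is not None and energy != prev_energy:
            sw = energy_switch_time(prev_energy, energy, machine)
            rows.append((t, "energy_switch_start", energy, np.nan, cp_idx))
            t += max(0.0, sw + (rng.normal(0.0, jitter_sd_ms) / 1000.0 if jitter_sd_ms > 0 else 0.0))
            rows.append((t, "energy_switch_end", energy, np.nan, cp_idx))
        rows.append((t, "layer_start", energy, np.nan, cp_idx))
        for k, spot in enumerate(layer.spots):
            if k > 0:
                t += dur(machine.spot_switch_time)
            rows.append((t, "spot_start", energy, spot.mu, cp_idx))
            t += dur(max(spot.mu * machine.spot_time_per_mu, machine.spot_time_min))
            rows.append((t, "spot_end", energy, spot.mu, cp_idx))
        rows.append((t, "layer_end", energy, np.nan, cp_idx))
        prev_energy = energy
    return pd.DataFrame(
        rows, columns=["timestamp", "event_type", "energy", "mu", "control_point_index"]
    )


def make_delivery_log(
    plan: TreatmentPlan,
    machine: MachineModel,
    jitter_sd_ms: float = 0.0,
    seed: int = 0,
    path=None,
) -> pd.DataFrame:
    """Event stream as a DataFrame; written as CSV when ``path`` is given."""
    df = make_delivery_events(plan, machine, jitter_sd_ms=jitter_sd_ms, seed=seed)
    if path is not None:
        df.to_csv(path, index=False)
    return df
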