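import numpy as np
import pytest

from arceval.grid import DoseGrid, RoiMask
from arceval.machine import MachineModel
from arceval.plan import ControlPoint, EnergyLayer, Spot, TreatmentPlan
from arceval.synthetic import PhantomConfig, make_phantom


@pytest.fixture
def machine() -> MachineModel:
    return MachineModel()


def make_layer(energy: float, mus, x0: float = 0.0) -> EnergyLayer:
    return EnergyLayer(
        energy=energy, spots=[Spot(x0 + i, 0.0, float(m)) for i, m in enumerate(mus)]
    )


def make_static_beam(angle: float, energies, mus_per_layer=(1.0,), rs: bool = False,
                     snout: bool = False) -> ControlPoint:
    return ControlPoint(
        gantry_angle=angle,
        angular_window=0.0,
        layers=[make_layer(e, mus_per_layer) for e in energies],
        range_shifter=rs,
        snout_motion_required=snout,
    )


def make_dynamic_cp(angle: float, window: float, energies, mus_per_layer=(1.0,)) -> ControlPoint:
    return ControlPoint(
        gantry_angle=angle,
        angular_window=window,
        layers=[make_layer(e, mus_per_layer) for e in energies],
    )


@pytest.fixture
def two_beam_plan() -> TreatmentPlan:
    return TreatmentPlan(
        technique="static_fields",
        control_points=[
            make_static_beam(45.0, [150.0, 120.0]),
            make_static_beam(315.0, [160.0, 130.0]),
        ],
    )


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse phantom for pipeline tests (fast, still resolves all ROIs)."""
    return make_phantom(PhantomConfig(shape=(32, 32, 32), spacing_mm=6.0), seed=11)


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(seed=3)


def random_dose_and_mask(rng, shape=(8, 8, 8), spacing=(2.0, 2.0, 2.0), max_dose=80.0):
    values = rng.uniform(0.0, max_dose, shape)
    mask = rng.random(shape) < 0.5
    if not mask.any():
        mask[0, 0, 0] = True
    return (
        DoseGrid(values=values, spacing=spacing),
        RoiMask(values=mask, spacing=spacing, name="roi"),
    )
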