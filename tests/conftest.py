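import numpy as np
import pytest

from humibuild.arena import EMPTY, ArenaGeometry
from humibuild.conditions import Condition, ConditionKind
from humibuild.physics import HumidityField, PhysicsParams, SubstrateMoisture


@pytest.fixture
def still() -> Condition:
    return Condition(ConditionKind.STILL_WET)


def open_geometry(nx: int, ny: int, cell_size: float = 1.0, lid_extent_y: float = 0.0,
                  corridor=(0, -1)) -> ArenaGeometry:
    """Structure-free arena for pure field-physics tests."""
    return ArenaGeometry(
        occupancy=np.full((nx, ny), EMPTY, dtype=np.int8),
        cell_size=cell_size,
        lid_extent_y=lid_extent_y,
        initial_wall_front_y=0.0,
        supply_position=(0, 0),
        corridor_ix=corridor,
        tunnel_center_x=nx * cell_size / 2,
        block_size=3.0,
        wall_seed_cell=(0, 0),
    )


def make_system(nx=20, ny=20, value=40.0, params=None, dt_safety=0.25):
    """Field + dry moisture + open geometry with a stability-checked dt."""
    params = params or PhysicsParams()
    geom = open_geometry(nx, ny)
    field = HumidityField.uniform(nx, ny, value, 1.0, params, dt_safety)
    moisture = SubstrateMoisture(np.zeros((nx, ny)), params.capacity)
    return geom, field, moisture, params
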